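"""Polymorphism statistics on allele alignments.

Computes segregating sites S and the total mutation count eta, nucleotide
diversity pi and mean pairwise differences k, Tajima's D (global and in a
sliding window), protein-level collapsing of synonymous alleles, the
per-allele frequency spectrum and the reads-vs-alleles correlation.

Conventions (matching the complete-deletion-per-site behaviour of standard
polymorphism software): alignment columns containing a gap or any non-ACGT
symbol are excluded from S, eta, pi and k; eta counts (distinct observed
bases - 1) per column; pi is k divided by the number of included sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "AlignmentStats",
    "SlidingProfile",
    "segregating_sites",
    "diversity",
    "tajimas_d",
    "tajima_significance",
    "sliding_tajima",
    "alignment_stats",
    "collapse_to_protein",
    "allele_spectrum",
    "reads_vs_alleles_correlation",
]


def _as_matrix(alignment) -> np.ndarray:
    seqs = [s if isinstance(s, str) else str(s.seq) for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    return np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs])


_ACGT = np.array([65, 67, 71, 84], dtype=np.uint8)


def _clean_columns(mat: np.ndarray) -> np.ndarray:
    return np.all(np.isin(mat, _ACGT), axis=0)


def _column_base_counts(mat: np.ndarray) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column."""
    return np.array([(mat == b).sum(axis=0) for b in _ACGT])


def segregating_sites(alignment) -> tuple[int, int]:
    """Count variable columns (S) and total mutations (eta).

    eta sums, over variable columns, the number of distinct observed bases
    minus one — the minimum number of substitutions explaining the column.
    """
    mat = _as_matrix(alignment)
    keep = _clean_columns(mat)
    counts = _column_base_counts(mat[:, keep])
    n_states = (counts > 0).sum(axis=0)
    S = int((n_states > 1).sum())
    eta = int((n_states - 1).sum())
    return S, eta


def diversity(alignment) -> tuple[float, float]:
    """Nucleotide diversity per site (pi) and mean pairwise differences (k).

    k averages the per-pair difference count over all n(n-1)/2 unordered
    pairs; pi divides by the number of included (gap-free, unambiguous)
    sites, so pi * L = k on clean alignments.
    """
    mat = _as_matrix(alignment)
    keep = _clean_columns(mat)
    sub = mat[:, keep]
    n, L = sub.shape
    if L == 0:
        return 0.0, 0.0
    counts = _column_base_counts(sub)
    pairs_total = n * (n - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    k = float((pairs_total - same).sum() / pairs_total)
    return k / L, k


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alignment) -> float | None:
    """Tajima's D: normalised difference between pi- and S-based theta estimates.

    Positive values indicate an excess of intermediate-frequency variants
    (balancing selection); negative values an excess of rare variants.
    Returns ``None`` (undefined) when the alignment has no segregating site.
    """
    mat = _as_matrix(alignment)
    n = mat.shape[0]
    S, _ = segregating_sites(alignment)
    if S == 0:
        return None
    _, k = diversity(alignment)
    c = _tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:  # degenerate, e.g. n = 3 with a single segregating site
        return None
    return float((k - S / c["a1"]) / math.sqrt(var))


def tajima_significance(d: float, n: int) -> float:
    """Two-sided p-value for Tajima's D under the beta approximation.

    D is assumed to follow a generalised beta distribution on
    ``[Dmin, Dmax]`` with mean 0 and variance 1 (the standard confidence
    bounds of the original test).
    """
    c = _tajima_constants(n)
    dmin = (2.0 / n - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    dmax = ((n + 1) / (2.0 * n) - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    span = dmax - dmin
    mean_u = -dmin / span
    var_u = 1.0 / span**2
    common = mean_u * (1 - mean_u) / var_u - 1.0
    alpha = mean_u * common
    beta_p = (1 - mean_u) * common
    u = min(max((d - dmin) / span, 0.0), 1.0)
    cdf = stats.beta.cdf(u, alpha, beta_p)
    return float(2.0 * min(cdf, 1.0 - cdf))


@dataclass
class SlidingProfile:
    """Per-window Tajima's D values; coordinates are 1-based inclusive."""

    windows: list[tuple[int, int, float | None]]
    window_size: int
    step: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["start", "end", "tajimas_d"])

    def mean_d(self) -> float | None:
        vals = [d for _, _, d in self.windows if d is not None]
        return float(np.mean(vals)) if vals else None


def sliding_tajima(alignment, window: int = 24, step: int = 3) -> SlidingProfile:
    """Tajima's D in sliding windows along the alignment."""
    if window < 4:
        raise ValueError("window must cover at least 4 nucleotides")
    seqs = [s if isinstance(s, str) else str(s.seq) for s in alignment]
    L = len(seqs[0])
    if window > L:
        raise ValueError("window exceeds alignment length")
    out = []
    start = 1
    while start + window - 1 <= L:
        end = start + window - 1
        chunk = [s[start - 1 : end] for s in seqs]
        s_count, _ = segregating_sites(chunk)
        d = tajimas_d(chunk) if s_count > 0 else None
        out.append((start, end, d))
        start += step
    return SlidingProfile(windows=out, window_size=window, step=step)


@dataclass
class AlignmentStats:
    n: int
    length: int
    S: int
    eta: int
    pi: float
    k: float
    tajimas_d: float | None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "length": self.length,
            "S": self.S,
            "eta": self.eta,
            "pi": self.pi,
            "k": self.k,
            "tajimas_d": self.tajimas_d,
        }


def alignment_stats(alignment) -> AlignmentStats:
    """All scalar polymorphism statistics for one alignment."""
    mat = _as_matrix(alignment)
    S, eta = segregating_sites(alignment)
    pi, k = diversity(alignment)
    return AlignmentStats(
        n=mat.shape[0],
        length=mat.shape[1],
        S=S,
        eta=eta,
        pi=pi,
        k=k,
        tajimas_d=tajimas_d(alignment),
    )


def collapse_to_protein(
    sequences: dict[str, str],
    counts: dict[str, float] | None = None,
    intron_tail_len: int = 7,
) -> tuple[dict[str, list[str]], list[str]]:
    """Group nucleotide alleles into amino-acid classes.

    Translates the exon portion (after ``intron_tail_len``) of each allele;
    alleles with identical protein sequence form one class, named after the
    most common member (by ``counts``, ties broken by name).  Returns the
    classes as ``{class_name: [member names]}`` plus the list of alleles
    whose translation contains a stop codon (excluded from classes).
    """
    by_protein: dict[str, list[str]] = {}
    nonfunctional: list[str] = []
    for name, seq in sequences.items():
        exon = seq[intron_tail_len:]
        if len(exon) % 3:
            raise ValueError(f"exon of {name} not a whole number of codons")
        protein = str(Seq(exon).translate())
        if "*" in protein:
            nonfunctional.append(name)
            continue
        by_protein.setdefault(protein, []).append(name)
    classes: dict[str, list[str]] = {}
    for members in by_protein.values():
        if counts:
            rep = max(members, key=lambda m: (counts.get(m, 0), m))
        else:
            rep = sorted(members)[0]
        classes[rep] = sorted(members)
    return classes, sorted(nonfunctional)


def allele_spectrum(
    table, protein_class_of: dict[str, str] | None = None
) -> pd.Series:
    """Number of QC-passed individuals carrying each allele (or protein class).

    Presence/absence: an allele shared by both haplotypes of an individual
    counts once.  Sorted by decreasing prevalence.
    """
    tally: dict[str, int] = {}
    for _, alleles in table.pass_rows():
        names = {a for a, _ in alleles}
        if protein_class_of:
            names = {protein_class_of.get(a, a) for a in names}
        for name in names:
            tally[name] = tally.get(name, 0) + 1
    s = pd.Series(tally, dtype=int)
    return s.sort_values(ascending=False, kind="stable")


def reads_vs_alleles_correlation(table) -> tuple[float, float]:
    """Pearson correlation of per-individual read totals against allele counts."""
    reads, alleles = [], []
    for ind, row in table.pass_rows():
        reads.append(table.total_reads(ind))
        alleles.append(len({a for a, _ in row}))
    if len(reads) < 3:
        raise ValueError("need at least three QC-passed individuals")
    if len(set(alleles)) < 2 or len(set(reads)) < 2:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(reads, alleles)
    return float(r), float(p)
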