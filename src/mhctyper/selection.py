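"""Codon-level tests of selection and recombination on allele alignments.

Implements the modified Nei–Gojobori counting method (potential synonymous /
nonsynonymous sites weighted by the transition/transversion ratio R, observed
differences averaged over all minimum-length mutational pathways) with
Jukes–Cantor distance correction; a codon-bootstrap Z-test of positive
selection on an a priori peptide-binding-region (PBR) partition; and the
pairwise-incompatibility Phi statistic for recombination.

Notation
--------
For a codon, each of its three positions can change to three other bases:
one transition and two transversions.  The modified method gives transitions
total weight ``2R`` against ``2`` for the transversions, so the synonymous
fraction of a position is ``(2R*syn_ts + syn_tv) / (2R + 2)``; with
``R = 0.5`` every change is weighted equally and the counts reduce to the
unmodified method.  Changes producing a stop codon count as nonsynonymous,
which keeps N + S = 3 per codon for any R.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

__all__ = [
    "CodonPartition",
    "SelectionResult",
    "PhiResult",
    "JukesCantorUndefinedError",
    "load_pbr_mask",
    "nei_gojobori_pair",
    "partition_z_test",
    "estimate_ts_tv_ratio",
    "phi_statistic",
    "export_for_external",
    "read_relaxed_phylip",
]

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class JukesCantorUndefinedError(ValueError):
    """Raised when a proportion of differences reaches 3/4 and the JC distance diverges."""


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def _codon_sites(codon: str, r: float) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) site counts of one codon."""
    syn_total = 0.0
    denom = 2.0 * r + 2.0
    aa0 = _aa(codon)
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            weight = 2.0 * r if b == _TRANSITION[codon[pos]] else 1.0
            if mutant not in STOPS and _aa(mutant) == aa0:
                syn_total += weight / denom
    return syn_total, 3.0 - syn_total


@lru_cache(maxsize=None)
def _codon_pair_diffs(a: str, b: str) -> tuple[float, float]:
    """Observed (synonymous, nonsynonymous) differences between two codons.

    Averages over every ordering of the differing positions (minimum-length
    pathways), equally weighted; pathways passing through a stop codon are
    excluded unless all are blocked.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for path in permutations(diff):
        cur = a
        syn = nonsyn = 0.0
        blocked = False
        for pos in path:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        if not blocked:
            results.append((syn, nonsyn))
    if not results:  # all pathways traverse stops; fall back to unrestricted
        for path in permutations(diff):
            cur = a
            syn = nonsyn = 0.0
            for pos in path:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt not in STOPS and _aa(nxt) == _aa(cur):
                    syn += 1.0
                else:
                    nonsyn += 1.0
                cur = nxt
            results.append((syn, nonsyn))
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


def _jc(p: float) -> float:
    if p >= 0.75:
        raise JukesCantorUndefinedError(
            f"proportion {p:.3f} >= 3/4: Jukes-Cantor distance undefined"
        )
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori_pair(
    seq_a: str,
    seq_b: str,
    r: float = 0.5,
    jc_correction: bool = True,
) -> tuple[float, float, float, float, float, float]:
    """Pairwise (dn, ds, Nd, Sd, N, S) by the modified Nei–Gojobori method.

    Codons containing a gap or ambiguity in either sequence are skipped
    (pairwise deletion).  Potential site counts are averaged between the two
    sequences.  Proportions are converted to distances with the Jukes–Cantor
    formula when ``jc_correction`` is set.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("length must be a multiple of 3 (codon alignment)")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    n_sites = s_sites = nd = sd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if set(ca + cb) - set(BASES):
            continue
        if ca in STOPS or cb in STOPS:
            raise ValueError(f"stop codon at position {i + 1}")
        sa, na = _codon_sites(ca, r)
        sb, nb = _codon_sites(cb, r)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        syn, nonsyn = _codon_pair_diffs(ca, cb)
        sd += syn
        nd += nonsyn
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    if jc_correction:
        dn, ds = _jc(pn), _jc(ps)
    else:
        dn, ds = pn, ps
    return dn, ds, nd, sd, n_sites, s_sites


def estimate_ts_tv_ratio(alignment) -> float:
    """Kimura two-parameter transition/transversion rate ratio of an alignment.

    Pools the transition (P) and transversion (Q) proportions over all
    sequence pairs and clean columns, then returns the ratio of the K2P
    transition and transversion distance components.  Falls back to the raw
    count ratio (or 0.5) where the logarithms are undefined.
    """
    seqs = [s if isinstance(s, str) else str(s.seq) for s in alignment]
    mat = np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs])
    keep = np.all(np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8)), axis=0)
    sub = mat[:, keep]
    n = sub.shape[0]
    ts = tv = total = 0
    purines = (sub == ord("A")) | (sub == ord("G"))
    for i in range(n):
        for j in range(i + 1, n):
            neq = sub[i] != sub[j]
            same_class = purines[i] == purines[j]
            ts += int((neq & same_class).sum())
            tv += int((neq & ~same_class).sum())
            total += sub.shape[1]
    if total == 0 or ts + tv == 0:
        return 0.5
    P, Q = ts / total, tv / total
    try:
        s_comp = 0.5 * math.log(1.0 / (1.0 - 2 * P - Q)) - 0.25 * math.log(
            1.0 / (1.0 - 2 * Q)
        )
        v_comp = 0.5 * math.log(1.0 / (1.0 - 2 * Q))
        if v_comp <= 0:
            raise ValueError
        return max(s_comp / v_comp, 1e-3)
    except ValueError:
        return max(P / Q, 1e-3) if Q > 0 else 10.0


@dataclass(frozen=True)
class CodonPartition:
    """A priori split of codon indices into PBR and non-PBR sets (1-based)."""

    pbr_codons: frozenset[int]
    n_codons: int = 90

    def __post_init__(self) -> None:
        if not self.pbr_codons:
            raise ValueError("PBR codon set is empty")
        bad = [c for c in self.pbr_codons if not 1 <= c <= self.n_codons]
        if bad:
            raise ValueError(f"codon indices out of range 1..{self.n_codons}: {bad}")

    @property
    def non_pbr_codons(self) -> frozenset[int]:
        return frozenset(range(1, self.n_codons + 1)) - self.pbr_codons


def load_pbr_mask(path=None, n_codons: int = 90) -> CodonPartition:
    """Read a codon-index mask file (one 1-based index per line, '#' comments).

    Without a path, loads the packaged peptide-contact mask derived from the
    human class II crystal structure mapped onto the 90-codon exon-2
    alignment.
    """
    if path is None:
        ref = importlib.resources.files("mhctyper").joinpath("data/pbr_codons.txt")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    codons = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codons.add(int(line))
    return CodonPartition(frozenset(codons), n_codons=n_codons)


@dataclass
class SelectionResult:
    """Substitution rates, bootstrap errors and the positive-selection Z-test."""

    dn: float
    ds: float
    se_dn: float
    se_ds: float
    z: float
    p: float
    n_codons: int

    @property
    def omega(self) -> float | None:
        return self.dn / self.ds if self.ds > 0 else None

    def to_dict(self) -> dict:
        return {
            "dn": self.dn,
            "ds": self.ds,
            "se_dn": self.se_dn,
            "se_ds": self.se_ds,
            "z": self.z,
            "p": self.p,
            "omega": self.omega,
            "n_codons": self.n_codons,
        }


def _pair_codon_arrays(seqs: list[str], r: float):
    """Per-pair, per-codon Nd/Sd/N/S arrays (pairs x codons), pairwise deletion."""
    n = len(seqs)
    L = len(seqs[0])
    n_codons = L // 3
    codons = [[s[3 * c : 3 * c + 3] for c in range(n_codons)] for s in seqs]
    n_pairs = n * (n - 1) // 2
    nd = np.zeros((n_pairs, n_codons), dtype=np.float32)
    sd = np.zeros_like(nd)
    nsites = np.zeros_like(nd)
    ssites = np.zeros_like(nd)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = codons[i], codons[j]
            for c in range(n_codons):
                ca, cb = ci[c], cj[c]
                if set(ca + cb) - set(BASES) or ca in STOPS or cb in STOPS:
                    continue
                sa, na = _codon_sites(ca, r)
                sb, nb = _codon_sites(cb, r)
                syn, nonsyn = _codon_pair_diffs(ca, cb)
                nd[idx, c] = nonsyn
                sd[idx, c] = syn
                nsites[idx, c] = (na + nb) / 2.0
                ssites[idx, c] = (sa + sb) / 2.0
            idx += 1
    return nd, sd, nsites, ssites


def _jc_vec(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(p < 0.75, -0.75 * np.log(1.0 - 4.0 * np.clip(p, 0, 0.7499999) / 3.0), np.nan)
    return out


def _mean_rates(
    nd, sd, nsites, ssites, cols: np.ndarray, jc_correction: bool = True
) -> tuple[float, float]:
    nd_p = nd[:, cols].sum(axis=1)
    sd_p = sd[:, cols].sum(axis=1)
    n_p = nsites[:, cols].sum(axis=1)
    s_p = ssites[:, cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pn = np.where(n_p > 0, nd_p / n_p, np.nan)
        ps = np.where(s_p > 0, sd_p / s_p, np.nan)
    if jc_correction:
        pn, ps = _jc_vec(pn), _jc_vec(ps)

    def _nanmean(x: np.ndarray) -> float:
        x = x[~np.isnan(x)]
        return float(x.mean()) if x.size else float("nan")

    return _nanmean(pn), _nanmean(ps)


def partition_z_test(
    alignment,
    partition: CodonPartition,
    r: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    jc_correction: bool = True,
) -> dict[str, SelectionResult]:
    """One-tailed Z-test of positive selection (dn > ds) per codon partition.

    dn and ds are the modified Nei–Gojobori rates averaged over all sequence
    pairs, restricted to each side of the partition; their standard errors
    come from ``n_boot`` bootstrap resamplings of codon sites within the
    side.  ``r=None`` estimates the transition/transversion ratio from the
    alignment by the Kimura two-parameter method.
    """
    seqs = [s if isinstance(s, str) else str(s.seq) for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0])
    if L % 3:
        raise ValueError("codon alignment length must be a multiple of 3")
    n_codons = L // 3
    if partition.n_codons != n_codons:
        raise ValueError(
            f"partition defined for {partition.n_codons} codons, alignment has {n_codons}"
        )
    if not partition.pbr_codons or not partition.non_pbr_codons:
        raise ValueError("both sides of the partition must be non-empty")
    if r is None:
        r = estimate_ts_tv_ratio(seqs)
    nd, sd, nsites, ssites = _pair_codon_arrays(seqs, r)
    rng = np.random.default_rng(seed)
    out: dict[str, SelectionResult] = {}
    for label, codon_set in (
        ("pbr", partition.pbr_codons),
        ("non_pbr", partition.non_pbr_codons),
    ):
        cols = np.array(sorted(c - 1 for c in codon_set), dtype=int)
        dn, ds = _mean_rates(nd, sd, nsites, ssites, cols, jc_correction)
        boot_dn = np.empty(n_boot)
        boot_ds = np.empty(n_boot)
        for b in range(n_boot):
            resampled = cols[rng.integers(0, len(cols), size=len(cols))]
            boot_dn[b], boot_ds[b] = _mean_rates(
                nd, sd, nsites, ssites, resampled, jc_correction
            )
        se_dn = float(np.nanstd(boot_dn, ddof=1))
        se_ds = float(np.nanstd(boot_ds, ddof=1))
        denom = math.hypot(se_dn, se_ds)
        z = (dn - ds) / denom if denom > 0 else 0.0
        p = float(stats.norm.sf(z))
        out[label] = SelectionResult(
            dn=dn, ds=ds, se_dn=se_dn, se_ds=se_ds, z=z, p=p, n_codons=len(cols)
        )
    return out


@dataclass
class PhiResult:
    """Pairwise homoplasy index with permutation and analytic p-values."""

    phi: float
    p_permutation: float
    p_analytic: float
    n_informative: int
    window: int


def _informative_columns(seqs: list[str]) -> np.ndarray:
    mat = np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs])
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    cols = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if not np.all(np.isin(col, acgt)):
            continue
        _, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            cols.append(j)
    return mat[:, cols] if cols else np.empty((mat.shape[0], 0), dtype=np.uint8)


def _incompatible(col_a: np.ndarray, col_b: np.ndarray) -> bool:
    """Two sites are incompatible when their state-intersection graph has a cycle."""
    edges = {(int(a), int(b)) for a, b in zip(col_a, col_b)}
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        u, v = ("a", a), ("b", b)
        for node in (u, v):
            parent.setdefault(node, node)
        ru, rv = find(u), find(v)
        if ru == rv:
            return True
        parent[ru] = rv
    return False


def phi_statistic(
    alignment,
    window: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> PhiResult:
    """Phi test of recombination (pairwise homoplasy index).

    Phi is the mean incompatibility of pairs of parsimony-informative sites
    within ``window`` informative sites of each other.  Recombination makes
    nearby sites share genealogies, so the observed Phi falls below its
    site-order-permutation null; the p-value is the left-tail probability,
    reported both by ``n_perm`` permutations and by a normal approximation
    with the exact permutation mean and variance.
    """
    seqs = [s if isinstance(s, str) else str(s.seq) for s in alignment]
    if len(seqs) < 4:
        raise ValueError("need at least four sequences")
    inf = _informative_columns(seqs)
    m = inf.shape[1]
    if m < 2:
        raise ValueError("fewer than two parsimony-informative sites: Phi undefined")
    M = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            M[i, j] = M[j, i] = float(_incompatible(inf[:, i], inf[:, j]))

    near = [(i, j) for i in range(m) for j in range(i + 1, min(i + window, m - 1) + 1)]
    n_near = len(near)
    phi_obs = float(np.mean([M[i, j] for i, j in near]))

    # exact permutation moments
    mu = float(M.sum() / (m * (m - 1)))
    row = M.sum(axis=1)
    q3 = float((row**2 - row).sum()) / (m * (m - 1) * (m - 2)) if m > 2 else mu
    s1 = float(M.sum())  # ordered sum (M symmetric, zero diagonal)
    if m > 3:
        t4 = (s1**2 - 2 * s1 - 4 * float((row**2 - row).sum())) / (
            m * (m - 1) * (m - 2) * (m - 3)
        )
    else:
        t4 = mu**2
    deg = np.zeros(m)
    for i, j in near:
        deg[i] += 1
        deg[j] += 1
    shared1 = float((deg * (deg - 1) / 2).sum())
    disjoint = n_near * (n_near - 1) / 2.0 - shared1
    var = (
        n_near * mu * (1 - mu)
        + 2 * shared1 * (q3 - mu**2)
        + 2 * disjoint * (t4 - mu**2)
    ) / n_near**2
    if var > 1e-15:
        p_analytic = float(stats.norm.cdf((phi_obs - mu) / math.sqrt(var)))
    else:
        p_analytic = 1.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        val = np.mean([M[perm[i], perm[j]] for i, j in near])
        if val <= phi_obs + 1e-12:
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    return PhiResult(
        phi=phi_obs,
        p_permutation=float(p_perm),
        p_analytic=p_analytic,
        n_informative=m,
        window=window,
    )


def export_for_external(
    sequences: dict[str, str], fasta_path, phylip_path=None
) -> None:
    """Write a codon alignment as sequential FASTA and relaxed PHYLIP."""
    if not sequences:
        raise ValueError("refusing to export an empty alignment")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("alignment export requires equal-length sequences")
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(records, fasta_path, "fasta")
    if phylip_path is not None:
        L = lengths.pop()
        with open(phylip_path, "w") as fh:
            fh.write(f" {len(sequences)} {L}\n")
            for n, s in sequences.items():
                fh.write(f"{n}  {s}\n")


def read_relaxed_phylip(path) -> dict[str, str]:
    """Read back a relaxed (whitespace-delimited) sequential PHYLIP alignment."""
    with open(path) as fh:
        header = fh.readline().split()
        n, L = int(header[0]), int(header[1])
        out: dict[str, str] = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            out[name] = seq.strip()
    if len(out) != n or any(len(s) != L for s in out.values()):
        raise ValueError("malformed PHYLIP alignment")
    return out
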