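"""Synthetic amplicon data with known ground truth.

Emulates a pyrosequencing survey of a duplicated MHC class II B gene family:
a population-wide pool of exon-2 amplicon alleles (270 nt of coding sequence
preceded by the last 7 nt of intron 1), diploid individuals whose two
haplotypes carry a variable number of gene copies, and dual-barcoded reads
with per-base substitution error, heavily right-skewed per-individual depth
and single-crossover PCR chimeras.  Every read's provenance is recorded in a
truth table so downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .copynumber import HaplotypeClassFreqs

__all__ = [
    "AllelePool",
    "TrueGenotype",
    "BarcodeScheme",
    "ReadSimParams",
    "SimulatedRead",
    "generate_allele_pool",
    "sample_population",
    "make_barcode_scheme",
    "simulate_reads",
    "DEFAULT_FW_PRIMER",
    "DEFAULT_RV_PRIMER",
]

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

# Locus-specific amplification primers (intron-1 anchored forward, intron-2
# anchored reverse); concrete sequences used when writing simulated reads.
DEFAULT_FW_PRIMER = "CTGACCAGCCTCCCTGCA"
DEFAULT_RV_PRIMER = "TTGTGCCACACACCCACC"  # given 5'->3' on the reverse strand

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AllelePool:
    """A population-wide catalogue of amplicon allele sequences.

    Each sequence is ``intron_tail_len`` nucleotides of intron followed by an
    ``exon_len``-nt coding region (reading frame starts at position
    ``intron_tail_len``, 0-based).
    """

    alleles: tuple[tuple[str, str], ...]
    exon_len: int = 270
    intron_tail_len: int = 7

    def __post_init__(self) -> None:
        L = self.exon_len + self.intron_tail_len
        seqs = [s for _, s in self.alleles]
        if any(len(s) != L for s in seqs):
            raise ValueError(f"all allele sequences must have length {L}")
        if len(set(seqs)) != len(seqs):
            raise ValueError("allele sequences must be unique")
        if any(set(s) - set(BASES) for s in seqs):
            raise ValueError("allele alphabet restricted to A/C/G/T")

    @property
    def length(self) -> int:
        return self.exon_len + self.intron_tail_len

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.alleles]

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.alleles)

    def exon(self, name: str) -> str:
        return self.sequences[name][self.intron_tail_len :]


@dataclass(frozen=True)
class TrueGenotype:
    """Ground-truth diploid genotype: allele names per inherited haplotype."""

    individual_id: str
    maternal_alleles: tuple[str, ...]
    paternal_alleles: tuple[str, ...]

    @property
    def distinct_alleles(self) -> frozenset[str]:
        return frozenset(self.maternal_alleles) | frozenset(self.paternal_alleles)

    @property
    def slots(self) -> tuple[str, ...]:
        return self.maternal_alleles + self.paternal_alleles


def _has_stop(seq: str, frame_start: int) -> bool:
    exon = seq[frame_start:]
    return any(
        exon[i : i + 3] in STOP_CODONS for i in range(0, len(exon) - len(exon) % 3, 3)
    )


def _codon_bounds(pos: int, frame_start: int, length: int) -> tuple[int, int] | None:
    if pos < frame_start:
        return None
    idx = (pos - frame_start) // 3
    lo = frame_start + 3 * idx
    hi = lo + 3
    if hi > length:
        return None
    return lo, hi


def _codon_to_aa() -> dict[str, str]:
    from Bio.Seq import Seq

    return {
        a + b + c: str(Seq(a + b + c).translate())
        for a in BASES
        for b in BASES
        for c in BASES
    }


_AA: dict[str, str] = _codon_to_aa()


def _mutate_site(
    seq: list[str],
    pos: int,
    rng: np.random.Generator,
    frame_start: int,
    prefer_nonsyn: bool = False,
) -> None:
    """Substitute the base at ``pos``, never creating an in-frame stop codon."""
    current = seq[pos]
    candidates = [b for b in BASES if b != current]
    rng.shuffle(candidates)
    bounds = _codon_bounds(pos, frame_start, len(seq))
    if bounds is None:
        seq[pos] = candidates[0]
        return
    lo, hi = bounds
    codon = seq[lo:hi]
    valid, nonsyn = [], []
    aa0 = _AA["".join(codon)]
    for b in candidates:
        trial = codon.copy()
        trial[pos - lo] = b
        c = "".join(trial)
        if c in STOP_CODONS:
            continue
        valid.append(b)
        if _AA[c] != aa0:
            nonsyn.append(b)
    pick_from = nonsyn if (prefer_nonsyn and nonsyn) else valid
    if pick_from:
        seq[pos] = pick_from[0]


def _kingman_tree(n: int, rng: np.random.Generator) -> tuple[list[tuple[int, int, int]], dict[int, float]]:
    """Random coalescent topology with exponential inter-coalescence times.

    Returns (merge events as (parent, child1, child2)) and branch lengths per
    node, in coalescent units of 2N generations.
    """
    active = list(range(n))
    times = {i: 0.0 for i in range(n)}
    t = 0.0
    events = []
    next_id = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        c1, c2 = active[int(i)], active[int(j)]
        parent = next_id
        next_id += 1
        events.append((parent, c1, c2))
        times[parent] = t
        active = [x for x in active if x not in (c1, c2)] + [parent]
    branch = {}
    for parent, c1, c2 in events:
        branch[c1] = times[parent] - times[c1]
        branch[c2] = times[parent] - times[c2]
    return events, branch


def generate_allele_pool(
    n_alleles: int,
    exon_len: int = 270,
    intron_tail_len: int = 7,
    divergence: float = 0.18,
    seed: int = 0,
    deep_split: float = 0.0,
    selected_codons: frozenset[int] | set[int] | None = None,
    selection_boost: float = 1.0,
    include_stop_allele: bool = False,
    name_prefix: str = "Fuat-DAB*",
) -> AllelePool:
    """Generate a pool of unique, stop-free amplicon allele sequences.

    Alleles descend from a random stop-free ancestor along a Kingman
    coalescent genealogy; substitutions are placed on branches at a per-site
    rate calibrated so the expected pairwise divergence is ``divergence``.
    ``deep_split > 0`` adds a long root branch separating two balanced clades,
    emulating the intermediate-frequency variants maintained by balancing
    selection.  ``selected_codons`` (1-based within the exon) take a
    ``selection_boost``-fold higher substitution rate biased toward
    nonsynonymous changes, emulating positive selection on peptide-contact
    codons.

    Deterministic given ``seed``.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if exon_len % 3:
        raise ValueError("exon_len must be divisible by 3")
    L = exon_len + intron_tail_len
    if math.log(n_alleles) > L * math.log(4) - 1:
        raise ValueError("n_alleles exceeds the available sequence space")
    rng = np.random.default_rng(seed)

    # stop-free random ancestor
    anc = list(rng.choice(list(BASES), size=intron_tail_len))
    sense = [c for c in _all_codons() if c not in STOP_CODONS]
    anc += list("".join(rng.choice(sense) for _ in range(exon_len // 3)))

    # boost only the first two codon positions, where changes are mostly
    # nonsynonymous; third positions keep the background (synonymous) rate
    rates = np.full(L, divergence / 2.0)
    boosted = np.zeros(L, dtype=bool)
    if selected_codons:
        for c in selected_codons:
            lo = intron_tail_len + 3 * (c - 1)
            rates[lo : lo + 2] *= selection_boost
            boosted[lo : lo + 2] = True

    if n_alleles == 1:
        tips = {0: anc.copy()}
    else:
        tips = _evolve_tips(anc, n_alleles, rates, boosted, intron_tail_len, rng, deep_split)

    # enforce uniqueness: extra substitutions on duplicates
    seqs = ["".join(tips[i]) for i in range(n_alleles)]
    seen: dict[str, int] = {}
    for i, s in enumerate(seqs):
        guard = 0
        while s in seen:
            cur = list(s)
            _mutate_site(cur, int(rng.integers(L)), rng, intron_tail_len)
            s = "".join(cur)
            guard += 1
            if guard > 10_000:
                raise ValueError("could not generate unique alleles")
        seen[s] = i
        seqs[i] = s

    if include_stop_allele:
        cur = list(seqs[-1])
        codon_idx = int(rng.integers(exon_len // 3 - 1))  # internal codon
        lo = intron_tail_len + 3 * codon_idx
        cur[lo : lo + 3] = list("TAA")
        s = "".join(cur)
        while s in seen:
            _mutate_site(cur, int(rng.integers(intron_tail_len)), rng, intron_tail_len)
            s = "".join(cur)
        seqs[-1] = s

    alleles = tuple(
        (f"{name_prefix}{i + 1}", s) for i, s in enumerate(seqs)
    )
    return AllelePool(alleles, exon_len=exon_len, intron_tail_len=intron_tail_len)


def _all_codons() -> list[str]:
    return [a + b + c for a in BASES for b in BASES for c in BASES]


def _evolve_tips(
    anc: list[str],
    n: int,
    rates: np.ndarray,
    boosted: np.ndarray,
    frame_start: int,
    rng: np.random.Generator,
    deep_split: float,
) -> dict[int, list[str]]:
    if deep_split > 0 and n >= 2:
        n1 = n // 2
        left = _subtree(anc, n1, rates, boosted, frame_start, rng, root_branch=deep_split)
        right = _subtree(anc, n - n1, rates, boosted, frame_start, rng, root_branch=deep_split)
        tips = {i: left[i] for i in range(n1)}
        tips.update({n1 + i: right[i] for i in range(n - n1)})
        return tips
    return _subtree(anc, n, rates, boosted, frame_start, rng, root_branch=0.0)


def _subtree(
    anc: list[str],
    n: int,
    rates: np.ndarray,
    boosted: np.ndarray,
    frame_start: int,
    rng: np.random.Generator,
    root_branch: float,
) -> dict[int, list[str]]:
    if n == 1:
        seq = anc.copy()
        _apply_branch(seq, root_branch, rates, boosted, frame_start, rng)
        return {0: seq}
    events, branch = _kingman_tree(n, rng)
    root = events[-1][0]
    branch[root] = root_branch
    children: dict[int, tuple[int, int]] = {p: (c1, c2) for p, c1, c2 in events}
    seqs: dict[int, list[str]] = {}

    def descend(node: int, parent_seq: list[str]) -> None:
        seq = parent_seq.copy()
        _apply_branch(seq, branch.get(node, 0.0), rates, boosted, frame_start, rng)
        if node in children:
            c1, c2 = children[node]
            descend(c1, seq)
            descend(c2, seq)
        else:
            seqs[node] = seq

    descend(root, anc)
    return seqs


def _apply_branch(
    seq: list[str],
    length: float,
    rates: np.ndarray,
    boosted: np.ndarray,
    frame_start: int,
    rng: np.random.Generator,
) -> None:
    if length <= 0:
        return
    lam = rates * length
    n_mut = rng.poisson(lam)
    for pos in np.nonzero(n_mut)[0]:
        for _ in range(int(n_mut[pos])):
            _mutate_site(seq, int(pos), rng, frame_start, prefer_nonsyn=bool(boosted[pos]))


def sample_population(
    pool: AllelePool,
    freqs: HaplotypeClassFreqs,
    n_individuals: int,
    allele_freqs: np.ndarray | None = None,
    seed: int = 0,
    id_prefix: str = "bird",
) -> list[TrueGenotype]:
    """Draw diploid genotypes from copy-number-variable haplotypes.

    Each individual inherits two haplotypes whose gene counts are drawn from
    ``freqs.p``; every gene slot receives an allele drawn from
    ``allele_freqs`` (uniform by default).  With probability ``freqs.s`` the
    allele in each paired maternal/paternal slot is copied from the maternal
    one, emulating haplotype-level allele sharing.
    """
    if not pool.alleles:
        raise ValueError("empty allele pool")
    names = pool.names
    if allele_freqs is None:
        allele_freqs = np.full(len(names), 1.0 / len(names))
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    if len(allele_freqs) != len(names):
        raise ValueError("allele_freqs length must match pool size")
    if abs(allele_freqs.sum() - 1.0) > 1e-8:
        raise ValueError("allele_freqs must sum to 1")
    rng = np.random.default_rng(seed)
    g_values = np.arange(1, freqs.g_max + 1)
    p = np.asarray(freqs.p)
    out = []
    width = len(str(n_individuals))
    for i in range(n_individuals):
        g1, g2 = rng.choice(g_values, size=2, p=p)
        maternal = [str(x) for x in rng.choice(names, size=int(g1), p=allele_freqs)]
        paternal = [str(x) for x in rng.choice(names, size=int(g2), p=allele_freqs)]
        for j in range(min(int(g1), int(g2))):
            if rng.random() < freqs.s:
                paternal[j] = maternal[j]
        out.append(
            TrueGenotype(
                individual_id=f"{id_prefix}{i + 1:0{width}d}",
                maternal_alleles=tuple(maternal),
                paternal_alleles=tuple(paternal),
            )
        )
    return out


@dataclass(frozen=True)
class BarcodeScheme:
    """Dual-index barcode design: forward/reverse tag lists plus pairing map."""

    forward_tags: tuple[str, ...]
    reverse_tags: tuple[str, ...]
    pairing: dict[tuple[int, int], str] = field(hash=False)

    def __post_init__(self) -> None:
        for tags in (self.forward_tags, self.reverse_tags):
            if not tags:
                raise ValueError("tag list empty")
            for t in tags:
                if not 4 <= len(t) <= 8 or set(t) - set(BASES):
                    raise ValueError(f"invalid tag {t!r}: need 4-8 nt of A/C/G/T")
            for i, a in enumerate(tags):
                for b in tags[i + 1 :]:
                    d = edlib.align(a, b, task="distance")["editDistance"]
                    if d < 3:
                        raise ValueError(f"tags {a!r} and {b!r} differ by only {d} < 3")
        ids = list(self.pairing.values())
        if len(set(ids)) != len(ids):
            raise ValueError("pairing must be injective (one individual per tag pair)")
        for fw, rv in self.pairing:
            if not (0 <= fw < len(self.forward_tags) and 0 <= rv < len(self.reverse_tags)):
                raise ValueError("pairing indexes outside tag lists")

    @property
    def individual_of(self) -> dict[tuple[int, int], str]:
        return self.pairing


def make_barcode_scheme(
    individual_ids: list[str],
    n_forward: int = 32,
    n_reverse: int = 32,
    min_len: int = 4,
    max_len: int = 8,
    min_distance: int = 3,
    seed: int = 0,
) -> BarcodeScheme:
    """Greedy random design of dual 4-8 nt tags with pairwise edit distance >= 3."""
    if len(individual_ids) > n_forward * n_reverse:
        raise ValueError("more individuals than tag combinations")
    rng = np.random.default_rng(seed)

    def build(n: int) -> tuple[str, ...]:
        tags: list[str] = []
        attempts = 0
        while len(tags) < n:
            length = int(rng.integers(min_len, max_len + 1))
            cand = "".join(rng.choice(list(BASES), size=length))
            if all(
                edlib.align(cand, t, task="distance")["editDistance"] >= min_distance
                for t in tags
            ):
                tags.append(cand)
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError("could not design enough distant tags")
        return tuple(tags)

    fw = build(n_forward)
    rv = build(n_reverse)
    pairing = {}
    k = 0
    for i in range(n_forward):
        for j in range(n_reverse):
            if k >= len(individual_ids):
                break
            pairing[(i, j)] = individual_ids[k]
            k += 1
    return BarcodeScheme(fw, rv, pairing)


@dataclass(frozen=True)
class ReadSimParams:
    """Sequencing-run emulation parameters.

    Depth per individual is lognormal with the given mean/SD, truncated by
    rejection to ``[depth_min, depth_max]`` — a heavy right tail matching the
    observed mean ~284 and range 29-2741.  ``per_base_error`` is an i.i.d.
    substitution rate over the whole read; ``chimera_rate`` is the fraction of
    reads formed by a single crossover between two of the individual's
    templates at a uniform breakpoint.
    """

    depth_mean: float = 284.0
    depth_sd: float = 284.0
    depth_min: int = 29
    depth_max: int = 2741
    per_base_error: float = 0.002
    chimera_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean <= 0 or self.depth_sd <= 0:
            raise ValueError("depth mean/sd must be positive")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")
        for p in (self.per_base_error, self.chimera_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str


def _draw_depth(rng: np.random.Generator, p: ReadSimParams) -> int:
    sigma2 = math.log(1.0 + (p.depth_sd / p.depth_mean) ** 2)
    mu = math.log(p.depth_mean) - sigma2 / 2.0
    for _ in range(100_000):
        d = int(round(rng.lognormal(mu, math.sqrt(sigma2))))
        if p.depth_min <= d <= p.depth_max:
            return d
    raise RuntimeError("depth truncation bounds reject essentially all draws")


def simulate_reads(
    genotypes: list[TrueGenotype],
    pool: AllelePool,
    scheme: BarcodeScheme,
    params: ReadSimParams,
    fw_primer: str = DEFAULT_FW_PRIMER,
    rv_primer: str = DEFAULT_RV_PRIMER,
    shuffle_orientation: bool = False,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Emit barcoded amplicon reads plus a per-read truth table.

    Each read is ``fw_tag + fw_primer + insert + revcomp(rv_primer) +
    revcomp(rv_tag)``.  The insert is one of the individual's allele
    templates (copy-proportional: shared alleles are sampled once per gene
    slot) or, with probability ``chimera_rate``, a single-crossover hybrid of
    two distinct templates.  Deterministic given ``params.seed``.
    """
    tag_of: dict[str, tuple[int, int]] = {ind: pair for pair, ind in scheme.pairing.items()}
    missing = [g.individual_id for g in genotypes if g.individual_id not in tag_of]
    if missing:
        raise ValueError(f"individuals missing from barcode scheme: {missing[:5]}")
    rng = np.random.default_rng(params.seed)
    seqs = pool.sequences
    L = pool.length
    reads: list[SimulatedRead] = []
    truth_rows = []
    for g in genotypes:
        fw_i, rv_i = tag_of[g.individual_id]
        fw_tag = scheme.forward_tags[fw_i]
        rv_tag = scheme.reverse_tags[rv_i]
        suffix = revcomp(rv_primer) + revcomp(rv_tag)
        depth = _draw_depth(rng, params)
        slots = g.slots
        distinct = sorted(set(slots))
        for r in range(depth):
            is_chimera = False
            breakpoint = -1
            if len(distinct) >= 2 and rng.random() < params.chimera_rate:
                a, b = rng.choice(len(distinct), size=2, replace=False)
                a_name, b_name = distinct[int(a)], distinct[int(b)]
                breakpoint = int(rng.integers(1, L))
                insert = seqs[a_name][:breakpoint] + seqs[b_name][breakpoint:]
                source = f"{a_name}+{b_name}"
                is_chimera = True
            else:
                name = slots[int(rng.integers(len(slots)))]
                insert = seqs[name]
                source = name
            read = fw_tag + fw_primer + insert + suffix
            if params.per_base_error > 0:
                arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                hits = np.nonzero(rng.random(len(arr)) < params.per_base_error)[0]
                for pos in hits:
                    cur = chr(arr[pos])
                    arr[pos] = ord(rng.choice([b for b in BASES if b != cur]))
                read = arr.tobytes().decode()
            read_id = f"{g.individual_id}_r{r + 1:05d}"
            if shuffle_orientation and rng.random() < 0.5:
                read = revcomp(read)
            reads.append(SimulatedRead(read_id, read))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "individual_id": g.individual_id,
                    "source_alleles": source,
                    "is_chimera": is_chimera,
                    "breakpoint": breakpoint,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "individual_id", "source_alleles", "is_chimera", "breakpoint"],
    )
    return reads, truth
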