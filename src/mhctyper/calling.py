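"""Per-individual read clustering, consensus calling, allele validation and genotyping.

The procedure mirrors a conservative amplicon-typing workflow for a
multigene family whose loci cannot be told apart:

1.  Reads from one individual are clustered greedily (identical-sequence
    groups in decreasing abundance) against running cluster consensi, with a
    mismatch ceiling of 2% and no alignment gap longer than 6 nt.
2.  Each cluster's consensus is called with a 75% per-column threshold;
    clusters whose consensus contains an ambiguous column are split by the
    offending column, which resolves co-clustered alleles differing at a
    single position when both are well represented.
3.  Contigs exactly reconstructable as a single crossover of two deeper
    co-occurring contigs are flagged as PCR chimeras.
4.  Identical consensi are pooled across individuals into an allele catalog:
    an allele is *confirmed* when seen in at least two individuals (>= 12
    reads in total), *provisional* when seen once with >= 12 reads at a
    depth not blatantly below its co-occurring alleles, and sequences whose
    exon translation contains a stop codon are set aside as nonfunctional.
5.  Individuals are genotyped by 100% full-length matches to the catalog,
    and individuals with fewer than 25 reads are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "Contig",
    "CatalogEntry",
    "AlleleCatalog",
    "GenotypeTable",
    "cluster_reads",
    "call_consensus",
    "flag_chimeras",
    "build_catalog",
    "genotype_individuals",
    "qc_individuals",
    "call_genotypes",
]

_AMBIG = "N"


@dataclass
class Contig:
    """A per-individual cluster of reads with its consensus and depth."""

    individual_id: str
    member_ids: list[str]
    members: list[str]  # member sequences projected onto consensus coordinates
    consensus: str
    ambiguous_sites: list[int] = field(default_factory=list)  # 0-based columns
    is_chimeric: bool = False

    @property
    def depth(self) -> int:
        return len(self.member_ids)


def _seq_array(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def _project_via_edlib(seq: str, target: str, max_gap: int) -> tuple[float, str] | None:
    """Globally align ``seq`` to ``target``; return (mismatch fraction, projection).

    The projection rewrites ``seq`` in ``target`` coordinates: deletions
    become ``-`` and insertions relative to the target are dropped.  Returns
    None when any contiguous gap run exceeds ``max_gap``.
    """
    res = edlib.align(seq, target, task="path", mode="NW")
    cigar = res["cigar"]
    qi = 0
    out = []
    mismatches = 0
    aligned_cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            frag = seq[qi : qi + n]
            out.append(frag)
            aligned_cols += n
            if ch == "X":
                mismatches += n
            qi += n
        elif ch == "I":  # in seq, absent from target
            if n > max_gap:
                return None
            qi += n
        elif ch == "D":  # absent from seq
            if n > max_gap:
                return None
            out.append("-" * n)
    if aligned_cols == 0:
        return None
    return mismatches / aligned_cols, "".join(out)


class _Cluster:
    __slots__ = ("length", "counts", "member_ids", "members", "size")

    _BASE_IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T

    def __init__(self, founder_seq: str):
        self.length = len(founder_seq)
        self.counts = np.zeros((self.length, 5), dtype=np.int64)
        self.member_ids: list[str] = []
        self.members: list[str] = []
        self.size = 0

    def consensus_plurality(self) -> str:
        if self.size == 0:
            return ""
        idx = np.argmax(self.counts[:, :4], axis=1)
        return "".join("ACGT"[i] for i in idx)

    def add(self, read_id: str, projected: str) -> None:
        arr = _seq_array(projected)
        for code, col in self._BASE_IDX.items():
            self.counts[arr == code, col] += 1
        self.counts[arr == 45, 4] += 1  # '-'
        self.member_ids.append(read_id)
        self.members.append(projected)
        self.size += 1


def _match_to_cluster(
    seq: str, cluster: _Cluster, consensus: str, max_mismatch_frac: float, max_gap: int
) -> tuple[float, str] | None:
    if len(seq) == len(consensus):
        a, b = _seq_array(seq), _seq_array(consensus)
        frac = np.count_nonzero(a != b) / len(seq)
        if frac <= max_mismatch_frac:
            return frac, seq
        return None
    if abs(len(seq) - len(consensus)) > max_gap:
        return None
    proj = _project_via_edlib(seq, consensus, max_gap)
    if proj is None:
        return None
    frac, projected = proj
    if frac <= max_mismatch_frac:
        return frac, projected
    return None


def call_consensus(
    members: Sequence[str], threshold: float = 0.75
) -> tuple[str, list[int]]:
    """Per-column threshold consensus over column-aligned member sequences.

    A column's base is emitted when its frequency among members reaches
    ``threshold``; otherwise the column is written as ``N`` and reported in
    the ambiguous-site list (0-based).
    """
    if not members:
        raise ValueError("no members")
    L = len(members[0])
    if any(len(m) != L for m in members):
        raise ValueError("members must be column-aligned (equal length)")
    n = len(members)
    cols = np.array([_seq_array(m) for m in members])
    out = []
    ambiguous: list[int] = []
    for j in range(L):
        counts = Counter(cols[:, j].tobytes().decode())
        base, cnt = max(
            ((b, c) for b, c in counts.items() if b in "ACGT"),
            key=lambda bc: (bc[1], bc[0]),
            default=(None, 0),
        )
        if base is not None and cnt / n >= threshold:
            out.append(base)
        else:
            out.append(_AMBIG)
            ambiguous.append(j)
    return "".join(out), ambiguous


def _finalize_cluster(
    individual_id: str,
    member_ids: list[str],
    members: list[str],
    threshold: float,
    depth_limit: int = 20,
) -> list[Contig]:
    """Call the threshold consensus; split on ambiguous columns recursively."""
    consensus, ambiguous = call_consensus(members, threshold)
    if not ambiguous or depth_limit == 0:
        # drop gap columns from the reported consensus? keep coordinates: no
        return [
            Contig(
                individual_id=individual_id,
                member_ids=member_ids,
                members=members,
                consensus=consensus,
                ambiguous_sites=ambiguous,
            )
        ]
    col = ambiguous[0]
    groups: dict[str, tuple[list[str], list[str]]] = {}
    for rid, m in zip(member_ids, members):
        ids, seqs = groups.setdefault(m[col], ([], []))
        ids.append(rid)
        seqs.append(m)
    if len(groups) == 1:  # cannot split further; keep flagged
        return [
            Contig(
                individual_id=individual_id,
                member_ids=member_ids,
                members=members,
                consensus=consensus,
                ambiguous_sites=ambiguous,
            )
        ]
    out: list[Contig] = []
    for key in sorted(groups, key=lambda k: (-len(groups[k][0]), k)):
        ids, seqs = groups[key]
        out.extend(_finalize_cluster(individual_id, ids, seqs, threshold, depth_limit - 1))
    return out


def cluster_reads(
    reads: Iterable,
    individual_id: str = "",
    max_mismatch_frac: float = 0.02,
    max_gap: int = 6,
    consensus_threshold: float = 0.75,
) -> list[Contig]:
    """Greedy agglomerative clustering of one individual's reads into contigs.

    Identical sequences are grouped first and visited in decreasing group
    size (ties broken lexicographically).  A group joins the cluster whose
    running plurality consensus it matches best, provided the mismatch
    fraction is at most ``max_mismatch_frac`` and no alignment gap run
    exceeds ``max_gap``; otherwise it founds a new cluster.  Clusters whose
    75% consensus contains ambiguous columns are split by those columns, so
    two alleles differing at a single site separate cleanly when both are
    well represented.

    ``reads`` may be strings or objects with ``read_id``/``sequence``.
    Every read ends up in exactly one contig; an empty input yields an empty
    list.
    """
    pairs: list[tuple[str, str]] = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            pairs.append((f"read{i + 1}", r))
        else:
            pairs.append((r.read_id, r.sequence))
    if not pairs:
        return []

    groups: dict[str, list[str]] = {}
    for rid, seq in pairs:
        groups.setdefault(seq, []).append(rid)
    order = sorted(groups, key=lambda s: (-len(groups[s]), s))

    clusters: list[_Cluster] = []
    for seq in order:
        ids = groups[seq]
        best: tuple[float, int, str] | None = None
        for ci, cl in enumerate(clusters):
            cons = cl.consensus_plurality()
            m = _match_to_cluster(seq, cl, cons, max_mismatch_frac, max_gap)
            if m is not None and (best is None or m[0] < best[0]):
                best = (m[0], ci, m[1])
        if best is None:
            cl = _Cluster(seq)
            clusters.append(cl)
            projected = seq
        else:
            _, ci, projected = best
            cl = clusters[ci]
        for rid in ids:
            cl.add(rid, projected)

    contigs: list[Contig] = []
    for cl in clusters:
        contigs.extend(
            _finalize_cluster(individual_id, cl.member_ids, cl.members, consensus_threshold)
        )
    contigs.sort(key=lambda c: (-c.depth, c.consensus))
    return contigs


def flag_chimeras(
    contigs: Sequence[Contig], chimera_depth_frac: float = 0.5
) -> list[bool]:
    """Mark contigs that look like single-crossover PCR artefacts.

    A contig is flagged when (a) its consensus is exactly a single-crossover
    hybrid of two other co-occurring contigs' consensi at some breakpoint and
    (b) its depth is under ``chimera_depth_frac`` times the shallower
    parent's depth — chimeras are clearly under-represented relative to their
    templates.  Flags are also written onto ``contig.is_chimeric``.
    """
    if not contigs:
        raise ValueError("no contigs to screen")
    flags = [False] * len(contigs)
    arrs = [_seq_array(c.consensus) for c in contigs]
    for i, c in enumerate(contigs):
        L = len(c.consensus)
        for j, p1 in enumerate(contigs):
            if j == i or len(p1.consensus) != L or p1.consensus == c.consensus:
                continue
            neq1 = np.nonzero(arrs[i] != arrs[j])[0]
            prefix = int(neq1[0]) if len(neq1) else L
            for k, p2 in enumerate(contigs):
                if k in (i, j) or len(p2.consensus) != L or p2.consensus == c.consensus:
                    continue
                if c.depth >= chimera_depth_frac * min(p1.depth, p2.depth):
                    continue
                neq2 = np.nonzero(arrs[i] != arrs[k])[0]
                suffix = L - 1 - int(neq2[-1]) if len(neq2) else L
                lo = max(1, L - suffix)
                hi = min(prefix, L - 1)
                if lo <= hi:
                    flags[i] = True
                    break
            if flags[i]:
                break
        contigs[i].is_chimeric = flags[i]
    return flags


@dataclass
class CatalogEntry:
    sequence: str
    n_individuals: int
    total_reads: int
    status: str  # confirmed | provisional | rejected_chimera | rejected_lowdepth | nonfunctional_stop


@dataclass
class AlleleCatalog:
    """Validated population-wide allele set with provenance counts."""

    entries: dict[str, CatalogEntry]
    intron_tail_len: int = 7

    def __post_init__(self) -> None:
        seqs = [e.sequence for e in self.entries.values()]
        if len(set(seqs)) != len(seqs):
            raise ValueError("catalog sequences must be unique")

    def accepted(self) -> dict[str, CatalogEntry]:
        ok = {"confirmed", "provisional", "nonfunctional_stop"}
        return {n: e for n, e in self.entries.items() if e.status in ok}

    def sequence_to_name(self) -> dict[str, str]:
        return {e.sequence: n for n, e in self.accepted().items()}

    def functional(self) -> dict[str, CatalogEntry]:
        ok = {"confirmed", "provisional"}
        return {n: e for n, e in self.entries.items() if e.status in ok}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "allele": n,
                    "status": e.status,
                    "n_individuals": e.n_individuals,
                    "total_reads": e.total_reads,
                    "sequence": e.sequence,
                }
                for n, e in self.entries.items()
            ]
        )


def _exon_has_stop(seq: str, intron_tail_len: int) -> bool:
    exon = seq[intron_tail_len:]
    exon = exon[: len(exon) - len(exon) % 3]
    if not exon or set(exon) - set("ACGT"):
        return False
    return "*" in str(Seq(exon).translate())


def build_catalog(
    contigs_by_individual: Mapping[str, Sequence[Contig]],
    min_reads: int = 12,
    singleton_min_frac: float = 0.25,
    min_reads_mode: str = "summed",
    name_prefix: str = "Fuat-DAB*",
    intron_tail_len: int = 7,
) -> AlleleCatalog:
    """Pool identical consensi across individuals and validate alleles.

    Chimera-flagged and ambiguous contigs never nominate alleles.  An allele
    is ``confirmed`` when isolated from >= 2 individuals with >= ``min_reads``
    reads (summed by default; ``min_reads_mode="per_individual"`` demands one
    individual alone reaching the floor), ``provisional`` when found in a
    single individual with >= ``min_reads`` reads at a depth at least
    ``singleton_min_frac`` of the mean depth of its co-occurring contigs, and
    ``rejected_lowdepth`` otherwise.  Sequences whose exon translation
    contains a stop codon are catalogued as ``nonfunctional_stop``.  Names
    are assigned sequentially in order of first detection (individuals in
    input order, contigs by decreasing depth).
    """
    # detection order over candidate sequences
    per_seq: dict[str, dict[str, int]] = {}
    chimera_only: dict[str, dict[str, int]] = {}
    order: list[str] = []
    singleton_frac: dict[str, float] = {}
    for ind, contigs in contigs_by_individual.items():
        usable = [c for c in contigs if not c.is_chimeric and not c.ambiguous_sites]
        for c in sorted(contigs, key=lambda c: (-c.depth, c.consensus)):
            target = per_seq if (not c.is_chimeric and not c.ambiguous_sites) else chimera_only
            if c.consensus not in per_seq and c.consensus not in chimera_only:
                order.append(c.consensus)
            bucket = target.setdefault(c.consensus, {})
            bucket[ind] = bucket.get(ind, 0) + c.depth
        for c in usable:
            others = [o.depth for o in usable if o.consensus != c.consensus]
            frac = c.depth / (sum(others) / len(others)) if others else np.inf
            prev = singleton_frac.get(c.consensus)
            singleton_frac[c.consensus] = max(prev, frac) if prev is not None else frac

    entries: dict[str, CatalogEntry] = {}
    num = 0
    for seq in order:
        num += 1
        name = f"{name_prefix}{num}"
        if seq in per_seq:
            support = per_seq[seq]
            n_ind = len(support)
            total = sum(support.values())
            if n_ind >= 2 and (
                total >= min_reads
                if min_reads_mode == "summed"
                else max(support.values()) >= min_reads
            ):
                status = "confirmed"
            elif (
                n_ind == 1
                and total >= min_reads
                and singleton_frac.get(seq, 0.0) >= singleton_min_frac
            ):
                status = "provisional"
            else:
                status = "rejected_lowdepth"
            if status in ("confirmed", "provisional") and _exon_has_stop(seq, intron_tail_len):
                status = "nonfunctional_stop"
        else:
            support = chimera_only[seq]
            n_ind = len(support)
            total = sum(support.values())
            status = "rejected_chimera"
        entries[name] = CatalogEntry(
            sequence=seq, n_individuals=n_ind, total_reads=total, status=status
        )
    return AlleleCatalog(entries, intron_tail_len=intron_tail_len)


@dataclass
class GenotypeTable:
    """Per-individual allele calls with depths, totals and QC status."""

    rows: dict[str, list[tuple[str, int]]]
    total_reads_map: dict[str, int]
    unmatched: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    qc: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind in self.rows:
            self.qc.setdefault(ind, "pass")
            names = [a for a, _ in self.rows[ind]]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate allele rows for {ind}")

    def total_reads(self, individual_id: str) -> int:
        return self.total_reads_map.get(individual_id, 0)

    def pass_rows(self):
        for ind, alleles in self.rows.items():
            if self.qc.get(ind) == "pass":
                yield ind, alleles

    def allele_count(self, individual_id: str) -> int:
        return len({a for a, _ in self.rows.get(individual_id, [])})

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for ind, alleles in self.rows.items():
            for name, depth in alleles:
                recs.append(
                    {
                        "individual_id": ind,
                        "allele": name,
                        "depth": depth,
                        "qc": self.qc.get(ind, "pass"),
                    }
                )
        return pd.DataFrame(recs, columns=["individual_id", "allele", "depth", "qc"])


def genotype_individuals(
    contigs_by_individual: Mapping[str, Sequence[Contig]],
    catalog: AlleleCatalog,
) -> GenotypeTable:
    """Assign alleles by 100% full-length matches of contig consensi to the catalog.

    Contigs matching no catalogued allele are reported per individual in
    ``unmatched``; a contig one mismatch away from its nearest allele is
    excluded from the genotype, not rescued.
    """
    db = catalog.sequence_to_name()
    rows: dict[str, list[tuple[str, int]]] = {}
    unmatched: dict[str, list[tuple[str, int]]] = {}
    totals: dict[str, int] = {}
    for ind, contigs in contigs_by_individual.items():
        hits: dict[str, int] = {}
        misses: list[tuple[str, int]] = []
        totals[ind] = sum(c.depth for c in contigs)
        for c in contigs:
            name = db.get(c.consensus)
            if name is None:
                misses.append((c.consensus, c.depth))
            else:
                hits[name] = hits.get(name, 0) + c.depth
        rows[ind] = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
        if misses:
            unmatched[ind] = misses
    return GenotypeTable(rows=rows, total_reads_map=totals, unmatched=unmatched)


def qc_individuals(table: GenotypeTable, individual_min_reads: int = 25) -> GenotypeTable:
    """Discard individuals sequenced below ``individual_min_reads`` total reads."""
    for ind in table.rows:
        if table.total_reads(ind) < individual_min_reads:
            table.qc[ind] = "discarded_low_reads"
        else:
            table.qc[ind] = "pass"
    return table


def call_genotypes(
    bins: Mapping[str, Sequence],
    max_mismatch_frac: float = 0.02,
    max_gap: int = 6,
    consensus_threshold: float = 0.75,
    min_reads: int = 12,
    singleton_min_frac: float = 0.25,
    chimera_depth_frac: float = 0.5,
    individual_min_reads: int = 25,
    name_prefix: str = "Fuat-DAB*",
    intron_tail_len: int = 7,
) -> tuple[AlleleCatalog, GenotypeTable, dict[str, list[Contig]]]:
    """Full calling pipeline over demultiplexed per-individual read bins."""
    contigs_by_individual: dict[str, list[Contig]] = {}
    for ind, reads in bins.items():
        contigs = cluster_reads(
            reads,
            individual_id=ind,
            max_mismatch_frac=max_mismatch_frac,
            max_gap=max_gap,
            consensus_threshold=consensus_threshold,
        )
        if contigs:
            flag_chimeras(contigs, chimera_depth_frac=chimera_depth_frac)
            contigs_by_individual[ind] = contigs
    catalog = build_catalog(
        contigs_by_individual,
        min_reads=min_reads,
        singleton_min_frac=singleton_min_frac,
        name_prefix=name_prefix,
        intron_tail_len=intron_tail_len,
    )
    table = genotype_individuals(contigs_by_individual, catalog)
    qc_individuals(table, individual_min_reads=individual_min_reads)
    return catalog, table, contigs_by_individual
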