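"""Barcode demultiplexing: assign reads to individuals and trim tags/primers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .simulate import BarcodeScheme, revcomp

__all__ = ["AmpliconRead", "DemuxResult", "assign_read", "demultiplex_run"]


@dataclass(frozen=True)
class AmpliconRead:
    """One sequencing read: id plus raw (or trimmed) sequence."""

    read_id: str
    sequence: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


_PRIMER_MAX_MISMATCH_FRAC = 0.3  # loose context check, never scored precisely


def _best_tag(
    segment_of_len,
    tags: tuple[str, ...],
    max_mismatch: int,
    primer_of_len=None,
    primer: str | None = None,
) -> int | str:
    """Index of the uniquely best-matching tag, or a rejection reason.

    ``segment_of_len`` maps a tag length to the read segment to compare
    against (tags may have different lengths).  Candidates are tags within
    ``max_mismatch`` substitutions whose following bases loosely match the
    amplification primer — tags of different lengths shift the primer
    window, so the context check stops a tag+primer prefix from impersonating
    a longer foreign tag.  A tie at the minimum distance is ambiguous.
    """
    best_d = None
    best_i: list[int] = []
    for i, tag in enumerate(tags):
        seg = segment_of_len(len(tag))
        if seg is None:
            continue
        d = _hamming(seg, tag)
        if d > max_mismatch:
            continue
        if primer is not None and primer_of_len is not None:
            ctx = primer_of_len(len(tag))
            if ctx is not None:
                frac = _hamming(ctx, primer) / len(primer)
                if frac > _PRIMER_MAX_MISMATCH_FRAC:
                    continue
        if best_d is None or d < best_d:
            best_d, best_i = d, [i]
        elif d == best_d:
            best_i.append(i)
    if best_d is None:
        return "unknown"
    if len(best_i) > 1:
        return "ambiguous"
    return best_i[0]


def assign_read(
    read: AmpliconRead,
    scheme: BarcodeScheme,
    max_tag_mismatch: int = 1,
    fw_primer: str | None = None,
    rv_primer: str | None = None,
) -> tuple[str, int, int] | str:
    """Resolve a read's individual from its forward/reverse tag pair.

    Returns ``(individual_id, fw_index, rv_index)`` or a rejection reason in
    ``{"unknown_fw", "unknown_rv", "unknown_pair", "ambiguous"}``.  With tags
    designed at pairwise distance >= 3, assignment is unambiguous for up to
    one substitution per tag.  When primers are given, candidate tags must
    also be followed by a rough primer match (see :func:`_best_tag`).
    """
    if not scheme.forward_tags or not scheme.reverse_tags:
        raise ValueError("barcode scheme has empty tag lists")
    seq = read.sequence

    fw = _best_tag(
        lambda n: seq[:n] if len(seq) >= n else None,
        scheme.forward_tags,
        max_tag_mismatch,
        primer_of_len=(
            (lambda n: seq[n : n + len(fw_primer)]
             if len(seq) >= n + len(fw_primer) else None)
            if fw_primer
            else None
        ),
        primer=fw_primer,
    )
    if fw == "unknown":
        return "unknown_fw"
    if fw == "ambiguous":
        return "ambiguous"
    # reverse tag appears reverse-complemented at the 3' end
    rv = _best_tag(
        lambda n: revcomp(seq[-n:]) if len(seq) >= n else None,
        scheme.reverse_tags,
        max_tag_mismatch,
        primer_of_len=(
            (lambda n: revcomp(seq[-(n + len(rv_primer)) : -n])
             if len(seq) >= n + len(rv_primer) else None)
            if rv_primer
            else None
        ),
        primer=rv_primer,
    )
    if rv == "unknown":
        return "unknown_rv"
    if rv == "ambiguous":
        return "ambiguous"
    ind = scheme.pairing.get((fw, rv))
    if ind is None:
        return "unknown_pair"
    return ind, fw, rv


@dataclass
class DemuxResult:
    """Partition of a run into per-individual bins plus rejected reads."""

    assigned: dict[str, list[AmpliconRead]] = field(default_factory=dict)
    unassigned: list[tuple[str, str]] = field(default_factory=list)  # (read_id, reason)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + len(self.unassigned)

    def bin_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.assigned.items()}


def demultiplex_run(
    reads,
    scheme: BarcodeScheme,
    fw_primer: str,
    rv_primer: str,
    max_tag_mismatch: int = 1,
) -> DemuxResult:
    """Assign every read to an individual and trim tags plus primers.

    Trimming is by fixed offset after the tag match: ``len(tag) +
    len(primer)`` from each end (primer mismatches are tolerated without
    scoring).  Every input read lands in exactly one bin or in the
    unassigned list.
    """
    result = DemuxResult()
    for rec in reads:
        if isinstance(rec, AmpliconRead):
            read = rec
        else:
            read = AmpliconRead(rec.read_id, rec.sequence)
        outcome = assign_read(read, scheme, max_tag_mismatch, fw_primer, rv_primer)
        if isinstance(outcome, str):
            result.unassigned.append((read.read_id, outcome))
            continue
        ind, fw_i, rv_i = outcome
        lo = len(scheme.forward_tags[fw_i]) + len(fw_primer)
        hi = len(scheme.reverse_tags[rv_i]) + len(rv_primer)
        insert = read.sequence[lo : len(read.sequence) - hi]
        result.assigned.setdefault(ind, []).append(AmpliconRead(read.read_id, insert))
    return result
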