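"""Retrieval of the published allele sequences from GenBank.

The study deposited the validated amplicon alleles under a contiguous
accession range.  These helpers fetch that range over NCBI E-utilities, trim
each record to the 270-nt exon-2 coding region (dropping the 7 leading
intron-1 nucleotides), separate the stop-codon-bearing allele, and recompute
the printed polymorphism statistics on the functional set.  Network access is
required; nothing is cached in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

from .popgen import alignment_stats, collapse_to_protein

DEFAULT_START = "KF924770"
DEFAULT_END = "KF925035"


def accession_range(start: str = DEFAULT_START, end: str = DEFAULT_END) -> list[str]:
    prefix = start[:2]
    lo, hi = int(start[2:]), int(end[2:])
    return [f"{prefix}{i}" for i in range(lo, hi + 1)]


def fetch_genbank_range(
    start: str = DEFAULT_START,
    end: str = DEFAULT_END,
    email: str = "mhctyper@example.org",
    timeout: float = 30.0,
) -> dict[str, str]:
    """Download nucleotide FASTA for an accession range via Entrez efetch."""
    import socket

    from Bio import Entrez, SeqIO

    Entrez.email = email
    ids = ",".join(accession_range(start, end))
    old_timeout = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        with Entrez.efetch(db="nuccore", id=ids, rettype="fasta", retmode="text") as h:
            return {rec.id.split(".")[0]: str(rec.seq).upper() for rec in SeqIO.parse(h, "fasta")}
    finally:
        socket.setdefaulttimeout(old_timeout)


def trim_to_exon2(seq: str, exon_len: int = 270) -> str:
    """Keep the trailing exon-2 coding region of an amplicon sequence."""
    if len(seq) < exon_len:
        raise ValueError(f"sequence shorter than exon length {exon_len}")
    return seq[-exon_len:]


@dataclass
class AccessionReport:
    """Polymorphism summary of the deposited allele set."""

    n_deposited: int
    n_unique_exon2: int
    n_functional: int
    n_protein_classes: int
    stop_alleles: list[str]
    S: int
    eta: int
    pi: float
    k: float
    tajimas_d: float | None


def accession_stats(sequences: dict[str, str], exon_len: int = 270) -> AccessionReport:
    """Recompute the headline polymorphism statistics from deposited sequences.

    Trims to exon 2, deduplicates identical exon sequences, excludes alleles
    whose translation contains a stop codon, and computes S, eta, pi, k and
    Tajima's D on the functional set plus the number of distinct protein
    classes among all unique exon-2 sequences.
    """
    # deduplicate identical exon-2 sequences, keeping the first accession
    unique: dict[str, str] = {}
    seen: set[str] = set()
    for name, seq in sequences.items():
        e = trim_to_exon2(seq, exon_len)
        if e not in seen:
            unique[name] = e
            seen.add(e)
    classes, stops = collapse_to_protein(unique, intron_tail_len=0)
    functional = {n: s for n, s in unique.items() if n not in stops}
    stats = alignment_stats(list(functional.values()))
    return AccessionReport(
        n_deposited=len(sequences),
        n_unique_exon2=len(unique),
        n_functional=len(functional),
        n_protein_classes=len(classes),
        stop_alleles=stops,
        S=stats.S,
        eta=stats.eta,
        pi=stats.pi,
        k=stats.k,
        tajimas_d=stats.tajimas_d,
    )
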