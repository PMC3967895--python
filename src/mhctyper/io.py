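"""File IO: FASTQ/FASTA, truth tables, barcode schemes, genotype tables."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demux import AmpliconRead
from .simulate import BarcodeScheme, SimulatedRead

__all__ = [
    "write_fastq",
    "read_fastq",
    "write_fasta",
    "read_fasta",
    "write_barcode_scheme",
    "read_barcode_scheme",
]

_Q30 = 30  # constant placeholder quality; the pipeline never uses qualities


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [_Q30] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[AmpliconRead]:
    out = []
    for i, rec in enumerate(SeqIO.parse(path, "fastq"), start=1):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"malformed FASTQ record {i}: empty sequence")
        out.append(AmpliconRead(rec.id, seq))
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_barcode_scheme(scheme: BarcodeScheme, path) -> None:
    rows = [
        {"role": "forward", "index": i, "tag": t, "individual_id": ""}
        for i, t in enumerate(scheme.forward_tags)
    ] + [
        {"role": "reverse", "index": i, "tag": t, "individual_id": ""}
        for i, t in enumerate(scheme.reverse_tags)
    ]
    for (fw, rv), ind in scheme.pairing.items():
        rows.append({"role": "pair", "index": f"{fw},{rv}", "tag": "", "individual_id": ind})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_barcode_scheme(path) -> BarcodeScheme:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    fw = [r.tag for r in df.itertuples() if r.role == "forward"]
    rv = [r.tag for r in df.itertuples() if r.role == "reverse"]
    pairing = {}
    for r in df.itertuples():
        if r.role == "pair":
            i, j = (int(x) for x in r.index.split(","))
            pairing[(i, j)] = r.individual_id
    return BarcodeScheme(tuple(fw), tuple(rv), pairing)


def reads_from_simulated(reads: list[SimulatedRead]) -> list[AmpliconRead]:
    return [AmpliconRead(r.read_id, r.sequence) for r in reads]
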