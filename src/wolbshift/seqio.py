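"""Sequence and table I/O helpers (FASTA/FASTQ via Biopython, TSV via pandas)."""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DUMMY_QUALITY = "I"  # Phred 40; the simulator does not model qualities


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{DUMMY_QUALITY * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def fasta_string(records: Iterable[tuple[str, str]]) -> str:
    buf = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records],
        buf,
        "fasta",
    )
    return buf.getvalue()
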