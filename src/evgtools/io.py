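"""FASTA/FASTQ/TSV/PHYLIP helpers shared across the pipeline.

Sequence I/O goes through Biopython; tables through pandas. Sequences are
handled internally as plain upper-case strings keyed by record id.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ (Phred+33) into ``(id, sequence, qualities)`` tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(reads: Iterable[tuple[str, str, list[int]]], path: str | os.PathLike) -> None:
    records = []
    for name, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_square_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a PHYLIP-style square distance/similarity matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(df)}\n")
        for name in df.index:
            row = " ".join(f"{v:.6f}" for v in df.loc[name])
            fh.write(f"{name}  {row}\n")


def read_square_matrix(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        names, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            names.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return pd.DataFrame(rows, index=names, columns=names)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
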