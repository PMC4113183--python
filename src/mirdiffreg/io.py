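"""Tabular and sequence IO helpers.

Count/RPM matrices travel as TSV with row ids in the first column; an
optional ``# mode: ...`` comment line records whether values are raw counts
or RPM and under which normalization. FASTA/FASTQ go through Biopython.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

MODE_PREFIX = "# mode: "


def write_matrix(matrix: pd.DataFrame, path: str | Path, mode: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if mode is not None:
            fh.write(f"{MODE_PREFIX}{mode}\n")
        matrix.to_csv(fh, sep="\t")


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, str | None]:
    """Read a matrix TSV, returning (matrix, mode-or-None)."""
    path = Path(path)
    mode = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(MODE_PREFIX):
            mode = first[len(MODE_PREFIX):].strip()
        else:
            fh.seek(0)
        matrix = pd.read_csv(fh, sep="\t", index_col=0)
    return matrix, mode


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """FASTA entries as (identifier, sequence) with T mapped to U."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    return entries


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq).upper()


def write_fastq(path: str | Path, reads: list[tuple[str, str]], quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs with a constant Phred quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
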