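"""Readers and writers for the pipeline's plain-text formats.

Ct tables, expression tables and rhythm summaries travel as tidy
tab-separated files with exact header names; protein sequences as FASTA.
All readers validate on the way in — malformed rows are reported with their
line number and duplicate measurement keys are rejected rather than
silently collapsed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .conservation import ProteinSeq
from .qpcr import CT_COLUMNS

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "read_fasta",
    "write_fasta",
    "write_tsv",
]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy Ct table (TSV or CSV by extension).

    The header must be exactly ``gene, colony, zt, replicate, ct``.  Raises
    ``ValueError`` with the offending line number for malformed rows and
    names the key for duplicated (gene, colony, zt, replicate) records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if [h.strip() for h in header] != list(CT_COLUMNS):
            raise ValueError(
                f"{path}: header must be exactly {list(CT_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            gene, colony, zt_s, rep_s, ct_s = (c.strip() for c in row)
            try:
                zt = float(zt_s)
                rep = int(rep_s)
                ct = float(ct_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed numeric field in row {row}"
                ) from None
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{path}:{lineno}: non-finite or non-positive ct {ct_s!r}")
            if not (0 <= zt < 48):
                raise ValueError(f"{path}:{lineno}: zt {zt} outside [0, 48)")
            if rep < 1:
                raise ValueError(f"{path}:{lineno}: replicate index must be >= 1")
            rows.append((gene, colony, zt, rep, ct))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=list(CT_COLUMNS))
    dup = df.duplicated(subset=["gene", "colony", "zt", "replicate"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for key (gene={r['gene']}, colony={r['colony']}, "
            f"zt={r['zt']}, replicate={r['replicate']})"
        )
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a Ct table as TSV (or CSV by extension) with the canonical header."""
    path = Path(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df[list(CT_COLUMNS)].to_csv(path, sep=sep, index=False)


def read_fasta(path: str | Path) -> list[ProteinSeq]:
    """Read protein sequences from FASTA.

    Identifiers are the header text up to the first whitespace; residues are
    uppercased and validated (gap characters and non-amino-acid letters are
    rejected by :class:`ProteinSeq`).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    seqs = []
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        seqs.append(ProteinSeq(rec.id, str(rec.seq)))
    return seqs


def write_fasta(seqs: list[ProteinSeq], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write any tidy result table as TSV."""
    df.to_csv(Path(path), sep="\t", index=False)
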