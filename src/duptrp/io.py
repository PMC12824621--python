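"""Readers and writers for the plain-text genomic formats used throughout.

All interval-bearing formats are handled in the BED convention: 0-based,
half-open.  Coordinates printed 1-based inclusive (HGVS-style ``g.start-end``)
are converted on input (``start - 1``) and back on output (``start + 1``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEPTH_COLUMNS = ["chrom", "start", "end", "count"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1",
    "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]
BED_COLUMNS = ["chrom", "start", "end", "name"]


class FormatError(ValueError):
    """A malformed record in an input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def to_one_based(start: int) -> int:
    """Convert a 0-based half-open start to a 1-based inclusive start."""
    return start + 1


def from_one_based(start: int) -> int:
    """Convert a 1-based inclusive start to a 0-based half-open start."""
    return start - 1


# ---------------------------------------------------------------------------
# bedGraph-like binned depth
# ---------------------------------------------------------------------------

def read_depth_bins(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph-like TSV of binned read counts."""
    df = pd.read_csv(path, sep="\t", header=None, names=DEPTH_COLUMNS,
                     dtype={"chrom": str})
    _validate_depth(df)
    return df


def write_depth_bins(df: pd.DataFrame, path: str | Path) -> None:
    df[DEPTH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _validate_depth(df: pd.DataFrame) -> None:
    if len(df) == 0:
        raise FormatError("depth table contains no bins")
    bad = df.index[(df["start"] >= df["end"]) | (df["count"] < 0)]
    if len(bad):
        raise FormatError("empty bin or negative count", line=int(bad[0]) + 1)


# ---------------------------------------------------------------------------
# BEDPE junction evidence
# ---------------------------------------------------------------------------

def read_bedpe(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a 10-column BEDPE file.

    Strand columns 9-10 are required.  In strict mode a malformed row raises
    :class:`FormatError` with its line number; otherwise it is skipped.
    """
    rows: list[list] = []
    text = Path(path).read_text()
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            rows.append(_parse_bedpe_fields(fields))
        except ValueError as exc:
            if strict:
                raise FormatError(str(exc), line=i) from exc
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)


def _parse_bedpe_fields(fields: list[str]) -> list:
    if len(fields) < 10:
        raise ValueError(f"expected 10 BEDPE columns, got {len(fields)}")
    s1, s2 = fields[8], fields[9]
    if s1 not in "+-" or s2 not in "+-":
        raise ValueError(f"invalid strand pair ({s1!r}, {s2!r})")
    score: int | str = fields[7]
    try:
        score = int(fields[7])
    except ValueError:
        pass
    return [
        fields[0], int(fields[1]), int(fields[2]),
        fields[3], int(fields[4]), int(fields[5]),
        fields[6], score, s1, s2,
    ]


def write_bedpe(df: pd.DataFrame, path: str | Path) -> None:
    df[BEDPE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file with at least 3 columns; extra columns are kept."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    ncol = df.shape[1]
    names = BED_COLUMNS[:min(ncol, 4)] + [f"col{i}" for i in range(4, ncol)]
    df.columns = names
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Headered TSV tables (sites, allele observations, expression, cohort, CNV)
# ---------------------------------------------------------------------------

def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)
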