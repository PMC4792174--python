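"""Readers and writers for the pipeline's tab-delimited output formats.

Three documented formats, all tab-delimited with one header row (comment
lines starting with '#' are permitted and used to echo seeds/metadata):

* ``hl.out``       — 14 columns of per-peptide kinetic fits:
                     ID, UniProt, Peptide, DP, z, mi, SS, a, pss, kp, N,
                     k, dk, R2 (fixed order);
* ``hl-data.out``  — 3 columns of per-time-point isotopomer fractions:
                     ID, t, A_0;
* ``intensity.txt``— 8 columns of per-protein relative intensity:
                     UniProt then one column per sampling day
                     (0, 1, 3, 5, 7, 10, 14).

Writing then reading any of these is the identity on the records.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HL_OUT_COLUMNS",
    "HL_DATA_COLUMNS",
    "INTENSITY_DAYS",
    "read_hl_out",
    "write_hl_out",
    "read_hl_data",
    "write_hl_data",
    "read_intensity",
    "write_intensity",
    "read_fasta",
    "write_fasta",
]

HL_OUT_COLUMNS = (
    "ID", "UniProt", "Peptide", "DP", "z", "mi", "SS",
    "a", "pss", "kp", "N", "k", "dk", "R2",
)
_HL_OUT_NUMERIC = ("DP", "z", "mi", "SS", "a", "pss", "kp", "N", "k", "dk", "R2")
HL_DATA_COLUMNS = ("ID", "t", "A_0")
INTENSITY_DAYS = (0, 1, 3, 5, 7, 10, 14)
INTENSITY_COLUMNS = ("UniProt",) + tuple(f"day{d}" for d in INTENSITY_DAYS)


def _read_table(path, columns: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        lines = [
            (i + 1, line.rstrip("\n"))
            for i, line in enumerate(fh)
            if line.strip() and not line.startswith("#")
        ]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header_no, header = lines[0]
    fields = header.split("\t")
    if fields != list(columns):
        raise ValueError(
            f"{path}:{header_no}: expected {len(columns)} columns "
            f"{list(columns)}, found {len(fields)}: {fields}"
        )
    records = []
    for line_no, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(columns):
            raise ValueError(
                f"{path}:{line_no}: expected {len(columns)} columns, "
                f"found {len(cells)}"
            )
        row = dict(zip(columns, cells))
        for col in numeric:
            try:
                row[col] = float(row[col])
            except ValueError as err:
                raise ValueError(
                    f"{path}:{line_no}: non-numeric value {row[col]!r} "
                    f"in column {col}"
                ) from err
        records.append(row)
    df = pd.DataFrame(records, columns=list(columns))
    if df.empty:
        df = pd.DataFrame(columns=list(columns))
    return df


def _write_table(df: pd.DataFrame, path, columns: Sequence[str], comments: Iterable[str] = ()) -> None:
    path = Path(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns for {path.name}: {missing}")
    with open(path, "w") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_format(row[c]) for c in columns) + "\n")


def _format(value) -> str:
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    return str(value)


def read_hl_out(path) -> pd.DataFrame:
    """Read a 14-column per-peptide kinetic-fit table."""
    df = _read_table(path, HL_OUT_COLUMNS, _HL_OUT_NUMERIC)
    for col in ("DP", "z", "mi"):
        df[col] = df[col].astype(int)
    if df["ID"].duplicated().any():
        dupes = df.loc[df["ID"].duplicated(), "ID"].tolist()
        raise ValueError(f"duplicate peptide IDs: {dupes[:5]}")
    return df


def write_hl_out(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    _write_table(df, path, HL_OUT_COLUMNS, comments)


def read_hl_data(path) -> pd.DataFrame:
    """Read a 3-column (ID, t, A_0) isotopomer time-series table."""
    return _read_table(path, HL_DATA_COLUMNS, ("t", "A_0"))


def write_hl_data(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    _write_table(df, path, HL_DATA_COLUMNS, comments)


def read_intensity(path) -> pd.DataFrame:
    """Read an 8-column per-protein relative-intensity table."""
    return _read_table(path, INTENSITY_COLUMNS, INTENSITY_COLUMNS[1:])


def write_intensity(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    _write_table(df, path, INTENSITY_COLUMNS, comments)


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader: accession (first word of header) → sequence."""
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
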