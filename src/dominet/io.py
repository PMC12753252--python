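"""Reading and writing the pipeline's plain-text formats.

Subject tables and result tables are tab-separated; matrices (time series,
connectivity, centrality tables) are delimited text.  Validation errors
report the offending line so malformed inputs fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_subject_table",
    "read_matrix",
    "write_matrix",
    "write_centrality_table",
    "read_region_table",
]

SUBJECT_COLUMNS = ("subject_id", "site", "diagnosis", "age", "sex")
DIAGNOSES = ("HC", "MCI", "AD")


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated subject table.

    Requires columns subject_id, site, diagnosis (HC/MCI/AD), age, sex;
    mmse/moca are optional.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = ~df["diagnosis"].isin(DIAGNOSES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: line {row + 2}: unknown diagnosis "
            f"{df['diagnosis'].iloc[row]!r} (expected one of {DIAGNOSES})"
        )
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{path}: duplicate subject_id {dup!r}")
    return df


def read_matrix(
    path: str | Path, delimiter: str = None, expected_rows: int | None = None
) -> np.ndarray:
    """Read a delimited numeric matrix, reporting the line of any malformed row."""
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            try:
                vals = [float(x) for x in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric entry") from exc
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(
                    f"{path}: line {lineno}: expected {width} columns, got {len(vals)}"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    mat = np.array(rows, dtype=float)
    if expected_rows is not None and mat.shape[0] != expected_rows:
        raise ValueError(
            f"{path}: expected {expected_rows} rows (regions), found {mat.shape[0]}"
        )
    return mat


def write_matrix(path: str | Path, matrix: np.ndarray, delimiter: str = "\t") -> None:
    np.savetxt(path, np.asarray(matrix), delimiter=delimiter)


def write_centrality_table(
    path: str | Path,
    values: np.ndarray,
    subject_ids: list[str],
    region_ids: np.ndarray | None = None,
) -> None:
    """Subjects x regions centrality values as TSV with 1-based region headers."""
    values = np.asarray(values)
    if region_ids is None:
        region_ids = np.arange(1, values.shape[1] + 1)
    df = pd.DataFrame(values, columns=[f"region_{r}" for r in region_ids])
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path, expected_n: int | None = None) -> pd.DataFrame:
    """Region metadata table (id, label, optional network assignment)."""
    df = pd.read_csv(path, sep="\t")
    if "region_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'region_id'")
    if expected_n is not None and len(df) != expected_n:
        raise ValueError(
            f"{path}: region table has {len(df)} rows but the data use "
            f"{expected_n} regions"
        )
    return df
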