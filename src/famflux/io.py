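"""Tabular I/O: TSV count matrices and tables, with located parse errors.

All matrices are families-in-rows TSVs whose first column holds family ids
and whose header row holds genome ids.  Distance matrices are square TSVs
with matching header row and id column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_count_matrix",
    "read_distance_matrix",
    "read_table",
    "write_tsv",
]


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as err:  # tokenizer reports the line itself
        raise ValueError(f"{path}: malformed TSV: {err}") from err


def _to_numeric(df: pd.DataFrame, path, integer: bool) -> pd.DataFrame:
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r} "
            f"(line {r + 2}), column {df.columns[c]!r}"
        )
    if num.isna().to_numpy().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {num.index[r]!r} (line {r + 2}), "
            f"column {num.columns[c]!r}"
        )
    if integer:
        arr = num.to_numpy(dtype=float)
        if not np.all(arr == np.rint(arr)):
            r, c = np.argwhere(arr != np.rint(arr))[0]
            raise ValueError(
                f"{path}: non-integer count {arr[r, c]} at row {num.index[r]!r} "
                f"(line {r + 2}), column {num.columns[c]!r}"
            )
        num = num.astype(np.int64)
    return num


def read_count_matrix(path) -> pd.DataFrame:
    """Read a families x genomes integer count TSV."""
    df = _to_numeric(_read_tsv(path), path, integer=True)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated family or genome ids")
    return df


def read_distance_matrix(path) -> pd.DataFrame:
    """Read a square symmetric distance TSV with matching row/column ids."""
    df = _to_numeric(_read_tsv(path), path, integer=False)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError(f"{path}: not a square matrix with matching ids")
    return df


def read_table(path, columns: list[str] | None = None) -> pd.DataFrame:
    """Read a generic keyed TSV (first column is the id)."""
    df = _read_tsv(path)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_tsv(obj, path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    obj.to_csv(path, sep="\t", index_label=index_label)
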