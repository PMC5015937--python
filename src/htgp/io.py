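"""CSV readers and writers for plot tables, kernels, markers and pedigrees.

All tables are plain UTF-8 CSV with a header row; output files may carry
``#``-prefixed comment lines (config hash, seed) which every reader skips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .relationships import MarkerMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "read_plot_table",
    "write_plot_table",
    "read_relationship_matrix",
    "write_relationship_matrix",
    "read_pedigree",
    "read_markers",
    "write_markers",
    "write_table",
    "config_hash",
]

REQUIRED_PLOT_COLUMNS = [
    "line", "environment", "trial", "replicate", "block", "trait", "value",
]
PLOT_KEY = ["environment", "trial", "replicate", "block", "line", "trait", "date"]


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_plot_table(path) -> pd.DataFrame:
    """Typed long-format plot table; enforces the uniqueness invariant."""
    df = _read_csv(path)
    missing = [c for c in REQUIRED_PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot table missing required columns: {missing}")
    if "date" not in df.columns:
        df["date"] = np.nan
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["replicate"] = df["replicate"].astype(int)
    key = df[PLOT_KEY].astype(str)
    dup = key.duplicated()
    if dup.any():
        rows = df.index[dup][:5].tolist()
        raise ValueError(
            f"duplicate (environment,trial,replicate,block,line,trait,date) keys "
            f"at rows {rows}"
        )
    return df


def _write_with_comments(df: pd.DataFrame, path, comments: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (comments or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def write_plot_table(df: pd.DataFrame, path, comments: dict | None = None) -> None:
    _write_with_comments(df, path, comments)


def write_table(df: pd.DataFrame, path, comments: dict | None = None) -> None:
    _write_with_comments(df, path, comments)


def read_relationship_matrix(path, kind: str = "G") -> RelationshipMatrix:
    """Square labelled kernel; asymmetry beyond 1e-8 is an error."""
    df = _read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    cols = [str(c) for c in df.columns[1:]]
    if cols != ids:
        raise ValueError("kernel row and column labels differ")
    return RelationshipMatrix(ids, vals, kind=kind)


def write_relationship_matrix(
    kernel: RelationshipMatrix, path, comments: dict | None = None
) -> None:
    df = pd.DataFrame(kernel.values, columns=kernel.line_ids)
    df.insert(0, "line", kernel.line_ids)
    _write_with_comments(df, path, comments)


def read_pedigree(path) -> Pedigree:
    df = _read_csv(path)
    missing = {"line", "parent1", "parent2"} - set(df.columns)
    if missing:
        raise ValueError(f"pedigree missing columns: {sorted(missing)}")
    return Pedigree(df)


def read_markers(path) -> MarkerMatrix:
    """Lines x markers call matrix, cells in {-1, 0, 1, NA}."""
    df = _read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    calls = df.iloc[:, 1:].to_numpy(dtype=float)
    return MarkerMatrix(ids, calls, [str(c) for c in df.columns[1:]])


def write_markers(m: MarkerMatrix, path, comments: dict | None = None) -> None:
    df = pd.DataFrame(m.calls, columns=m.marker_ids)
    df.insert(0, "line", m.line_ids)
    _write_with_comments(df, path, comments)
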