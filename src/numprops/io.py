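"""Readers and writers for the pipeline's tabular formats.

Canonical on-disk format is CSV.  Files written by this package carry a
``# key=value`` comment header recording the generating seed and package
version; the readers skip such comments.  An optional reader accepts
trial tables stored as MATLAB ``.mat`` files in the conventional
``alltrial_Dataset*`` schema (column-named variables or a struct array).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior_sim import TRIAL_COLUMNS

__all__ = ["read_trials", "read_table", "write_table", "read_stimlist"]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV with an optional '# key=value' comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")


def read_stimlist(path) -> pd.DataFrame:
    """Read a stimulus-list CSV; empty file columns become empty strings."""
    df = read_table(path)
    for col in ("file_a", "file_b", "file_joint"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def _trials_from_mat(path) -> pd.DataFrame:
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=True)
    lowered = {str(k).upper(): v for k, v in raw.items()
               if not str(k).startswith("__")}
    if set(TRIAL_COLUMNS) <= set(lowered):
        data = {c: np.asarray(lowered[c]).ravel() for c in TRIAL_COLUMNS}
        return pd.DataFrame(data)
    # single struct array with named fields
    for v in lowered.values():
        if hasattr(v, "dtype") and v.dtype.names:
            names = {n.upper(): n for n in v.dtype.names}
            if set(TRIAL_COLUMNS) <= set(names):
                return pd.DataFrame(
                    {c: np.asarray(v[names[c]]).ravel()
                     for c in TRIAL_COLUMNS})
    raise ValueError(f"{path}: no trial variables "
                     f"({', '.join(TRIAL_COLUMNS)}) found in .mat file")


def read_trials(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a trial-level behavior table (CSV or .mat) and validate it.

    Column matching is case-insensitive.  ERR must be coded {0, 1}
    (1 = error, 0 = correct) and GENDER {1, 2} (1 = male, 2 = female).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mat" if path.suffix.lower() == ".mat" else "csv"
    if fmt == "mat":
        df = _trials_from_mat(path)
    elif fmt == "csv":
        df = pd.read_csv(path, comment="#")
        df.columns = [str(c).upper() for c in df.columns]
        for col in TRIAL_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        df = df[TRIAL_COLUMNS]
    else:
        raise ValueError(f"unknown trial format {fmt!r}")
    err = pd.to_numeric(df["ERR"], errors="coerce")
    bad = df.index[~err.isin([0, 1])]
    if len(bad):
        raise ValueError(f"{path}: ERR outside {{0, 1}} at row {bad[0]}")
    df["ERR"] = err.astype(int)
    gender = pd.to_numeric(df["GENDER"], errors="coerce")
    bad = df.index[~gender.isin([1, 2])]
    if len(bad):
        raise ValueError(f"{path}: GENDER outside {{1, 2}} at row {bad[0]}")
    df["GENDER"] = gender.astype(int)
    df["RT"] = pd.to_numeric(df["RT"])
    if (df["RT"] <= 0).any():
        raise ValueError(f"{path}: non-positive RT values present")
    return df
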