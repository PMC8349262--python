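"""Reading sample data from plain-text CSV.

Two layouts are accepted: a single file with columns ``x,y`` (unequal sample
sizes via blank cells) or two one-column files, one sample each.  Values are
decimal reals; a header row is optional.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mle import TwoSampleData

__all__ = ["read_samples", "read_two_files"]


def _read_csv(path: str | Path) -> pd.DataFrame:
    # sniff for a header: if the first row parses as numbers, there is none
    head = pd.read_csv(path, nrows=1, header=None)
    try:
        head.astype(float)
        header = None
    except (ValueError, TypeError):
        header = 0
    return pd.read_csv(path, header=header)


def _column(df: pd.DataFrame, idx: int) -> np.ndarray:
    v = pd.to_numeric(df.iloc[:, idx], errors="raise").dropna().to_numpy(dtype=float)
    return v


def read_samples(path: str | Path) -> TwoSampleData:
    """Read a two-column CSV (x = stress sample, y = strength sample)."""
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (x, y), found {df.shape[1]}")
    return TwoSampleData(_column(df, 0), _column(df, 1))


def read_two_files(x_path: str | Path, y_path: str | Path) -> TwoSampleData:
    """Read the two samples from separate one-column CSV files."""
    dx, dy = _read_csv(x_path), _read_csv(y_path)
    return TwoSampleData(_column(dx, 0), _column(dy, 0))
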