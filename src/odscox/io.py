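"""Readers and writers for the package's CSV/JSON interfaces.

Subject tables are plain CSV with header columns ``family_id,time,status,
covariate`` (extra ``covariate*`` columns are allowed and used as additional
regressors).  Incidence tables are CSV with ``age_low,age_high,rate`` in
events per person-year.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .intervals import IntervalTable

__all__ = ["read_subjects", "write_subjects", "read_rates", "write_fit_result"]

_REQUIRED = ("family_id", "time", "status", "covariate")


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"subject table {path} missing column(s): {missing}")
    t = df["time"].to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        bad = int(np.flatnonzero(~np.isfinite(t) | (t <= 0))[0])
        raise ValueError(f"subject table {path}: invalid time at row {bad}")
    if not df["status"].isin([0, 1]).all():
        bad = int(df.index[~df["status"].isin([0, 1])][0])
        raise ValueError(f"subject table {path}: status must be 0/1 (row {bad})")
    return df


def write_subjects(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_rates(path) -> IntervalTable:
    return IntervalTable.from_csv(path)


def write_fit_result(result, path) -> None:
    """Serialize a FitResult to JSON."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")
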