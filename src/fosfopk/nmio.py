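"""NONMEM-style event-dataset reader/writer.

One comma-delimited table with a header row and a fixed column order.  Row
semantics follow NONMEM conventions: ``EVID`` 0 = observation (``DV`` mg/L,
``MDV`` 0), 1 = dose (zero-order infusion of ``AMT`` mg at ``RATE`` mg/h,
``MDV`` 1), 2 = other event (used here to mark dialysis-session start/stop
through the ``KRTON``/``QD`` columns, which otherwise carry forward).
Missing numeric covariates are empty fields.  Times are hours since first
dose and must be non-decreasing within a subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "validate_dataset"]

COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "CMT",
    "EGFR", "ANUR", "QD", "KRTON", "STUDYB",
    "WT", "HT", "AGE", "SEX", "UO24", "STUDY",
]

def validate_dataset(df: pd.DataFrame) -> None:
    """Raise ValueError (with the offending row index) on malformed rows."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    for idx, row in df.iterrows():
        evid = int(row["EVID"])
        if evid == 1:
            if not row["AMT"] > 0:
                raise ValueError(f"row {idx}: dose row needs AMT > 0")
            if not row["RATE"] > 0:
                raise ValueError(f"row {idx}: dose row needs RATE > 0 (infusion)")
            if int(row["MDV"]) != 1:
                raise ValueError(f"row {idx}: dose row needs MDV = 1")
        elif evid == 0:
            amt = row["AMT"]
            if pd.notna(amt) and amt != 0:
                raise ValueError(f"row {idx}: observation row must have AMT = 0")
            if int(row["MDV"]) == 0 and not row["DV"] >= 0:
                raise ValueError(f"row {idx}: observation needs DV >= 0")
    for sid, g in df.groupby("ID", sort=False):
        t = g["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < -1e-9):
            raise ValueError(f"subject {sid}: times are not non-decreasing")


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write the dataset as comma-delimited text (lossless float roundtrip)."""
    validate_dataset(df)
    df.to_csv(path, index=False, columns=COLUMNS, na_rep="")


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dataset written by :func:`write_dataset`."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise ValueError(f"malformed dataset file {path}: {exc}") from exc
    validate_dataset(df)
    return df
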