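"""Panel CSV input/output.

The on-disk panel format is a plain CSV with one row per subject per wave:

    subject_id,wave,age_group,male,urban,widowed,dead,activity,body,participation,health

``dead`` is 0/1; the four score columns are empty for dead records.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .scoring import DIMENSIONS

PANEL_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "wave",
    "age_group",
    "male",
    "urban",
    "widowed",
    "dead",
    *DIMENSIONS,
)

_DTYPES = {
    "subject_id": str,
    "wave": int,
    "age_group": str,
    "male": int,
    "urban": int,
    "widowed": int,
    "dead": int,
}


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a panel CSV, validating the header and basic column types."""
    df = pd.read_csv(path, dtype={"subject_id": str, "age_group": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"panel file {path} lacks columns: {missing}")
    for col, typ in _DTYPES.items():
        if typ is int:
            df[col] = df[col].astype(int)
    for col in DIMENSIONS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = ~df["dead"].isin((0, 1))
    if bad.any():
        raise ValidationError(f"`dead` must be 0/1; {int(bad.sum())} bad rows")
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a panel CSV at full numeric precision (lossless round-trip)."""
    cols = [c for c in PANEL_COLUMNS if c in panel.columns]
    extra = [c for c in panel.columns if c not in cols]
    panel.loc[:, cols + extra].to_csv(path, index=False)
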