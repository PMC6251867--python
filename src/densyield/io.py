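"""Delimited-text I/O contracts.

All tabular files are comma-delimited UTF-8 with a header row; densities in
plants m⁻², yields in g m⁻² (population role) or g per plant (single-plant
role), relative yields dimensionless.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = ["read_trial_table", "write_table"]

_TRIAL_REQUIRED = ("variety", "density", "yield")


def read_trial_table(path: str | Path, role: str | None = None) -> pd.DataFrame:
    """Read a trial table (``variety,density,yield,role`` + extras).

    ``role`` filters to one response role (``population`` /
    ``single_plant``) when the file stacks both.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRIAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if role is not None:
        if "role" not in df.columns:
            raise ValidationError(f"{path}: no role column to filter on")
        df = df[df["role"] == role].reset_index(drop=True)
        if df.empty:
            raise ValidationError(f"{path}: no records with role={role!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
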