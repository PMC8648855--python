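"""CSV / JSON readers and writers for curves, scalar tables and results.

Functional predictors travel as long-format CSV with columns
``subject_id,t,value``; every subject must be observed at every grid point
(sparse or ragged designs are rejected, not imputed).  Subject alignment
across files is always by explicit ``subject_id``, never by row order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InputError
from .fpca import CurveSet

__all__ = [
    "read_functional_csv",
    "read_functional_table",
    "write_functional_csv",
    "read_scalar_csv",
    "write_band_csv",
    "write_json",
]

FUNCTIONAL_COLUMNS = ("subject_id", "t", "value")


def read_functional_table(path) -> tuple[CurveSet, np.ndarray]:
    """Read a long-format functional CSV into (CurveSet, subject ids).

    Subjects are sorted by ``subject_id``; the grid is the sorted unique
    ``t``.  Raises :class:`InputError` on duplicate ``(subject, t)`` pairs or
    on subjects missing grid points.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FUNCTIONAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    if df.duplicated(subset=["subject_id", "t"]).any():
        dup = df[df.duplicated(subset=["subject_id", "t"])].iloc[0]
        raise InputError(
            f"{path}: duplicate observation for subject "
            f"{dup['subject_id']!r} at t={dup['t']!r}"
        )
    wide = df.pivot(index="subject_id", columns="t", values="value").sort_index()
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()[:5]
        raise InputError(
            f"{path}: ragged grids are not supported; subjects with missing "
            f"grid points include {bad}"
        )
    grid = wide.columns.to_numpy(dtype=float)
    curves = CurveSet(grid, wide.to_numpy(dtype=float))
    return curves, wide.index.to_numpy()


def read_functional_csv(path) -> CurveSet:
    """Read a long-format functional CSV into a :class:`CurveSet`."""
    return read_functional_table(path)[0]


def write_functional_csv(path, curves: CurveSet, subject_ids=None) -> None:
    """Write a CurveSet as long-format ``subject_id,t,value`` CSV."""
    n, g = curves.values.shape
    if subject_ids is None:
        subject_ids = np.arange(n)
    subject_ids = np.asarray(subject_ids)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, g),
            "t": np.tile(curves.grid, n),
            "value": curves.values.ravel(),
        }
    )
    # %.17g keeps write->read round trips bit-exact for float64
    df.to_csv(path, index=False, float_format="%.17g")


def read_scalar_csv(path, require: Optional[list[str]] = None) -> pd.DataFrame:
    """Read a scalar table indexed by ``subject_id``."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise InputError(f"{path}: missing 'subject_id' column")
    if df["subject_id"].duplicated().any():
        raise InputError(f"{path}: duplicate subject_id rows")
    if require:
        missing = [c for c in require if c not in df.columns]
        if missing:
            raise InputError(f"{path}: missing column(s) {missing}")
    return df.set_index("subject_id").sort_index()


def align_subjects(reference_ids: np.ndarray, other_ids: np.ndarray, what: str) -> None:
    """Raise :class:`AlignmentError` listing offenders on any mismatch."""
    ref = set(np.asarray(reference_ids).tolist())
    oth = set(np.asarray(other_ids).tolist())
    if ref != oth:
        only_ref = sorted(ref - oth)[:10]
        only_oth = sorted(oth - ref)[:10]
        raise AlignmentError(
            f"subject mismatch in {what}: missing {only_ref}, unexpected {only_oth}"
        )


def write_band_csv(path, band) -> None:
    """Write a confidence band as ``t,beta_hat,lower,upper`` CSV."""
    pd.DataFrame(
        {
            "t": band.grid,
            "beta_hat": band.beta_hat,
            "lower": band.lower,
            "upper": band.upper,
        }
    ).to_csv(path, index=False)


def write_json(path, payload: dict) -> None:
    """Write a JSON artifact with numpy types coerced to plain Python."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default))
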