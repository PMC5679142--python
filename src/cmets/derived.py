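"""Physiologic measures derived from raw anthropometric and blood-pressure readings.

Unit contracts are explicit: blood pressures in mmHg, weight in kg,
heights and waist circumference in cm.  Heights are stored in cm
throughout the package; the conversion to metres happens only inside
:func:`bmi`.  No rounding is performed here — display rounding belongs to
the report layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mean_arterial_pressure",
    "bmi",
    "waist_height_ratio",
    "add_derived_measures",
]


def mean_arterial_pressure(sbp, dbp):
    """Mean arterial pressure, (SBP - DBP)/3 + DBP, in mmHg.

    Accepts scalars or arrays.  MAP is a strict convex combination of the
    two pressures (weights 1/3 on systolic, 2/3 on diastolic), so
    ``dbp < MAP < sbp`` whenever ``sbp > dbp``.

    Raises
    ------
    ValueError
        If any ``sbp <= dbp`` (inconsistent blood-pressure reading) or
        any pressure is non-positive.
    """
    sbp_a = np.asarray(sbp, dtype=float)
    dbp_a = np.asarray(dbp, dtype=float)
    if np.any(dbp_a <= 0) or np.any(sbp_a <= 0):
        raise ValueError("blood pressures must be strictly positive")
    if np.any(sbp_a <= dbp_a):
        raise ValueError("inconsistent BP reading: SBP must exceed DBP")
    out = (sbp_a - dbp_a) / 3.0 + dbp_a
    return out.item() if np.isscalar(sbp) and np.isscalar(dbp) else out


def bmi(weight, height_cm):
    """Body mass index in kg/m²: weight (kg) divided by squared height (m²).

    ``height_cm`` is in centimetres and converted internally.
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = w / (h / 100.0) ** 2
    return out.item() if np.isscalar(weight) and np.isscalar(height_cm) else out


def waist_height_ratio(wc_cm, height_cm):
    """Waist-to-height ratio (dimensionless); both arguments in cm."""
    wc = np.asarray(wc_cm, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if np.any(wc <= 0) or np.any(h <= 0):
        raise ValueError("waist and height must be strictly positive")
    out = wc / h
    return out.item() if np.isscalar(wc_cm) and np.isscalar(height_cm) else out


def add_derived_measures(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a cohort table with ``map``, ``bmi`` and ``whtr`` columns.

    Expects the subject-table columns ``sbp``, ``dbp``, ``weight``,
    ``height`` and ``wc`` (cm / kg / mmHg as documented in
    :mod:`cmets.synthetic`).  Vectorized; rows are never dropped.
    """
    required = {"sbp", "dbp", "weight", "height", "wc"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    out = cohort.copy()
    out["map"] = mean_arterial_pressure(out["sbp"].to_numpy(), out["dbp"].to_numpy())
    out["bmi"] = bmi(out["weight"].to_numpy(), out["height"].to_numpy())
    out["whtr"] = waist_height_ratio(out["wc"].to_numpy(), out["height"].to_numpy())
    return out
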