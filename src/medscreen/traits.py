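"""Trait-level transformations, filters and effect-size descriptors.

Composite insulin-resistance indices (TyG, TG-to-HDL-C ratio), quantile
winsorization, complete-case and questionnaire-response filtering, averaging
of repeated measurements, Cohen's d and Welch's t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# mmol/L -> mg/dL conversion factors
TG_MMOL_TO_MGDL = 88.57
GLUCOSE_MMOL_TO_MGDL = 18.018


@dataclass(frozen=True)
class TraitSpec:
    """One screened trait: a raw cohort column or a named composite of
    cohort columns, with an optional winsorization fraction (0 = off)."""

    name: str
    kind: str = "raw"  # {"raw", "composite"}
    components: tuple[str, ...] = ()
    units: str = ""
    winsor_fraction: float = 0.0
    composite: str | None = None  # {"tyg", "tg_hdl_ratio"} for kind="composite"

    def __post_init__(self):
        if not 0.0 <= self.winsor_fraction < 0.5:
            raise ValueError("winsorization fraction must lie in [0, 0.5)")
        if self.kind == "composite" and not self.components:
            raise ValueError("composite trait needs component columns")


def compute_tyg(triglycerides, glucose, units: str = "mg/dL"):
    """Triglyceride-glucose index, ``ln(TG[mg/dL] * glucose[mg/dL] / 2)``.

    ``units`` applies to both inputs; mmol/L values are converted to mg/dL
    (TG x 88.57, glucose x 18.018) before the formula.  Non-positive inputs
    yield a missing result (propagating to the complete-case filter).
    """
    tg = np.asarray(triglycerides, dtype=float)
    glu = np.asarray(glucose, dtype=float)
    if units == "mmol/L":
        tg = tg * TG_MMOL_TO_MGDL
        glu = glu * GLUCOSE_MMOL_TO_MGDL
    elif units != "mg/dL":
        raise ValueError(f"unknown units {units!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((tg > 0) & (glu > 0), np.log(np.abs(tg) * np.abs(glu) / 2.0), np.nan)
    return out


def compute_tg_hdl_ratio(triglycerides, hdl_c):
    """Triglycerides over HDL cholesterol (consistent units; unit scale
    cancels).  Zero or negative HDL yields missing."""
    tg = np.asarray(triglycerides, dtype=float)
    hdl = np.asarray(hdl_c, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(hdl > 0, tg / np.where(hdl > 0, hdl, 1.0), np.nan)
    return out


def winsorize(values, lower_fraction: float, upper_fraction: float):
    """Clip values at the given lower/upper quantiles.

    The quantile convention is the nearest order statistic *inside* the
    winsorization band (``method="higher"`` for the lower bound,
    ``method="lower"`` for the upper).  Interpolated (type-7) quantiles look
    natural here but break idempotence: clipped values pile up at the
    bound, which drags a re-computed interpolated quantile further inward,
    so winsorizing twice would keep moving data.  Order-statistic bounds
    are fixed points of the operation.  Missing values pass through and
    output order is preserved.
    """
    for f in (lower_fraction, upper_fraction):
        if not 0.0 <= f < 0.5:
            raise ValueError("winsorization fractions must lie in [0, 0.5)")
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any() or (lower_fraction == 0.0 and upper_fraction == 0.0):
        return x.copy()
    lo = np.quantile(x[finite], lower_fraction, method="higher") if lower_fraction > 0 else -np.inf
    hi = np.quantile(x[finite], 1.0 - upper_fraction, method="lower") if upper_fraction > 0 else np.inf
    out = x.copy()
    out[finite] = np.clip(x[finite], lo, hi)
    return out


def complete_case_filter(cohort: pd.DataFrame, required_columns: list[str]) -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing value in ``required_columns``; returns the
    filtered frame and the removal count (per-column counts are logged)."""
    missing = [c for c in required_columns if c not in cohort.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    mask = cohort[required_columns].notna().all(axis=1)
    n_removed = int((~mask).sum())
    if n_removed:
        per_col = cohort.loc[~mask, required_columns].isna().sum()
        logger.info("complete-case filter removed %d rows (%s)", n_removed,
                    ", ".join(f"{c}: {int(v)}" for c, v in per_col.items() if v))
    out = cohort.loc[mask]
    if out.empty:
        logger.warning("complete-case filter removed every row")
    return out, n_removed


def mediator_response_filter(
    cohort: pd.DataFrame, mediator: str, special_codes
) -> tuple[pd.DataFrame, int]:
    """Remove rows whose mediator value is a special questionnaire response
    code ("do not know" / "prefer not to answer").  Applied before any
    NDE/NIE estimation, never to total-effect runs.  Codes are negative and
    valid activity durations non-negative, so no valid value can collide."""
    codes = np.asarray(list(special_codes), dtype=float)
    assert np.all(codes < 0), "special codes must be negative, disjoint from valid durations"
    mask = cohort[mediator].isin(codes)
    return cohort.loc[~mask.fillna(False)], int(mask.sum())


def average_repeated_measurements(
    long_table: pd.DataFrame,
    subject_col: str = "subject_id",
    value_col: str | None = "value",
    components: list[str] | None = None,
    composite_func=None,
) -> pd.Series:
    """Average repeated measurements to one value per subject.

    For raw traits, pass ``value_col``.  For composite traits, pass the
    component columns plus the composite function: the composite is computed
    per contemporaneous measurement first, then averaged — ``mean(f(t1),
    f(t2))``, not ``f(mean inputs)``.  Subjects with no (valid) measurement
    come back missing.
    """
    if composite_func is not None:
        if not components:
            raise ValueError("composite averaging needs component columns")
        vals = composite_func(*[long_table[c] for c in components])
        series = pd.Series(np.asarray(vals, dtype=float), index=long_table.index)
    else:
        series = long_table[value_col].astype(float)
    return series.groupby(long_table[subject_col]).mean()


def cohens_d(case_values, control_values) -> float:
    """Standardised mean difference with the pooled-SD denominator."""
    x1 = np.asarray(case_values, dtype=float)
    x0 = np.asarray(control_values, dtype=float)
    x1, x0 = x1[np.isfinite(x1)], x0[np.isfinite(x0)]
    n1, n0 = x1.size, x0.size
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 values per group")
    s1, s0 = np.var(x1, ddof=1), np.var(x0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2))
    if pooled == 0.0:
        logger.warning("zero pooled SD; Cohen's d undefined")
        return np.nan
    return float((np.mean(x1) - np.mean(x0)) / pooled)


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float, float]:
    """Welch's unequal-variance t test from summary statistics.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0.0:
        raise ValueError("both groups have zero variance; t undefined")
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def add_composite_columns(cohort: pd.DataFrame, trait_specs: list[TraitSpec], units: str = "mg/dL") -> pd.DataFrame:
    """Materialise composite trait columns (missing whenever any component
    is missing) and apply per-trait winsorization."""
    out = cohort.copy()
    for spec in trait_specs:
        if spec.kind == "composite":
            if spec.composite == "tyg":
                tg, glu = spec.components
                out[spec.name] = compute_tyg(out[tg], out[glu], units=spec.units or units)
            elif spec.composite == "tg_hdl_ratio":
                tg, hdl = spec.components
                out[spec.name] = compute_tg_hdl_ratio(out[tg], out[hdl])
            else:
                raise ValueError(f"unknown composite {spec.composite!r} for trait {spec.name!r}")
        elif spec.name not in out.columns:
            raise KeyError(f"trait column {spec.name!r} not in cohort")
        if spec.winsor_fraction > 0:
            out[spec.name] = winsorize(out[spec.name], spec.winsor_fraction, spec.winsor_fraction)
    return out
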