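"""Phenotype preparation: control-plate normalization and growth rates.

Colony growth on a drug plate mixes the drug response with the strain's
intrinsic growth and plate-position effects.  Both are removed by
regressing drug-plate radii on same-strain control-plate (drug-free)
radii, one ordinary-least-squares fit per plate layout configuration, and
mapping with the residuals.  Maximum growth rates are extracted from
liquid growth curves with a smoothing spline.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .errors import (
    DegenerateRegressionError,
    InsufficientDataError,
    InvalidParameterError,
    MissingControlError,
)

__all__ = [
    "normalize_records",
    "normalize_to_control",
    "fit_max_growth_rate",
    "summarize_replicates",
]


def _layout_fit(drug: pd.DataFrame, control_mean: pd.Series) -> pd.Series:
    """OLS of drug radius on the strain's mean control radius; residuals."""
    x = control_mean.loc[drug["strain"]].to_numpy(dtype=float)
    y = drug["radius"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateRegressionError(
            "control radii are constant within a layout; slope is undefined"
        )
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ coef, index=drug.index)


def normalize_records(
    drug_records: pd.DataFrame,
    control_records: pd.DataFrame,
    layout_pairing: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-record residual growth after control-plate regression.

    Within each layout configuration, drug radii are regressed on the
    same-strain, same-layout mean control radius; the returned table is the
    drug table with a ``residual`` column.  ``layout_pairing`` maps a drug
    layout to the control layout it was pinned against (identity when None).
    """
    if drug_records.empty or control_records.empty:
        raise InsufficientDataError("drug and control tables must be non-empty")
    if drug_records["dose_uM"].nunique() != 1:
        raise InvalidParameterError("normalize one dose at a time")
    pairing = dict(layout_pairing or {})
    out = drug_records.copy()
    out["residual"] = np.nan
    for layout, drug in drug_records.groupby("layout", sort=False):
        ctrl_layout = pairing.get(layout, layout)
        ctrl = control_records[control_records["layout"] == ctrl_layout]
        ctrl_mean = ctrl.groupby("strain")["radius"].mean()
        missing = set(drug["strain"]) - set(ctrl_mean.index)
        if missing:
            raise MissingControlError(missing)
        out.loc[drug.index, "residual"] = _layout_fit(drug, ctrl_mean)
    return out


def normalize_to_control(
    drug_records: pd.DataFrame,
    control_records: pd.DataFrame,
    layout_pairing: Mapping[str, str] | None = None,
) -> pd.Series:
    """Mapping-ready phenotype: per-strain mean residual across layouts.

    Returns a Series indexed by strain in first-appearance order.  Because
    each layout fit includes an intercept, residuals average to ~0 within
    every layout and hence overall.
    """
    rec = normalize_records(drug_records, control_records, layout_pairing)
    order = pd.unique(rec["strain"])
    return rec.groupby("strain", sort=False)["residual"].mean().reindex(order)


def fit_max_growth_rate(
    time_hr: np.ndarray,
    od: np.ndarray,
    smoothing: float | None = None,
    log_od: bool = False,
    grid_points: int = 400,
) -> float:
    """Maximum slope (OD per hour) of a smoothing-spline fit to a growth curve.

    The spline penalty is chosen by generalized cross-validation unless
    ``smoothing`` (the penalty weight, >= 0) is given; the first derivative
    of the fitted curve is maximized over the observed time interval.  With
    ``log_od`` the spline is fitted to log(OD) and the returned value is the
    maximum of dOD/dt reconstructed from the fitted log-curve.
    """
    t = np.asarray(time_hr, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise InvalidParameterError("time and OD must be 1-D and equal length")
    if len(t) < 4:
        raise InsufficientDataError("need >= 4 points for spline fitting")
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("time points must be strictly increasing")
    if np.any(y < 0):
        raise InvalidParameterError("optical density must be >= 0")
    target = np.log(np.clip(y, 1e-9, None)) if log_od else y
    if np.ptp(target) == 0:  # flat curve; GCV would be degenerate
        return 0.0
    lam = None if smoothing is None else float(smoothing)
    spl = make_smoothing_spline(t, target, lam=lam)
    grid = np.linspace(t[0], t[-1], int(grid_points))
    if log_od:
        rate = spl(grid, 1) * np.exp(spl(grid))  # dOD/dt = OD * dlogOD/dt
    else:
        rate = spl(grid, 1)
    return float(np.max(rate))


def summarize_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(strain, dose) replicate mean and sample SD (n-1 denominator).

    A single replicate yields SD = NaN (absent), matching the convention
    that one measurement carries no spread information.
    """
    if records.empty:
        raise InsufficientDataError("empty phenotype table")
    g = records.groupby(["strain", "dose_uM"], sort=False)["radius"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    out.loc[out["n"] == 1, "sd"] = np.nan
    return out
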