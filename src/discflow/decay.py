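"""First-order decay fitting of drainage observations.

The draining column follows ``y = y0 exp(-k t)`` to a good approximation, so
``ln(dr) = -k t + ln(dr0)`` is linear in time. The semilog ordinary
least-squares fit is the primary estimator (R^2 reported in ln space); a
nonlinear least-squares fit in linear space is offered as a cross-check.
Condition-level summaries average k across replicates, and means-based fits
regress ln(height) on the mean elapsed time across replicates at each
graduation, mirroring how drainage plots are usually reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecayFit",
    "FitError",
    "fit_semilog",
    "fit_nonlinear",
    "fit_study",
    "fit_condition_means",
    "summarize_fits",
    "relative_permeability",
]

CONDITION_KEYS = ["membrane", "matrix", "rpm"]


class FitError(RuntimeError):
    """Raised when a decay fit cannot be computed."""


@dataclass(frozen=True)
class DecayFit:
    """A fitted exponential decay.

    ``time_offset`` is the amount subtracted from the raw clock before
    fitting (time is re-origined to the first crossing so that the
    pre-wetting plateau does not bias the fit); ``y0`` is the fitted column
    height at the re-origined t = 0.
    """

    y0: float
    k: float
    r_squared: float
    method: Literal["semilog", "nonlinear"]
    n_points: int
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.k):
            raise ValueError("fitted k must be finite")
        if self.n_points < 2:
            raise ValueError("a decay fit needs at least 2 points")


def _clean(times, heights, drop_plateau: bool = True):
    """Validate, average duplicate timestamps, drop non-positive heights,
    and re-origin time to the first retained point."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(heights, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and heights must be 1-D arrays of equal length")
    ok = np.isfinite(t) & np.isfinite(y)
    if (y[ok] <= 0).any():
        warnings.warn(
            "non-positive column heights excluded from log-space fit",
            stacklevel=3,
        )
        ok &= y > 0
    t, y = t[ok], y[ok]
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    # average duplicate timestamps
    if t.size and np.any(np.diff(t) == 0):
        ut, inv = np.unique(t, return_inverse=True)
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        t, y = ut, uy
    if drop_plateau and t.size:
        # drop leading samples where the column has not yet moved
        moving = np.nonzero(y < y[0] - 1e-15)[0]
        if moving.size and moving[0] > 1:
            first = moving[0] - 1  # keep the last plateau point as onset
            t, y = t[first:], y[first:]
    if t.size < 2:
        raise FitError("fewer than 2 usable points for a decay fit")
    offset = float(t[0])
    return t - offset, y, offset


def _r_squared(resid: np.ndarray, y: np.ndarray) -> float:
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_semilog(times, heights) -> DecayFit:
    """OLS of ln(height) on time; ``k = -slope``, ``y0 = exp(intercept)``.

    R^2 is computed in ln space (the space of the linearized fit).
    """
    t, y, offset = _clean(times, heights)
    ly = np.log(y)
    design = np.column_stack([t, np.ones_like(t)])
    (slope, intercept), *_ = np.linalg.lstsq(design, ly, rcond=None)
    resid = ly - design @ np.array([slope, intercept])
    return DecayFit(
        y0=float(np.exp(intercept)),
        k=-float(slope),
        r_squared=_r_squared(resid, ly),
        method="semilog",
        n_points=int(t.size),
        time_offset=offset,
    )


def fit_nonlinear(times, heights) -> DecayFit:
    """Least squares on ``y = y0 exp(-k t)`` in linear space.

    Initialized from the semilog fit. Raises :class:`FitError` carrying the
    semilog fallback on non-convergence.
    """
    t, y, offset = _clean(times, heights)
    if t.size < 3:
        raise FitError("nonlinear fit needs at least 3 points")
    start = fit_semilog(times, heights)

    def model(tt, y0, k):
        return y0 * np.exp(-k * tt)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[start.y0, start.k], maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger
        err = FitError(f"nonlinear fit did not converge: {exc}")
        err.fallback = start
        raise err from exc
    resid = y - model(t, *popt)
    return DecayFit(
        y0=float(popt[0]),
        k=float(popt[1]),
        r_squared=_r_squared(resid, y),
        method="nonlinear",
        n_points=int(t.size),
        time_offset=offset,
    )


def fit_study(
    table: pd.DataFrame, method: Literal["semilog", "nonlinear"] = "semilog"
) -> pd.DataFrame:
    """One decay fit per replicate of an observation table.

    No-flow replicates are flagged (``no_flow=True``, NaN estimates), not
    fitted. Returns a tidy frame keyed by (membrane, matrix, rpm,
    replicate_id).
    """
    fitter = fit_semilog if method == "semilog" else fit_nonlinear
    recs = []
    for (mem, mat, rpm, rep), grp in table.groupby(
        CONDITION_KEYS + ["replicate_id"], sort=True
    ):
        if grp["no_flow"].any():
            recs.append(
                dict(
                    membrane=mem, matrix=mat, rpm=rpm, replicate_id=rep,
                    method=method, k_per_s=np.nan, y0_m=np.nan,
                    r_squared=np.nan, n_points=0, no_flow=True,
                )
            )
            continue
        fit = fitter(grp["crossing_time_s"], grp["graduation_height_m"])
        recs.append(
            dict(
                membrane=mem, matrix=mat, rpm=rpm, replicate_id=rep,
                method=method, k_per_s=fit.k, y0_m=fit.y0,
                r_squared=fit.r_squared, n_points=fit.n_points, no_flow=False,
            )
        )
    return pd.DataFrame.from_records(recs)


def fit_condition_means(
    table: pd.DataFrame, method: Literal["semilog", "nonlinear"] = "semilog"
) -> pd.DataFrame:
    """One fit per condition to replicate-mean elapsed times per graduation.

    For each (membrane, matrix, rpm), crossing times are averaged across
    replicates at each graduation height, and the decay is fitted to the
    mean times — the primary quantity drainage studies report.
    """
    fitter = fit_semilog if method == "semilog" else fit_nonlinear
    recs = []
    for (mem, mat, rpm), grp in table.groupby(CONDITION_KEYS, sort=True):
        if grp["no_flow"].any():
            recs.append(
                dict(
                    membrane=mem, matrix=mat, rpm=rpm, method=method,
                    k_per_s=np.nan, y0_m=np.nan, r_squared=np.nan,
                    n_points=0, no_flow=True,
                )
            )
            continue
        means = (
            grp.groupby("graduation_height_m")["crossing_time_s"]
            .mean()
            .reset_index()
        )
        fit = fitter(means["crossing_time_s"], means["graduation_height_m"])
        recs.append(
            dict(
                membrane=mem, matrix=mat, rpm=rpm, method=method,
                k_per_s=fit.k, y0_m=fit.y0, r_squared=fit.r_squared,
                n_points=fit.n_points, no_flow=False,
            )
        )
    return pd.DataFrame.from_records(recs)


def summarize_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Group means and standard deviations of k per condition."""
    flowing = fits[~fits["no_flow"]]
    out = (
        flowing.groupby(CONDITION_KEYS)["k_per_s"]
        .agg(mean_k_per_s="mean", sd_k_per_s="std", n="count")
        .reset_index()
    )
    return out


def relative_permeability(
    fits: pd.DataFrame, reference_matrix: str
) -> pd.Series:
    """Estimate per-matrix permeability factors from fitted decay constants.

    Because k is linear in the effective permeability when the membrane
    dominates the series resistance, the ratio of mean k for a matrix to the
    reference matrix's mean k at the same (membrane, rpm) estimates that
    matrix's permeability multiplier. Ratios are averaged across all
    matching (membrane, rpm) conditions.
    """
    summary = summarize_fits(fits)
    ref = summary[summary["matrix"] == reference_matrix].set_index(
        ["membrane", "rpm"]
    )["mean_k_per_s"]
    if ref.empty:
        raise ValueError(f"no conditions found for reference matrix {reference_matrix!r}")
    ratios: dict[str, list[float]] = {}
    for _, row in summary.iterrows():
        key = (row["membrane"], row["rpm"])
        if key not in ref.index or not np.isfinite(row["mean_k_per_s"]):
            continue
        ratios.setdefault(row["matrix"], []).append(
            row["mean_k_per_s"] / ref.loc[key]
        )
    if not ratios:
        raise ValueError("no matching (membrane, rpm) conditions with the reference")
    return pd.Series(
        {m: float(np.mean(v)) for m, v in sorted(ratios.items())},
        name="matrix_factor_estimate",
    )
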