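"""Trend derivation: transform, fit, and filter yearly series.

Every series (wildlife abundance or SDG indicator) is reduced to a single
mean-annual-change trend by the same chain:

1. transform: abundance -> log10 (zeros replaced by a small fraction of the
   series mean); indicators -> log10 after positive-shift when flagged, or a
   positive shift alone when the indicator takes negative values anywhere
   across countries.
2. fit: ordinary least squares for series with fewer than six observations
   (gap years filled by linear interpolation), a penalized cubic regression
   spline with basis dimension ceil(n/2) otherwise, predicted at every
   integer year in the observed span.
3. annual changes: consecutive differences of the yearly (predicted)
   values, clipped to the study window.
4. filter: keep the fit only if R^2 > 0.5 (squared Pearson correlation of
   fitted and observed values) and the series covers at least five years
   inside the window; the mean of the retained annual changes is the trend.

All trends are in log10 units per year for log-transformed series; the
proportional form is 10**x - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .series import AbundanceSeries, IndicatorSeries, StudyWindow, TrendFit
from .spline import NaturalCubicSmoother

REJECT_TOO_FEW_OBS = "too_few_obs"
REJECT_TOO_SHORT = "too_short"
REJECT_LOW_R2 = "low_r2"
REJECT_CONSTANT = "constant_series"
REJECT_NO_OVERLAP = "insufficient_window_overlap"
REJECT_ALL_ZERO = "all_zero_series"


@dataclass(frozen=True)
class TrendParams:
    """Tunable knobs of the trend chain, defaulting to the study's values.

    ``gam_threshold``: observation count at which the spline path takes over
    from the linear path (series with ``n_obs < gam_threshold`` use OLS).
    ``basis_frac``: spline basis dimension as a fraction of ``n_obs``
    (k = ceil(basis_frac * n_obs), floored at 3).
    ``linear_changes_from``: whether linear-path annual changes are read from
    the observed/interpolated series (default) or from the regression line.
    """

    r2_min: float = 0.5
    min_span: int = 5
    gam_threshold: int = 6
    basis_frac: float = 0.5
    linear_changes_from: str = "interpolated"  # or "fitted"
    zero_replacement_frac: float = 0.01
    shift_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.linear_changes_from not in ("interpolated", "fitted"):
            raise ValueError("linear_changes_from must be 'interpolated' or 'fitted'")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def transform_series(
    series: Union[AbundanceSeries, IndicatorSeries],
    *,
    params: TrendParams = TrendParams(),
    cross_country_min: Optional[float] = None,
) -> np.ndarray:
    """Return the transformed value vector for one series.

    Abundance: log10 after replacing exact zeros with
    ``zero_replacement_frac`` times the series mean; an all-zero series is
    rejected.  Indicator: if ``log_required``, log10 after shifting the whole
    series positive when the cross-country minimum is <= 0; otherwise a
    positive shift alone when the cross-country minimum is negative; identity
    otherwise.  ``cross_country_min`` must be the minimum of the indicator's
    values over *all* countries so that every country's series is shifted by
    the same constant; it defaults to this series' own minimum.
    """
    values = np.asarray(series.values, dtype=float)
    if isinstance(series, AbundanceSeries):
        if np.all(values == 0):
            raise ValueError(f"abundance series {series.population_id} is all zero")
        if np.any(values == 0):
            # zeros replaced by a fraction of the mean over all observed values
            replacement = params.zero_replacement_frac * values.mean()
            values = values.copy()
            values[values == 0] = replacement
        return np.log10(values)

    cmin = float(np.min(values)) if cross_country_min is None else float(cross_country_min)
    if series.log_required:
        if cmin <= 0:
            values = values - cmin + params.shift_eps
        return np.log10(values)
    if cmin < 0:
        return values - cmin + params.shift_eps
    return values


def transform_indicator_group(
    group: Sequence[IndicatorSeries], *, params: TrendParams = TrendParams()
) -> List[np.ndarray]:
    """Transform all countries' series of one indicator consistently.

    The positive-shift constant is the minimum value across every country's
    series, so the same shift applies panel-wide.
    """
    codes = {s.indicator_code for s in group}
    if len(codes) > 1:
        raise ValueError(f"mixed indicator codes in one group: {sorted(codes)}")
    cmin = min(min(s.values) for s in group)
    return [transform_series(s, params=params, cross_country_min=cmin) for s in group]


# ---------------------------------------------------------------------------
# trend fitting
# ---------------------------------------------------------------------------

def _r2_fitted_vs_observed(fitted: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson correlation between fitted and observed values.

    Used uniformly for both paths; defined as 0 when either side is
    (numerically) constant, so degenerate flat fits are never retained.
    """
    f = fitted - fitted.mean()
    o = observed - observed.mean()
    denom2 = float(f @ f) * float(o @ o)
    if denom2 <= 0 or not np.isfinite(denom2):
        return 0.0
    r2 = float(f @ o) ** 2 / denom2
    return min(max(r2, 0.0), 1.0)


def fit_trend(
    years: Sequence[int],
    values: Sequence[float],
    window: StudyWindow = StudyWindow(),
    params: TrendParams = TrendParams(),
    series_id: str = "series",
) -> TrendFit:
    """Fit the linear/GAM chain to one transformed yearly series.

    ``values`` must already be on the transformed (e.g. log10) scale.
    Returns a :class:`TrendFit`; never raises for quality failures (those
    are recorded in ``rejection_reason``), but raises for structurally
    invalid input (fewer than two observations, non-increasing years).
    """
    years = np.asarray(years, dtype=int)
    vals = np.asarray(values, dtype=float)
    n = len(years)
    if n < 2:
        raise ValueError("need at least two observations to fit a trend")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in series")

    grid_years = np.arange(years[0], years[-1] + 1)

    if n < params.gam_threshold:
        method = "linear"
        slope, intercept = np.polyfit(years.astype(float), vals, 1)
        # for OLS, r2 = corr(fitted, y)^2 = corr(year, y)^2 (slope 0 -> corr 0);
        # correlating on years directly avoids rounding from slope/intercept
        fitted_obs = years.astype(float) if slope != 0 else np.zeros(n)
        if params.linear_changes_from == "fitted":
            yearly = slope * grid_years + intercept
        else:
            # gap years imputed by linear interpolation between observations
            yearly = np.interp(grid_years, years, vals)
    else:
        method = "gam"
        k = max(3, math.ceil(n * params.basis_frac))
        smoother = NaturalCubicSmoother(n_basis=k).fit(years.astype(float), vals)
        fitted_obs = smoother.fitted_
        yearly = smoother.predict(grid_years)

    r2 = _r2_fitted_vs_observed(fitted_obs, vals)

    changes = {
        int(t): float(yearly[i] - yearly[i - 1])
        for i, t in enumerate(grid_years)
        if i > 0 and window.start + 1 <= t <= window.end
    }
    overlap_span = min(years[-1], window.end) - max(years[0], window.start) + 1

    fit = TrendFit(
        series_id=series_id,
        method=method,
        n_obs=n,
        r_squared=r2,
        annual_changes=changes,
        mean_trend=float(np.mean(list(changes.values()))) if changes else None,
    )
    if overlap_span <= 1 or not changes:
        return replace(fit, retained=False, rejection_reason=REJECT_NO_OVERLAP)
    if overlap_span < params.min_span:
        return replace(fit, retained=False, rejection_reason=REJECT_TOO_SHORT)
    if np.all(vals == vals[0]):
        return replace(fit, retained=False, rejection_reason=REJECT_CONSTANT)
    if not (r2 > params.r2_min):
        return replace(fit, retained=False, rejection_reason=REJECT_LOW_R2)
    return replace(fit, retained=True)


def batch_trends(
    series: Iterable[Tuple[str, Sequence[int], Sequence[float]]],
    window: StudyWindow = StudyWindow(),
    params: TrendParams = TrendParams(),
) -> Tuple[List[TrendFit], pd.DataFrame]:
    """Fit the chain to a batch of transformed series.

    Per-series failures are captured in the audit frame, never raised.
    Returns (fits, audit) where audit has one row per input with the
    retention outcome and machine-readable reason.
    """
    fits: List[TrendFit] = []
    rows = []
    for series_id, years, values in series:
        try:
            fit = fit_trend(years, values, window, params, series_id=series_id)
        except ValueError as err:
            fit = TrendFit(
                series_id=series_id,
                method="none",
                n_obs=len(years),
                r_squared=0.0,
                retained=False,
                rejection_reason=REJECT_TOO_FEW_OBS if len(years) < 2 else str(err),
            )
        fits.append(fit)
        rows.append(
            {
                "series_id": fit.series_id,
                "method": fit.method,
                "n_obs": fit.n_obs,
                "r_squared": fit.r_squared,
                "mean_trend": fit.mean_trend,
                "retained": fit.retained,
                "rejection_reason": fit.rejection_reason or "",
            }
        )
    return fits, pd.DataFrame(
        rows,
        columns=[
            "series_id",
            "method",
            "n_obs",
            "r_squared",
            "mean_trend",
            "retained",
            "rejection_reason",
        ],
    )


# ---------------------------------------------------------------------------
# batch entry points used by the pipeline
# ---------------------------------------------------------------------------

def wildlife_trends(
    populations: Sequence[AbundanceSeries],
    window: StudyWindow = StudyWindow(),
    params: TrendParams = TrendParams(),
) -> Tuple[List[TrendFit], pd.DataFrame]:
    """Transform and fit every abundance series; all-zero series are logged
    as rejections rather than raised."""
    prepared = []
    failed = []
    for s in populations:
        try:
            prepared.append((s.population_id, s.years, transform_series(s, params=params)))
        except ValueError:
            failed.append(
                TrendFit(
                    series_id=s.population_id,
                    method="none",
                    n_obs=len(s.years),
                    r_squared=0.0,
                    retained=False,
                    rejection_reason=REJECT_ALL_ZERO,
                )
            )
    fits, audit = batch_trends(prepared, window, params)
    for f in failed:
        fits.append(f)
        audit = pd.concat(
            [
                audit,
                pd.DataFrame(
                    [
                        {
                            "series_id": f.series_id,
                            "method": f.method,
                            "n_obs": f.n_obs,
                            "r_squared": f.r_squared,
                            "mean_trend": None,
                            "retained": False,
                            "rejection_reason": f.rejection_reason,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return fits, audit


def indicator_trends(
    indicators: Sequence[IndicatorSeries],
    window: StudyWindow = StudyWindow(),
    params: TrendParams = TrendParams(),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Transform (with panel-wide shifts) and fit every indicator series.

    Returns (trend frame, audit frame); the trend frame has one row per
    (country, indicator_code) with the fit summary, retention flag and the
    indicator's invert flag carried through for the orientation stage.
    """
    by_code: Mapping[str, List[IndicatorSeries]] = {}
    for s in indicators:
        by_code.setdefault(s.indicator_code, []).append(s)

    rows = []
    audits = []
    for code in sorted(by_code):
        group = by_code[code]
        transformed = transform_indicator_group(group, params=params)
        batch = [
            (f"{s.country}:{code}", s.years, vals) for s, vals in zip(group, transformed)
        ]
        fits, audit = batch_trends(batch, window, params)
        audits.append(audit)
        for s, fit in zip(group, fits):
            rows.append(
                {
                    "country": s.country,
                    "indicator_code": code,
                    "method": fit.method,
                    "n_obs": fit.n_obs,
                    "r_squared": fit.r_squared,
                    "mean_trend": fit.mean_trend,
                    "retained": fit.retained,
                    "rejection_reason": fit.rejection_reason or "",
                    "invert": s.invert,
                }
            )
    trend_frame = pd.DataFrame(
        rows,
        columns=[
            "country",
            "indicator_code",
            "method",
            "n_obs",
            "r_squared",
            "mean_trend",
            "retained",
            "rejection_reason",
            "invert",
        ],
    )
    audit_frame = (
        pd.concat(audits, ignore_index=True) if audits else pd.DataFrame()
    )
    return trend_frame, audit_frame


def trend_table(fits: Sequence[TrendFit]) -> pd.DataFrame:
    """Flatten TrendFits into the CSV schema used by the pipeline."""
    return pd.DataFrame(
        [
            {
                "series_id": f.series_id,
                "method": f.method,
                "n_obs": f.n_obs,
                "r_squared": f.r_squared,
                "mean_trend": f.mean_trend,
                "retained": f.retained,
                "rejection_reason": f.rejection_reason or "",
            }
            for f in fits
        ],
        columns=[
            "series_id",
            "method",
            "n_obs",
            "r_squared",
            "mean_trend",
            "retained",
            "rejection_reason",
        ],
    )
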