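"""Domain types for yearly time series and their fitted trends.

The analysis consumes two kinds of series: wildlife population abundance
series (one per monitored population, labelled with taxonomy and geography)
and country-level SDG indicator series (one per country x indicator).  Both
are reduced to a single mean-annual-change trend by the trend chain in
:mod:`devwild.trends`, whose output is a :class:`TrendFit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple


@dataclass(frozen=True)
class StudyWindow:
    """Calendar-year window over which annual changes are retained."""

    start: int = 1996
    end: int = 2015

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"study window start {self.start} must precede end {self.end}")


def _check_years_values(years: Tuple[int, ...], values: Tuple[float, ...], *, min_obs: int = 2) -> None:
    if len(years) != len(values):
        raise ValueError("years and values must have equal length")
    if len(years) < min_obs:
        raise ValueError(f"series needs at least {min_obs} observations, got {len(years)}")
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValueError("years must be strictly increasing")


@dataclass(frozen=True)
class AbundanceSeries:
    """One population's yearly abundance observations.

    Values are population counts, densities or proxies for population size;
    they must be non-negative.  A valid series has at least two observations
    and spans at least five calendar years (last - first + 1 >= 5).
    """

    population_id: str
    species: str
    order: str
    region: str
    country: str
    years: Tuple[int, ...]
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        _check_years_values(self.years, self.values)
        if self.span < 5:
            raise ValueError(
                f"abundance series {self.population_id} spans {self.span} years; minimum is 5"
            )
        if any(v < 0 for v in self.values):
            raise ValueError(f"abundance series {self.population_id} has negative values")

    @property
    def span(self) -> int:
        return self.years[-1] - self.years[0] + 1


@dataclass(frozen=True)
class IndicatorSeries:
    """One country's yearly values for one SDG indicator.

    ``log_required`` marks indicators in monetary or population-size units
    that are log-transformed before trend fitting; ``invert`` marks
    indicators whose trend is multiplied by -1 downstream so that greater
    values always signify progress.
    """

    country: str
    indicator_code: str
    years: Tuple[int, ...]
    values: Tuple[float, ...]
    log_required: bool = False
    invert: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        _check_years_values(self.years, self.values)

    @property
    def span(self) -> int:
        return self.years[-1] - self.years[0] + 1


@dataclass
class TrendFit:
    """Fitted trend-chain output for one series.

    ``annual_changes`` maps calendar year ``t`` (within the study window) to
    the change in (predicted) transformed value from year ``t - 1``.
    ``mean_trend`` is the arithmetic mean of those in-window changes; it is
    reported whenever in-window changes exist, but only fits with
    ``retained=True`` (model fit R^2 above threshold and at least five years
    of in-window series length) feed the regression stage.
    """

    series_id: str
    method: str  # "linear" | "gam"
    n_obs: int
    r_squared: float
    annual_changes: Mapping[int, float] = field(default_factory=dict)
    mean_trend: Optional[float] = None
    retained: bool = False
    rejection_reason: Optional[str] = None
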