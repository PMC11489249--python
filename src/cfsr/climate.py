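"""Climate hazard scoring from sea-surface-temperature and chlorophyll-a series.

The hazard magnitude of a climate variable is summarised by an index of
variability

    IV = (mu_FUT - mu_REF) / sigma_REF

the shift of the future-window mean away from the reference-window mean,
in units of the reference window's natural (monthly) variability.  The
standard deviation uses the sample (n-1) convention.  A single IV per
variable is computed for the whole study area; with communities ~50 km
apart the satellite products do not resolve community-level differences.

|IV| is then mapped onto a [0, 1] hazard score through a configurable
piecewise-linear map; a fixture mode passes through externally assessed
scores so downstream stages can run without raw climate data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ClimateSeries:
    """Monthly values of one climate variable (``sst`` or ``chl_a``)."""

    variable: str
    values: pd.Series  # indexed by month-start Timestamp, strictly increasing
    units: str = ""

    def __post_init__(self) -> None:
        idx = self.values.index
        if len(self.values) == 0:
            raise ValueError("climate series is empty")
        if idx.has_duplicates:
            raise ValueError("duplicate months in climate series")
        if not idx.is_monotonic_increasing:
            raise ValueError("climate series time index must be increasing")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("climate series contains non-finite values")


@dataclass(frozen=True)
class IVResult:
    mu_ref: float
    sigma_ref: float
    mu_fut: float

    @property
    def iv(self) -> float:
        return (self.mu_fut - self.mu_ref) / self.sigma_ref


def to_monthly(
    timestamps: Sequence, values: Sequence[float], variable: str, units: str = ""
) -> ClimateSeries:
    """Aggregate dated observations to monthly means.

    Each retained month's value is the arithmetic mean of that month's
    observations; months with no data are simply absent (never
    zero-filled).
    """
    if len(values) == 0:
        raise ValueError("no observations to aggregate")
    s = pd.Series(
        np.asarray(values, dtype=float), index=pd.DatetimeIndex(pd.to_datetime(timestamps))
    )
    monthly = s.groupby(s.index.to_period("M")).mean()
    monthly.index = monthly.index.to_timestamp()
    return ClimateSeries(variable=variable, values=monthly, units=units)


def read_climate_csv(path) -> dict[str, ClimateSeries]:
    """Read a ``date,variable,value`` CSV into monthly series per variable."""
    table = pd.read_csv(path, parse_dates=["date"])
    out = {}
    for name, sub in table.groupby("variable"):
        out[str(name)] = to_monthly(sub["date"], sub["value"], variable=str(name))
    return out


def _window(series: ClimateSeries, years: tuple[int, int]) -> np.ndarray:
    lo, hi = years
    if lo > hi:
        raise ValueError(f"window {years} is not well-ordered")
    mask = (series.values.index.year >= lo) & (series.values.index.year <= hi)
    return series.values.to_numpy(dtype=float)[mask]


def index_of_variability(
    series: ClimateSeries,
    ref_window: tuple[int, int],
    fut_window: tuple[int, int],
) -> IVResult:
    """Compute IV = (mu_FUT - mu_REF) / sigma_REF over two year windows.

    Windows are inclusive year ranges and may share a boundary year (the
    study uses 2001-2011 vs 2011-2021, with 2011 in both).  A constant
    reference window leaves IV undefined and raises.
    """
    ref = _window(series, ref_window)
    fut = _window(series, fut_window)
    if ref.size == 0:
        raise ValueError(f"reference window {ref_window} has no data")
    if fut.size == 0:
        raise ValueError(f"future window {fut_window} has no data")
    sigma = float(np.std(ref, ddof=1)) if ref.size > 1 else 0.0
    if sigma == 0.0:
        raise ValueError("reference window is constant: sigma_REF = 0, IV undefined")
    return IVResult(mu_ref=float(np.mean(ref)), sigma_ref=sigma, mu_fut=float(np.mean(fut)))


#: default |IV| -> score breakpoints: no shift scores 0, a one-sigma shift
#: scores 0.5, and scores saturate at 1 from two sigmas on.
DEFAULT_IV_BREAKPOINTS = ((0.0, 0.0), (1.0, 0.5), (2.0, 1.0))


def iv_to_hazard_score(
    iv: float, breakpoints: Sequence[tuple[float, float]] = DEFAULT_IV_BREAKPOINTS
) -> float:
    """Map |IV| to a hazard score in [0, 1] via a piecewise-linear curve.

    ``breakpoints`` is a sequence of (|iv|, score) knots, monotone
    non-decreasing in both coordinates; beyond the last knot the score
    saturates at the final value.
    """
    xs = [b[0] for b in breakpoints]
    ys = [b[1] for b in breakpoints]
    if sorted(xs) != list(xs) or sorted(ys) != list(ys):
        raise ValueError("breakpoints must be monotone non-decreasing")
    if any(not 0.0 <= y <= 1.0 for y in ys):
        raise ValueError("breakpoint scores must lie in [0,1]")
    return float(np.interp(abs(iv), xs, ys))


def hazard_scores(
    series: Mapping[str, ClimateSeries] | None,
    ref_window: tuple[int, int],
    fut_window: tuple[int, int],
    fixture_scores: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Hazard scores for SST (EH1) and primary productivity (EH2).

    With ``fixture_scores`` given (e.g. externally assessed values such
    as ``{"sst": 0.35, "chl_a": 0.55}``), those pass through unchanged
    and no series are needed; otherwise each variable's IV is computed
    and mapped through the default breakpoint curve.
    """
    if fixture_scores is not None:
        bad = {k: v for k, v in fixture_scores.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"fixture hazard scores outside [0,1]: {bad}")
        return dict(fixture_scores)
    if not series:
        raise ValueError("no climate series and no fixture scores given")
    return {
        name: iv_to_hazard_score(index_of_variability(s, ref_window, fut_window).iv)
        for name, s in series.items()
    }
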