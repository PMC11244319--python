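"""Germination analytics: cumulative curves, threshold crossing, curve fits.

Daily detected seedling counts become cumulative germination percentages
(a germinated seed cannot un-germinate, so transient detection dips are
smoothed with a running maximum; the raw series is kept alongside).  The
day a series first reaches a configurable "desired germination" threshold
(90% by default) summarizes seed-lot quality; a lot whose curve never
reaches the line germinated poorly and gets an explicit not-reached
sentinel rather than an imputed day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth_model import FitSummary, SigmoidParams, fit_sigmoid

#: Sentinel returned when a series never reaches the desired threshold.
NOT_REACHED = None


@dataclass(frozen=True)
class GerminationSeries:
    """Cumulative germination percentage indexed by day after sowing."""

    days: tuple[int, ...]
    germination_pct: tuple[float, ...]  # cumulative (running max), in [0, 100]
    raw_pct: tuple[float, ...]  # as observed, before cumulative smoothing
    n_sown: int
    cultivar: str = ""

    def __post_init__(self) -> None:
        if len(self.days) != len(self.germination_pct):
            raise ValueError("days and germination_pct must have equal length")
        d = np.asarray(self.days)
        if d.size == 0:
            raise ValueError("series must contain at least one measurement")
        if np.any(np.diff(d) <= 0):
            raise ValueError("days must be strictly increasing")
        p = np.asarray(self.germination_pct)
        if np.any(p < 0) or np.any(p > 100):
            raise ValueError("germination percentages must lie in [0, 100]")
        if np.any(np.diff(p) < 0):
            raise ValueError("cumulative germination must be non-decreasing")


def build_series(
    days,
    values,
    n_sown: int,
    cultivar: str = "",
    values_are: str = "count",
) -> GerminationSeries:
    """Build a cumulative germination series from daily measurements.

    ``values`` are germinated-plant counts (``values_are="count"``) or
    percentages (``values_are="percent"``).  Days must be unique; the
    series is sorted by day and each day's value is the running maximum of
    the observed percentages.
    """
    if values_are not in ("count", "percent"):
        raise ValueError(f"values_are must be 'count' or 'percent', got {values_are!r}")
    if n_sown <= 0:
        raise ValueError(f"n_sown must be positive, got {n_sown}")
    days = np.asarray(days)
    values = np.asarray(values, dtype=np.float64)
    if days.size == 0:
        raise ValueError("at least one measurement is required")
    if days.size != values.size:
        raise ValueError("days and values must have equal length")
    uniq, counts = np.unique(days, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1]
        raise ValueError(f"duplicate days in series: {dup.tolist()}")
    order = np.argsort(days)
    days = days[order]
    values = values[order]
    pct = values if values_are == "percent" else 100.0 * values / n_sown
    pct = np.clip(pct, 0.0, 100.0)
    cumulative = np.maximum.accumulate(pct)
    return GerminationSeries(
        days=tuple(int(d) for d in days),
        germination_pct=tuple(float(p) for p in cumulative),
        raw_pct=tuple(float(p) for p in pct),
        n_sown=n_sown,
        cultivar=cultivar,
    )


def days_to_threshold(series: GerminationSeries, threshold_pct: float = 90.0):
    """First observed day with cumulative germination >= threshold (inclusive).

    Returns the NOT_REACHED sentinel (None) when the series never reaches
    the threshold.  The crossing is read off observed whole days; see
    :func:`fitted_crossing_day` for the continuous alternative.
    """
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError(f"threshold_pct must be in (0, 100], got {threshold_pct}")
    for day, pct in zip(series.days, series.germination_pct):
        if pct >= threshold_pct:
            return day
    return NOT_REACHED


def fitted_crossing_day(params: SigmoidParams, threshold_pct: float = 90.0):
    """Continuous day at which a fitted germination curve crosses the threshold.

    Solves a / (1 + exp(-b (x - c))) = threshold for x; NOT_REACHED when
    the fitted asymptote never attains the threshold.
    """
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError(f"threshold_pct must be in (0, 100], got {threshold_pct}")
    if params.a <= threshold_pct:
        return NOT_REACHED
    return float(params.c - np.log(params.a / threshold_pct - 1.0) / params.b)


def fit_germination_curve(
    series: GerminationSeries, seed=None
) -> tuple[SigmoidParams, FitSummary]:
    """Fit the logistic curve to a cumulative germination series.

    The asymptote is constrained to (0, 100] (a percentage cannot exceed
    100).  Requires at least 4 distinct days and some germination; a flat
    series (e.g. 100% from the first day) yields a degenerate-fit flag in
    the summary.
    """
    days = np.asarray(series.days, dtype=np.float64)
    pct = np.asarray(series.germination_pct, dtype=np.float64)
    if days.size < 4:
        raise ValueError(f"need at least 4 distinct days to fit, got {days.size}")
    if pct.max() <= 0:
        raise ValueError("no germination observed: cannot fit a germination curve")
    return fit_sigmoid(
        days,
        pct,
        bounds=((1e-9, 1e-9, -np.inf), (100.0, np.inf, np.inf)),
        seed=seed,
    )
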