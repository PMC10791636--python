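"""Embryo-transfer outcome rates and abortion-time survival analysis.

Rates are reported as half-up-rounded percentages of the activated-embryo
denominator, matching how outcome tables in this field are printed.
Survival uses the Kaplan-Meier product-limit estimator and the standard
(unweighted) log-rank test, both via lifelines; abortion timing is
summarized with a Gaussian kernel density.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

OUTCOME_ORDER = [
    "activated",
    "transferred",
    "implanted",
    "fetuses",
    "live_births",
    "surviving",
]


def check_outcome_table(row: dict[str, int]) -> None:
    """Enforce the monotone chain surviving <= live births <= ... <= activated."""
    present = [k for k in OUTCOME_ORDER if k in row]
    for later, earlier in zip(present[1:], present[:-1]):
        if row[later] > row[earlier]:
            raise ValueError(f"{later} ({row[later]}) exceeds {earlier} ({row[earlier]})")


def rate_pct(numerator: int, denominator: int) -> float:
    """100*k/n rounded half-up to one decimal (the printed-table convention)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class KMCurve:
    times: np.ndarray  # event-time grid (starts at 0)
    survival: np.ndarray  # S(t), non-increasing from 1
    median: float | None  # earliest time with S <= 0.5; None if never reached
    label: str = ""


def km_estimate(times, event_flags=None, label: str = "") -> KMCurve:
    """Product-limit survival estimate; all-censored data yields S == 1."""
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    if event_flags is None:
        event_flags = np.ones_like(times, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=np.asarray(event_flags, dtype=bool), label=label or "KM")
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    return KMCurve(grid, surv, median, label)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Standard (unweighted) log-rank comparison, 1-df chi-square p-value."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(
        times_a,
        times_b,
        event_observed_A=np.asarray(events_a, dtype=bool),
        event_observed_B=np.asarray(events_b, dtype=bool),
    )
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def abortion_density(times, bandwidth: float | str = "silverman", grid: np.ndarray | None = None):
    """Gaussian kernel density of abortion/stillbirth days.

    Returns (grid, density).  The default evaluation grid spans the data
    plus three bandwidths each side so the density integrates to ~1 on it.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2 or np.ptp(times) == 0:
        # degenerate: single support point; return a narrow Gaussian bump
        center = float(times.mean())
        width = max(1.0, 0.01 * max(center, 1.0))
        if grid is None:
            grid = np.linspace(center - 6 * width, center + 6 * width, 512)
        dens = stats.norm.pdf(grid, loc=center, scale=width)
        return grid, dens
    kde = stats.gaussian_kde(times, bw_method=bandwidth)
    if grid is None:
        bw = kde.covariance_factor() * times.std(ddof=1)
        grid = np.linspace(times.min() - 3 * bw, times.max() + 3 * bw, 512)
    return grid, kde(grid)


def events_only(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a gestation table to aborted/stillborn records.

    Survival curves drawn over aborted fetuses only (each aborted fetus one
    unit) use this restriction; live deliveries are censored out entirely.
    """
    return table[table["event"].astype(bool)].reset_index(drop=True)
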