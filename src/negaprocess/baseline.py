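"""Per-dye baseline statistics of negative-control signals.

The baseline of an instrument/kit combination is characterised by the
pooled heights of all negative-control signals of each dye: their count,
mean and sample standard deviation (RFU scale), the mean and SD of their
natural logarithms (the lognormal model), percentiles and the maximum.
Negative controls are also grouped by calendar quarter (S1 = Jan-Mar ...
S4 = Oct-Dec) to track baseline drift over time, and groups (quarters,
laboratories, cycle numbers) are compared with a two-sided Mann-Whitney
rank test whose p-value is banded into the conventional significance
stars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError
from .io import SizingTable

DEFAULT_PERCENTILES = (0.5, 0.95, 0.99)


@dataclass(frozen=True)
class QuarterKey:
    """A calendar quarter: S1=Jan-Mar, S2=Apr-Jun, S3=Jul-Sep, S4=Oct-Dec."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if not 1 <= self.quarter <= 4:
            raise ValidationError(f"quarter must be 1..4, got {self.quarter}")

    @classmethod
    def from_date(cls, d) -> "QuarterKey":
        return cls(year=d.year, quarter=(d.month - 1) // 3 + 1)

    def __str__(self) -> str:
        return f"{self.year}_S{self.quarter}"


@dataclass
class BaselineStats:
    """Summary of pooled negative signals for one dye.

    ``n_samples`` is the number of negative-control injections pooled (the
    n_n entering the t-based threshold formulas), while the mean/SD are
    taken over all pooled signal heights.  ``log_mean``/``log_sd`` are the
    mean and sample SD of the natural log heights; they are NaN when any
    height is non-positive or fewer than one/two signals exist.
    """

    dye: str
    n_signals: int
    n_samples: int
    mean_height: float
    sd_height: float
    log_mean: float
    log_sd: float
    percentiles: dict[float, float] = field(default_factory=dict)
    max_height: float = float("nan")

    @property
    def undefined_mean(self) -> bool:
        return self.n_signals == 0


def pooled_heights(tables: Iterable[SizingTable], dye: str) -> np.ndarray:
    """Concatenate the heights of ``dye`` across all tables."""
    parts = [t.heights(dye) for t in tables]
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def compute_baseline_stats(
    tables: Sequence[SizingTable],
    dye: str,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> BaselineStats:
    """Pool the heights of ``dye`` over all (post-filtering) negative tables.

    A dye with zero signals yields a stats object with ``n_signals = 0``
    and NaN moments (``undefined_mean`` flag) rather than an exception.
    """
    heights = pooled_heights(tables, dye)
    n = len(heights)
    nn = len(tables)
    if n == 0:
        return BaselineStats(dye, 0, nn, math.nan, 0.0, math.nan, 0.0, {}, math.nan)
    mean = float(np.mean(heights))
    sd = float(np.std(heights, ddof=1)) if n > 1 else 0.0
    if np.all(heights > 0):
        logs = np.log(heights)
        log_mean = float(np.mean(logs))
        log_sd = float(np.std(logs, ddof=1)) if n > 1 else 0.0
    else:
        log_mean, log_sd = math.nan, math.nan
    pct = {q: float(np.quantile(heights, q)) for q in percentiles}
    return BaselineStats(
        dye=dye,
        n_signals=n,
        n_samples=nn,
        mean_height=mean,
        sd_height=sd,
        log_mean=log_mean,
        log_sd=log_sd,
        percentiles=pct,
        max_height=float(np.max(heights)),
    )


def group_by_quarter(tables: Iterable[SizingTable]) -> dict[QuarterKey, list[SizingTable]]:
    """Partition tables by the calendar quarter of their run date.

    The partition is total and disjoint; tables without a run date raise a
    :class:`ValidationError` listing the offending sample identifiers.
    """
    tables = list(tables)
    missing = [
        t.records["sample_id"].iloc[0] if len(t) else f"<empty table {i}>"
        for i, t in enumerate(tables)
        if t.run_date is None
    ]
    if missing:
        raise ValidationError(f"tables without run_date: {missing}")
    groups: dict[QuarterKey, list[SizingTable]] = {}
    for t in tables:
        groups.setdefault(QuarterKey.from_date(t.run_date), []).append(t)
    return groups


def star_band(p: float) -> str:
    """Significance stars: **** p<=1e-4, *** <=1e-3, ** <=0.01, * <=0.05, else ns."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


class GroupComparison(NamedTuple):
    statistic: float
    p_value: float
    stars: str


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two groups of values.

    Uses the normal approximation with tie correction (the default for the
    group sizes seen here); returns the U statistic, the p-value and its
    star band.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need at least 2 values per group, got {len(a)} and {len(b)}"
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(float(res.statistic), p, star_band(p))


class LognormalFit(NamedTuple):
    log_mean: float
    log_sd: float
    ks_statistic: float
    ks_pvalue: float


def fit_lognormal(heights: Sequence[float]) -> LognormalFit:
    """Fit the lognormal height model and report a goodness-of-fit statistic.

    The fit is by moments of the log heights (mean and sample SD), which is
    also the maximum-likelihood location/shape up to the SD denominator.
    Goodness of fit is the Kolmogorov-Smirnov statistic of the log heights
    against the fitted normal; because the parameters are estimated from
    the same data the p-value is approximate (slightly anti-conservative).
    """
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise InsufficientDataError("no heights to fit")
    if np.any(h <= 0):
        raise ValidationError("lognormal fit requires strictly positive heights")
    logs = np.log(h)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=1)) if h.size > 1 else 0.0
    if sigma > 0:
        ks = sps.kstest(logs, "norm", args=(mu, sigma))
        return LognormalFit(mu, sigma, float(ks.statistic), float(ks.pvalue))
    return LognormalFit(mu, sigma, 0.0, 1.0)
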