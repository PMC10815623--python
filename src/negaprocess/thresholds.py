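"""Analytical-threshold estimators derived from negative-control baselines.

An analytical threshold (AT) is the minimum peak height (RFU) at and
above which a detected peak is distinguished from baseline noise.  Five
published estimators computed per dye from negative-control signals are
implemented, alongside the conventional static setting (AT_ori, one fixed
RFU value for every dye):

* ``AT1 = Y_n + k * s_{Y,n}`` — mean plus k standard deviations of the
  pooled negative signal heights (k = 3 by convention, ~99.7% one-sided
  coverage under normality).
* ``AT2 = Y_n + t(alpha, nu) * s_{Y,n} / sqrt(n_n)`` — a one-sided upper
  confidence limit on the *mean* negative signal; n_n is the number of
  negative-control injections and nu = n_n - 1.
* ``AT3 = Y_n + t(alpha, nu) * sqrt(1 + 1/n_n) * s_{Y,n}`` — a one-sided
  prediction limit for a future negative signal, correcting for the
  uncertainty of the estimated mean.
* ``AT4`` — the empirical quantile separating 99% of the negative signals
  from the rest (linear interpolation between order statistics).
* ``AT5 = exp(upsilon + k * tau)`` — the lognormal-model analogue of AT1:
  upsilon and tau are the mean and sample SD of the natural-log heights.

Reported thresholds are rounded up to integer RFU (conservative for noise
exclusion); raw real values are available with ``rounding="none"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .baseline import BaselineStats, compute_baseline_stats, pooled_heights
from .errors import InsufficientDataError, ValidationError
from .io import SizingTable
from .kits import KitConfig

METHODS = ("AT_ori", "AT1", "AT2", "AT3", "AT4", "AT5")
CALCULATED_METHODS = METHODS[1:]

#: conventional static analytical threshold (RFU), applied to every dye
DEFAULT_STATIC_AT = 175.0


@dataclass(frozen=True)
class ThresholdParams:
    """Tunable constants of the threshold estimators.

    ``k`` multiplies the (log-)SD in AT1/AT5; ``alpha`` is the one-sided
    t confidence level in AT2/AT3; ``q`` is the AT4 quantile; ``rounding``
    is ``"ceil_int"`` (report integer RFU, rounded up, floored at 1) or
    ``"none"`` (raw real values).
    """

    k: float = 3.0
    alpha: float = 0.99
    q: float = 0.99
    rounding: str = "ceil_int"

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValidationError("k must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.q < 1:
            raise ValidationError("q must be in (0, 1)")
        if self.rounding not in ("none", "ceil_int"):
            raise ValidationError(f"unknown rounding rule {self.rounding!r}")

    def round(self, value: float) -> float:
        if self.rounding == "ceil_int":
            # guard against float dust pushing an exact integer up one
            return float(max(1, math.ceil(round(value, 9))))
        return value


@dataclass(frozen=True)
class ThresholdSet:
    """Per-dye threshold values (RFU) of one method.

    ``flagged`` lists dyes for which the method could not be computed
    (fewer than two negative signals); those dyes are absent from
    ``values``.
    """

    method: str
    values: dict[str, float]
    flagged: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.values.values()):
            raise ValidationError(f"{self.method}: threshold values must be >= 1 RFU")

    def __getitem__(self, dye: str) -> float:
        return self.values[dye]


def _require_signals(stats: BaselineStats, n_min: int = 2) -> None:
    if stats.n_signals < n_min:
        raise InsufficientDataError(
            f"dye {stats.dye}: need >= {n_min} negative signals, have {stats.n_signals}"
        )


def _t_critical(alpha: float, nn: int) -> float:
    if nn < 2:
        raise InsufficientDataError(f"need >= 2 negative injections, have {nn}")
    return float(sps.t.ppf(alpha, nn - 1))


def at1(stats: BaselineStats, params: ThresholdParams = ThresholdParams()) -> float:
    """Mean plus k standard deviations of the pooled negative heights."""
    _require_signals(stats)
    return params.round(stats.mean_height + params.k * stats.sd_height)


def at2(stats: BaselineStats, params: ThresholdParams = ThresholdParams()) -> float:
    """One-sided upper confidence limit on the mean negative signal."""
    _require_signals(stats)
    t = _t_critical(params.alpha, stats.n_samples)
    return params.round(
        stats.mean_height + t * stats.sd_height / math.sqrt(stats.n_samples)
    )


def at3(stats: BaselineStats, params: ThresholdParams = ThresholdParams()) -> float:
    """One-sided prediction limit for a future negative signal."""
    _require_signals(stats)
    t = _t_critical(params.alpha, stats.n_samples)
    return params.round(
        stats.mean_height
        + t * math.sqrt(1.0 + 1.0 / stats.n_samples) * stats.sd_height
    )


def at4(heights: Sequence[float], params: ThresholdParams = ThresholdParams()) -> float:
    """Empirical quantile separating fraction ``q`` of the negative signals."""
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise InsufficientDataError("no negative signals for the quantile threshold")
    return params.round(float(np.quantile(h, params.q, method="linear")))


def at5(stats: BaselineStats, params: ThresholdParams = ThresholdParams()) -> float:
    """Lognormal-model threshold exp(log-mean + k * log-SD)."""
    _require_signals(stats)
    if math.isnan(stats.log_mean) or math.isnan(stats.log_sd):
        raise ValidationError(
            f"dye {stats.dye}: lognormal threshold needs strictly positive heights"
        )
    return params.round(math.exp(stats.log_mean + params.k * stats.log_sd))


def compute_all_thresholds(
    negatives: Sequence[SizingTable],
    kit: KitConfig,
    params: ThresholdParams = ThresholdParams(),
    static_at: float = DEFAULT_STATIC_AT,
) -> list[ThresholdSet]:
    """Compute the six threshold sets from filtered negative-control tables.

    Returns ``[AT_ori, AT1, ..., AT5]``.  AT_ori carries ``static_at`` for
    every analysis dye; the five calculated methods are computed per dye
    from that dye's pooled baseline statistics.  Dyes with fewer than two
    signals are flagged on each calculated set instead of raising.
    """
    estimators = {"AT1": at1, "AT2": at2, "AT3": at3, "AT5": at5}
    values: dict[str, dict[str, float]] = {m: {} for m in CALCULATED_METHODS}
    flagged: dict[str, set[str]] = {m: set() for m in CALCULATED_METHODS}
    for dye in kit.analysis_dyes:
        stats = compute_baseline_stats(negatives, dye)
        heights = pooled_heights(negatives, dye)
        for method in CALCULATED_METHODS:
            try:
                if method == "AT4":
                    if stats.n_signals < 2:
                        raise InsufficientDataError(
                            f"dye {dye}: need >= 2 negative signals"
                        )
                    values[method][dye] = at4(heights, params)
                else:
                    values[method][dye] = estimators[method](stats, params)
            except (InsufficientDataError, ValidationError):
                flagged[method].add(dye)
    sets = [
        ThresholdSet("AT_ori", {d: float(static_at) for d in kit.analysis_dyes})
    ]
    for method in CALCULATED_METHODS:
        sets.append(
            ThresholdSet(method, values[method], frozenset(flagged[method]))
        )
    return sets


def thresholds_frame(sets: Iterable[ThresholdSet], dyes: Sequence[str]):
    """Arrange threshold sets as a methods x dyes table (pandas DataFrame)."""
    import pandas as pd

    rows = {s.method: [s.values.get(d, math.nan) for d in dyes] for s in sets}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(dyes))
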