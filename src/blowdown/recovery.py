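"""Bookkeeping estimates of time to recover pre-disturbance carbon.

Two bounding approaches bracket the recovery time of the landscape mean
aboveground carbon density (ACD):

* the long-term approach divides the carbon loss by the long-term annual
  ACD gain of the intact forest (likely an overestimate, since growth is
  faster right after disturbance), and
* the two-phase approach applies elevated annual gains — estimated from
  plot records of the years following large treefall losses — for an
  initial fast phase, then the long-term gain (likely an underestimate,
  since not all of the landscape recovers fast).

An optional baseline adjustment extrapolates the reference-epoch ACD
forward to the eve of the disturbance using the observed inter-census gain,
which raises the effective loss and lengthens both estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RecoveryScenario",
    "RecoveryEstimate",
    "recovery_time_long_term",
    "recovery_time_two_phase",
    "adjust_baseline",
    "estimate_elevated_gains",
]

#: annual ACD loss (Mg C ha^-1) above which a plot-census interval counts as
#: a large treefall event for the elevated-phase estimator
LARGE_LOSS_THRESHOLD = 11.5


@dataclass
class RecoveryScenario:
    """Inputs of the recovery bookkeeping, all in Mg C ha^-1 (per yr for gains)."""

    acd_loss_mg_c_ha: float
    long_term_gain: float = 0.49
    elevated_gains: tuple[float, ...] = ()
    elevated_years: int = 0
    baseline_adjust_gain: float = 0.74
    baseline_adjust_years: int = 9

    def __post_init__(self) -> None:
        if self.acd_loss_mg_c_ha < 0:
            raise ValueError("acd_loss must be >= 0")
        if self.long_term_gain < 0 or self.baseline_adjust_gain < 0:
            raise ValueError("gains must be >= 0")
        if self.elevated_years < 0:
            raise ValueError("elevated_years must be >= 0")
        if len(self.elevated_gains) != self.elevated_years:
            raise ValueError("elevated_gains length must equal elevated_years")
        if any(g < 0 for g in self.elevated_gains):
            raise ValueError("elevated gains must be >= 0")


@dataclass
class RecoveryEstimate:
    years: int
    exact_years: float   # unrounded time at which cumulative gain reaches the loss


def _round_years(exact: float, loss: float) -> int:
    # integer part of the exact recovery time; any positive loss takes at
    # least one year (a sub-annual deficit is recovered within the first year)
    if loss == 0:
        return 0
    return max(1, int(np.floor(exact)))


def recovery_time_long_term(scenario: RecoveryScenario) -> RecoveryEstimate:
    """Years to recover at the long-term gain: integer part of loss/gain."""
    if scenario.long_term_gain <= 0:
        raise ValueError("long_term_gain must be positive: no recovery at zero gain")
    ratio = scenario.acd_loss_mg_c_ha / scenario.long_term_gain
    return RecoveryEstimate(_round_years(ratio, scenario.acd_loss_mg_c_ha),
                            float(ratio))


def recovery_time_two_phase(scenario: RecoveryScenario) -> RecoveryEstimate:
    """Years to recover with an elevated initial phase then the long-term gain.

    Cumulative gain accrues through the elevated years and then at the
    long-term rate; the reported count is the integer part of the exact
    crossing time, reducing exactly to :func:`recovery_time_long_term` when
    the elevated phase is empty.
    """
    if scenario.long_term_gain <= 0:
        raise ValueError("long_term_gain must be positive: no recovery at zero gain")
    loss = scenario.acd_loss_mg_c_ha
    if loss == 0:
        return RecoveryEstimate(0, 0.0)
    cum = 0.0
    for year, gain in enumerate(scenario.elevated_gains, start=1):
        prev = cum
        cum += gain
        if cum >= loss:
            frac = (loss - prev) / gain if gain > 0 else 0.0
            exact = year - 1 + frac
            return RecoveryEstimate(_round_years(exact, loss), exact)
    remaining = loss - cum
    exact = scenario.elevated_years + remaining / scenario.long_term_gain
    return RecoveryEstimate(_round_years(exact, loss), exact)


def adjust_baseline(scenario: RecoveryScenario) -> RecoveryScenario:
    """Raise the loss by the pre-event growth accrued since the reference map.

    Extrapolating the reference-epoch ACD forward by
    ``baseline_adjust_gain * baseline_adjust_years`` means the disturbance
    is measured against the (higher) eve-of-event carbon stock.
    """
    extra = scenario.baseline_adjust_gain * scenario.baseline_adjust_years
    return replace(scenario, acd_loss_mg_c_ha=scenario.acd_loss_mg_c_ha + extra)


def estimate_elevated_gains(acd_series: np.ndarray, phase_years: int = 5,
                            loss_threshold: float = LARGE_LOSS_THRESHOLD
                            ) -> np.ndarray:
    """Per-year mean ACD gains following large annual losses in a census series.

    ``acd_series`` is an annual sequence of (plot-mean) ACD.  Census
    intervals with a loss exceeding ``loss_threshold`` Mg C ha^-1 mark
    disturbance events; for each event the gains of the following
    ``phase_years`` years are collected, and the mean gain per
    post-event-year index is returned (length ``phase_years``).
    """
    acd = np.asarray(acd_series, dtype=float)
    if acd.ndim != 1 or acd.size < 3:
        raise ValueError("acd_series must be a 1-D annual series of length >= 3")
    diff = np.diff(acd)
    events = np.flatnonzero(diff < -loss_threshold)
    if events.size == 0:
        raise ValueError(
            f"no census interval with annual loss > {loss_threshold} Mg C ha^-1"
        )
    collected: list[list[float]] = [[] for _ in range(phase_years)]
    for e in events:
        for i in range(phase_years):
            j = e + 1 + i
            if j < diff.size:
                collected[i].append(diff[j])
    gains = np.array([np.mean(c) if c else np.nan for c in collected])
    if np.isnan(gains).any():
        # events near the series end: pad with the last observed phase mean
        last = gains[~np.isnan(gains)][-1] if (~np.isnan(gains)).any() else 0.0
        gains = np.where(np.isnan(gains), last, gains)
    return np.clip(gains, 0.0, None)
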