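"""Exponential-decay fitting of variance traces and resistance calls.

After insecticide addition at onset time T, per-well pixel variance falls
from its pre-exposure plateau toward a baseline:

    V(t) = A + B                      for t <  T
    V(t) = A + B * exp(-k * (t - T))  for t >= T

A is the baseline (noise) variance, B the maximum variance contributed by
moving larvae, and k (= 1/tau, in s^-1) the decay rate. Susceptible larvae
are paralysed quickly (large k); resistant larvae keep moving (small k), so
fitted rates discriminate the two: groups are compared by a one-tailed
pooled-variance (Student) t-test of H1: mean k(susceptible) > mean
k(resistant), and single wells are called against a rate threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .streaming import VarianceTimeSeries

__all__ = [
    "DecayFit",
    "GroupComparison",
    "decay_model",
    "fit_decay",
    "compare_decay_rates",
    "classify_strain",
    "log_midpoint_threshold",
]

_FIT_TOL = 1e-12
#: Series whose total range is below this fraction of their magnitude carry
#: no decay signal; k is unidentifiable and the fit is returned unconverged.
_FLAT_REL_RANGE = 1e-9


@dataclass
class DecayFit:
    """Fitted plateau-then-exponential-decay parameters for one well."""

    baseline_a: float
    amplitude_b: float
    rate_k: float
    onset_t: float
    rss: float
    converged: bool

    @property
    def tau_s(self) -> float:
        """Decay time constant 1/k (inf when k = 0)."""
        return math.inf if self.rate_k == 0 else 1.0 / self.rate_k


@dataclass
class GroupComparison:
    """One-tailed unpaired t-test of decay rates, susceptible vs resistant."""

    rates_1: list[float]
    rates_2: list[float]
    t_stat: float
    df: int
    p_one_tailed: float


def decay_model(t, baseline_a: float, amplitude_b: float, rate_k: float, onset_t: float):
    """Plateau A + B before onset, exponential decay toward A after."""
    t = np.asarray(t, dtype=float)
    out = baseline_a + amplitude_b * np.exp(-rate_k * np.clip(t - onset_t, 0.0, None))
    return float(out) if out.ndim == 0 else out


def _init_decay(
    times: np.ndarray, values: np.ndarray, onset_fixed: float | None
) -> tuple[float, float, float, float]:
    a0 = float(values.min())
    b0 = float(values.max() - values.min())
    if onset_fixed is not None:
        t0 = float(onset_fixed)
    else:
        # end of plateau: last time the trace is still within 5% of the top
        high = values >= a0 + 0.95 * b0
        t0 = float(times[np.nonzero(high)[0][-1]]) if high.any() else float(times[0])
    # log-linear slope of the post-onset tail seeds k
    tail = (times >= t0) & (values - a0 > 0.02 * b0)
    k0 = 1.0 / max(times[-1] - t0, 1e-9)
    if tail.sum() >= 3:
        slope, _ = np.polyfit(times[tail], np.log(values[tail] - a0), 1)
        if slope < 0:
            k0 = -float(slope)
    return a0, b0, k0, t0


def fit_decay(
    series: VarianceTimeSeries, onset_fixed: float | None = None
) -> DecayFit:
    """Least-squares fit of the decay model to one variance trace.

    Requires >= 6 points with ascending times. When ``onset_fixed`` is given
    (e.g. the known compound-addition time), T is held there; otherwise it is
    estimated. A flat trace (range ~ 0) yields ``converged = False`` with
    amplitude ~ 0, since k is then unidentifiable.
    """
    times = np.asarray(series.times_s, dtype=float)
    values = np.asarray(series.values, dtype=float)
    if times.size < 6:
        raise ValueError(f"need at least 6 points to fit a decay, got {times.size}")

    vrange = float(values.max() - values.min())
    if vrange <= _FLAT_REL_RANGE * max(abs(values).max(), 1.0):
        return DecayFit(
            baseline_a=float(values.mean()),
            amplitude_b=0.0,
            rate_k=0.0,
            onset_t=float(onset_fixed) if onset_fixed is not None else float(times[0]),
            rss=float(((values - values.mean()) ** 2).sum()),
            converged=False,
        )

    a0, b0, k0, t0 = _init_decay(times, values, onset_fixed)

    if onset_fixed is None:

        def residuals(p):
            return decay_model(times, p[0], p[1], p[2], p[3]) - values

        x0 = np.array([a0, b0, k0, t0])
        lo = np.array([-np.inf, 0.0, 0.0, times[0] - (times[-1] - times[0])])
        hi = np.array([np.inf, np.inf, np.inf, times[-1]])
    else:

        def residuals(p):
            return decay_model(times, p[0], p[1], p[2], onset_fixed) - values

        x0 = np.array([a0, b0, k0])
        lo = np.array([-np.inf, 0.0, 0.0])
        hi = np.array([np.inf, np.inf, np.inf])

    result = least_squares(
        residuals, x0, bounds=(lo, hi), ftol=_FIT_TOL, xtol=_FIT_TOL, gtol=_FIT_TOL
    )
    p = result.x
    onset = float(onset_fixed) if onset_fixed is not None else float(p[3])
    return DecayFit(
        baseline_a=float(p[0]),
        amplitude_b=float(p[1]),
        rate_k=float(p[2]),
        onset_t=onset,
        rss=float(2.0 * result.cost),
        converged=bool(result.success),
    )


def compare_decay_rates(
    group_susceptible: Sequence[float], group_resistant: Sequence[float]
) -> GroupComparison:
    """One-tailed unpaired pooled-variance t-test on fitted decay rates.

    Tests H1: mean k(susceptible) > mean k(resistant), with
    df = n1 + n2 - 2 (so two groups of 3 give df = 4). Degenerate inputs
    (zero pooled variance) return t = 0, p = 0.5 for equal means, or p -> 0
    with a warning for unequal means.
    """
    g1 = np.asarray(group_susceptible, dtype=float)
    g2 = np.asarray(group_resistant, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 decay rates")
    df = int(g1.size + g2.size - 2)
    pooled_ss = float(((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum())
    if pooled_ss == 0.0:
        if g1.mean() == g2.mean():
            t_stat, p = 0.0, 0.5
        else:
            warnings.warn("zero pooled variance with unequal means: p -> 0 or 1")
            t_stat = math.inf if g1.mean() > g2.mean() else -math.inf
            p = 0.0 if g1.mean() > g2.mean() else 1.0
    else:
        result = stats.ttest_ind(g1, g2, equal_var=True, alternative="greater")
        t_stat, p = float(result.statistic), float(result.pvalue)
    return GroupComparison(
        rates_1=list(map(float, g1)),
        rates_2=list(map(float, g2)),
        t_stat=t_stat,
        df=df,
        p_one_tailed=p,
    )


def classify_strain(
    fit: DecayFit, k_threshold: float
) -> Literal["susceptible", "resistant", "indeterminate"]:
    """Call a well susceptible (k > threshold: fast paralysis) or resistant.

    Unconverged fits and near-zero amplitudes (no larval signal) are
    indeterminate; k exactly at the threshold is also indeterminate rather
    than forcing an arbitrary side.
    """
    if k_threshold <= 0:
        raise ValueError("k_threshold must be positive")
    if not fit.converged or fit.amplitude_b <= 0:
        return "indeterminate"
    if fit.rate_k > k_threshold:
        return "susceptible"
    if fit.rate_k < k_threshold:
        return "resistant"
    return "indeterminate"


def log_midpoint_threshold(k_susceptible_ref: float, k_resistant_ref: float) -> float:
    """Geometric-mean rate threshold between two reference strains.

    Supports relative classification against a characterised sensitive
    reference when no absolute field threshold is available.
    """
    if k_susceptible_ref <= 0 or k_resistant_ref <= 0:
        raise ValueError("reference rates must be positive")
    return math.sqrt(k_susceptible_ref * k_resistant_ref)
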