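"""Concentration-response fitting: pIC50 / logLC50 estimation.

The normalized movement index M is fitted against concentration with the
two-parameter log-logistic (Hill) curve

    M(C) = 1 / (1 + 10^((C - I) * H))

where C and I are log10 molar concentration and log10 IC50 and H > 0 is the
Hill slope, so M falls from 1 to 0 with dose and M = 0.5 exactly at C = I.
The pIC50 is -I. Mortality data (dead fraction D) are fitted with the rising
mirror curve D = 1 - M, whose midpoint is the LC50; the reported logLC50
follows the same -log10 convention as the pIC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponsePoint",
    "SigmoidFit",
    "predict_sigmoid",
    "fit_sigmoid",
    "fit_mortality",
    "pic50_from_molar",
    "inhibition_ratio",
]

#: Responses whose total range is below this are considered flat (no dose
#: effect resolvable; the fit is returned unconverged).
FLAT_RESPONSE_RANGE = 0.1

_FIT_TOL = 1e-10
_SLOPE_MAX = 20.0


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (concentration, response) observation.

    ``response`` is a baseline-normalized movement index (typically in
    [0, ~1.5]; values above 1 are tolerated) or a mortality fraction in [0, 1].
    """

    concentration_molar: float
    response: float

    def __post_init__(self) -> None:
        if not self.concentration_molar > 0:
            raise ValueError("concentration must be positive")
        if not math.isfinite(self.response):
            raise ValueError("response must be finite")

    @property
    def log_concentration(self) -> float:
        return math.log10(self.concentration_molar)


@dataclass
class SigmoidFit:
    """Least-squares estimates of the curve midpoint and slope.

    ``log_ic50`` is on the log10 molar axis; ``pic50`` is its negation by
    construction. ``converged`` is False for degenerate (flat) input or
    optimizer failure, and such fits should not feed ratio computations.
    """

    log_ic50: float
    slope: float
    rss: float
    converged: bool
    n_points: int

    @property
    def pic50(self) -> float:
        return -self.log_ic50


def predict_sigmoid(log_conc, log_ic50: float, slope: float):
    """Normalized movement predicted at log10 concentration ``log_conc``.

    Vectorized over ``log_conc``. Strictly decreasing in concentration for
    slope > 0 and equal to 0.5 at the midpoint.
    """
    log_conc = np.asarray(log_conc, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** ((log_conc - log_ic50) * slope))
    return float(out) if out.ndim == 0 else out


def _validate_points(points: Sequence[DoseResponsePoint]) -> tuple[np.ndarray, np.ndarray]:
    if len(points) < 4:
        raise ValueError(f"need at least 4 dose-response points, got {len(points)}")
    log_c = np.array([p.log_concentration for p in points])
    resp = np.array([p.response for p in points])
    if np.unique(log_c).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    return log_c, resp


def _fit(log_c: np.ndarray, resp: np.ndarray, rising: bool) -> SigmoidFit:
    flat = resp.max() - resp.min() < FLAT_RESPONSE_RANGE

    def model(params: np.ndarray) -> np.ndarray:
        pred = predict_sigmoid(log_c, params[0], params[1])
        return (1.0 - pred) if rising else pred

    def residuals(params: np.ndarray) -> np.ndarray:
        return model(params) - resp

    # start at the concentration whose response is nearest the half-maximum
    target = 0.5
    i0 = log_c[np.argmin(np.abs(resp - target))]
    x0 = np.array([i0, 1.0])
    lo = np.array([log_c.min() - 3.0, 1e-6])
    hi = np.array([log_c.max() + 3.0, _SLOPE_MAX])
    result = least_squares(
        residuals, x0, bounds=(lo, hi), ftol=_FIT_TOL, xtol=_FIT_TOL, gtol=_FIT_TOL
    )
    # a curve that is effectively flat across the tested window supports no
    # potency claim (midpoint outside the tested range / no dose effect)
    pred = model(result.x)
    flat_fit = float(pred.max() - pred.min()) < FLAT_RESPONSE_RANGE
    converged = bool(result.success) and not flat and not flat_fit
    if flat or flat_fit:
        import warnings

        what = "response" if flat else "fitted curve"
        warnings.warn(
            f"flat {what} (range < {FLAT_RESPONSE_RANGE}) over the tested "
            "concentrations: midpoint unidentifiable",
            stacklevel=3,
        )
    return SigmoidFit(
        log_ic50=float(result.x[0]),
        slope=float(result.x[1]),
        rss=float(2.0 * result.cost),
        converged=converged,
        n_points=int(log_c.size),
    )


def fit_sigmoid(points: Sequence[DoseResponsePoint]) -> SigmoidFit:
    """Fit the falling movement curve M(C) by bounded least squares.

    Requires >= 4 points over >= 2 distinct concentrations. Undefined
    (NaN-flagged) responses must be removed by the caller; flat responses
    yield ``converged = False``.
    """
    log_c, resp = _validate_points(points)
    return _fit(log_c, resp, rising=False)


def fit_mortality(points: Sequence[DoseResponsePoint]) -> SigmoidFit:
    """Fit mortality fractions with the rising curve D = 1 - M(C).

    Algebraically identical to :func:`fit_sigmoid` applied to 1 - D, so the
    recovered (midpoint, slope) agree between the two routes; the midpoint is
    the logLC50 and ``pic50`` holds its -log10-convention value.
    """
    log_c, resp = _validate_points(points)
    return _fit(log_c, resp, rising=True)


def pic50_from_molar(ic50_molar: float) -> float:
    """pIC50 (or logLC50) = -log10 of a molar IC50/LC50.

    100 nM -> 7.0; 2.5 nM -> 8.60; 1 M -> 0.0.
    """
    if not ic50_molar > 0:
        raise ValueError("IC50 must be a positive molar concentration")
    return -math.log10(ic50_molar)


def inhibition_ratio(fit_resistant: SigmoidFit, fit_susceptible: SigmoidFit) -> float:
    """IC50(resistant) / IC50(susceptible); > 1 means the resistant strain
    needs more compound for the same inhibition."""
    for fit in (fit_resistant, fit_susceptible):
        if not fit.converged:
            raise ValueError("inhibition ratio requires converged fits")
    return 10.0 ** (fit_resistant.log_ic50 - fit_susceptible.log_ic50)
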