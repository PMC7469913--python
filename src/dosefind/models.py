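"""Dose-toxicity model families and skeleton calibration.

A phase I design works on *standardized doses* ``x_1 < ... < x_K`` rather
than on the raw administered doses.  For the one-parameter empiric (power)
model the standardized dose of a level is simply its prior DLT probability;
for logistic families the working dose is recovered from the skeleton by
inverting the model at the prior parameter value.

The skeleton itself is built by the indifference-interval construction:
starting from the prior-MTD level, whose probability is anchored at the
target toxicity ``theta``, neighbouring levels are placed so that adjacent
doses are separated by exactly one indifference interval
``[theta - delta, theta + delta]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "DoseGrid",
    "Skeleton",
    "ModelSpec",
    "dlt_probability",
    "calibrate_skeleton",
    "standardized_doses",
]

_FAMILIES = ("empiric", "logistic1", "logistic2")


@dataclass(frozen=True)
class ModelSpec:
    """Dose-toxicity model family.

    ``empiric``:   psi(x, a)  = x ** exp(a),            x in (0, 1)
    ``logistic1``: psi(x, a)  = expit(b + exp(a) * x),  fixed intercept b
    ``logistic2``: psi(x, a0, a1) = expit(a0 + a1 * x), slope a1 > 0
    """

    family: str = "empiric"
    fixed_intercept: float = 3.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def n_params(self) -> int:
        return 2 if self.family == "logistic2" else 1


@dataclass(frozen=True)
class DoseGrid:
    """The ordered space of dose levels with their standardized doses."""

    standardized_doses: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.standardized_doses, dtype=float)
        object.__setattr__(self, "standardized_doses", x)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("need at least two dose levels")
        if not np.all(np.diff(x) > 0):
            raise ValueError("standardized doses must be strictly increasing")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(str(i + 1) for i in range(x.size))
            )
        elif len(self.labels) != x.size:
            raise ValueError("labels do not match number of levels")

    @property
    def K(self) -> int:
        return int(self.standardized_doses.size)

    def dose(self, level: int) -> float:
        """Standardized dose of a 1-based level index."""
        if not 1 <= level <= self.K:
            raise ValueError(f"level {level} outside [1, {self.K}]")
        return float(self.standardized_doses[level - 1])


@dataclass(frozen=True)
class Skeleton:
    """Prior DLT probabilities per level, anchored at the target ``theta``."""

    probs: np.ndarray
    theta: float
    nu: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie in (0, 1)")
        if not np.all((p > 0.0) & (p < 1.0)):
            raise ValueError("skeleton probabilities must lie in (0, 1)")
        if not np.all(np.diff(p) > 0):
            raise ValueError("skeleton probabilities must be strictly increasing")
        if not 1 <= self.nu <= p.size:
            raise ValueError("prior-MTD level nu out of range")

    @property
    def K(self) -> int:
        return int(self.probs.size)


def _check_empiric_x(x: np.ndarray) -> None:
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("empiric model requires standardized doses in (0, 1)")


def dlt_probability(model: ModelSpec, x, params):
    """DLT probability psi(x, params) under the given family.

    ``x`` and the entries of ``params`` broadcast against each other, so a
    vector of quadrature nodes can be evaluated in one call.
    """
    x = np.asarray(x, dtype=float)
    params = np.atleast_1d(np.asarray(params, dtype=float))
    if model.family in ("empiric", "logistic1"):
        # a broadcasts against x: either may be a vector (quadrature nodes
        # against one dose, or the dose grid against one estimate)
        a = params[0] if params.size == 1 else params
        if model.family == "empiric":
            _check_empiric_x(x)
            return np.exp(np.exp(a) * np.log(x))
        return expit(model.fixed_intercept + np.exp(a) * x)
    # logistic2
    if params.ndim == 1 and params.size == 2:
        a0, a1 = params
    else:
        a0, a1 = params[0], params[1]
    if np.any(np.asarray(a1) <= 0.0):
        raise ValueError("logistic2 slope a1 must be positive")
    return expit(a0 + a1 * x)


def _psi_one(model: ModelSpec, x: float, a: float) -> float:
    return float(dlt_probability(model, x, [a]))


def _inv_dose(model: ModelSpec, p: float, a: float) -> float:
    """Standardized dose x with psi(x, a) == p, for one-parameter families."""
    if model.family == "empiric":
        return float(np.exp(np.log(p) / np.exp(a)))
    # logistic1: expit(b + exp(a) x) = p
    return float((logit(p) - model.fixed_intercept) / np.exp(a))


def _solve_param(model: ModelSpec, x: float, p: float) -> float:
    """Parameter a with psi(x, a) == p (bisection; monotone in a)."""
    f = lambda a: _psi_one(model, x, a) - p
    lo, hi = -50.0, 50.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def standardized_doses(skeleton: Skeleton, model: ModelSpec) -> DoseGrid:
    """Working doses implied by a skeleton at the prior parameter value.

    The prior parameter is the neutral value a = 0, so the empiric working
    doses equal the skeleton probabilities and the logistic ones are the
    logit-transformed probabilities shifted by the fixed intercept.
    """
    p = skeleton.probs
    if model.family == "empiric":
        x = p.copy()
    elif model.family == "logistic1":
        x = logit(p) - model.fixed_intercept
    else:  # logistic2: location-only transform; intercept plays no role
        x = logit(p)
    return DoseGrid(standardized_doses=x)


def calibrate_skeleton(
    theta: float,
    delta: float,
    nu: int,
    K: int,
    model: ModelSpec | None = None,
) -> Skeleton:
    """Indifference-interval skeleton calibration.

    Anchors level ``nu`` at ``theta`` and spaces neighbouring levels so that
    the parameter value mapping level i+1 to ``theta + delta`` maps level i
    to ``theta - delta``.  For the empiric family this gives the closed
    recursion  p_{i+1} = exp( ln(theta+delta) * ln(p_i) / ln(theta-delta) );
    logistic families are solved numerically level by level.
    """
    model = model or ModelSpec()
    if model.family == "logistic2":
        raise ValueError("skeleton calibration applies to one-parameter families")
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    if not (0.0 < delta < min(theta, 1.0 - theta)):
        raise ValueError("halfwidth delta must lie in (0, min(theta, 1-theta))")
    if not 1 <= nu <= K:
        raise ValueError("nu out of range")

    probs = np.empty(K)
    probs[nu - 1] = theta
    lo, hi = theta - delta, theta + delta
    if model.family == "empiric":
        for i in range(nu - 1, K - 1):  # upward
            probs[i + 1] = np.exp(np.log(hi) * np.log(probs[i]) / np.log(lo))
        for i in range(nu - 1, 0, -1):  # downward
            probs[i - 1] = np.exp(np.log(lo) * np.log(probs[i]) / np.log(hi))
    else:
        # place working doses so adjacent levels straddle one indifference
        # interval, then read probabilities back at the prior parameter
        for i in range(nu - 1, K - 1):
            a = _solve_param(model, _inv_dose(model, probs[i], 0.0), lo)
            probs[i + 1] = _psi_one(model, _inv_dose(model, hi, a), 0.0)
        for i in range(nu - 1, 0, -1):
            a = _solve_param(model, _inv_dose(model, probs[i], 0.0), hi)
            probs[i - 1] = _psi_one(model, _inv_dose(model, lo, a), 0.0)
    return Skeleton(probs=probs, theta=theta, nu=nu)
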