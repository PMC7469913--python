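"""Likelihoods, Bayesian posteriors, maximum likelihood, and TITE weights.

The accumulating trial history is a sequence of patient records
``(x_j, y_j, u_j)``: the standardized dose given, the DLT outcome (or
pending), and the follow-up time.  All estimation flows through the
weighted binomial likelihood

    L(a) = prod_j [w_j psi(x_j, a)]^{y_j} [1 - w_j psi(x_j, a)]^{1 - y_j}

where the weight ``w_j`` is 1 for fully observed patients and ``u_j / T``
for patients still on follow-up (the linear time-to-event weight).  With
all weights equal to 1 this is the ordinary CRM likelihood.

Posteriors for the one-parameter families are computed by deterministic
trapezoid quadrature on a fixed parameter grid, with all products taken in
log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .models import DoseGrid, ModelSpec, dlt_probability

__all__ = [
    "PatientRecord",
    "TrialHistory",
    "PriorSpec",
    "PosteriorSummary",
    "NoHeterogeneityError",
    "tite_weight",
    "likelihood",
    "log_likelihood",
    "bayes_posterior",
    "dose_tox_estimates",
    "mle_estimate",
]

PENDING = None  # sentinel outcome for a patient still on follow-up


class NoHeterogeneityError(ValueError):
    """The likelihood has no maximiser: all observed outcomes are identical."""


def tite_weight(u: float, T: float, dlt: bool) -> float:
    """Linear time-to-event weight: u/T while on follow-up, 1 on DLT."""
    if T <= 0:
        raise ValueError("observation window T must be positive")
    if u < 0 or u > T:
        raise ValueError(f"follow-up u={u} outside [0, T={T}]")
    if dlt:
        return 1.0
    return u / T


@dataclass(frozen=True)
class PatientRecord:
    """One enrolled patient: dose given, outcome, follow-up.

    ``outcome`` is 1 (DLT), 0 (no DLT) or None (pending).  The likelihood
    weight is always recomputed from ``(followup, T, outcome)`` at
    estimation time; a pending patient contributes through the partial
    weight u/T, and a resolved patient through weight 1.
    """

    id: int
    dose_level: int
    dose_value: float
    outcome: int | None = 0
    followup: float | None = None

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1, PENDING):
            raise ValueError("outcome must be 0, 1 or pending (None)")

    @property
    def pending(self) -> bool:
        return self.outcome is PENDING

    def weight(self, T: float | None) -> float:
        """Likelihood weight given the observation window (None => non-TITE)."""
        if T is None:
            if self.pending:
                raise ValueError(
                    "pending outcome has no weight outside a TITE design"
                )
            return 1.0
        if self.outcome == 1:
            return 1.0
        u = T if self.followup is None else min(self.followup, T)
        return tite_weight(u, T, dlt=False)


@dataclass(frozen=True)
class TrialHistory:
    """Ordered patient records with contiguous ids starting at 1."""

    records: tuple[PatientRecord, ...] = ()

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("patient ids must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def append(self, record: PatientRecord) -> "TrialHistory":
        return TrialHistory(records=self.records + (record,))

    def arrays(self, T: float | None):
        """(doses, outcomes, weights) as arrays; pending counts as y=0."""
        if not self.records:
            z = np.empty(0)
            return z, z, z
        x = np.array([r.dose_value for r in self.records])
        y = np.array([0 if r.pending else r.outcome for r in self.records], float)
        w = np.array([r.weight(T) for r in self.records])
        return x, y, w


@dataclass(frozen=True)
class PriorSpec:
    """Prior on the model parameter of a one-parameter family.

    Families and parameters:
      unit_exponential: ()                 — Exp(1), the classic CRM example
      normal:           (mean, var)        — default (0, 1.34**2)
      gamma:            (shape, scale)
      uniform:          (lo, hi)
      lognormal:        (mu, sigma)
    """

    family: str = "normal"
    params: tuple[float, ...] = (0.0, 1.34**2)

    def _dist(self):
        f, p = self.family, self.params
        if f == "unit_exponential":
            return stats.expon()
        if f == "normal":
            return stats.norm(loc=p[0], scale=np.sqrt(p[1]))
        if f == "gamma":
            return stats.gamma(a=p[0], scale=p[1])
        if f == "uniform":
            return stats.uniform(loc=p[0], scale=p[1] - p[0])
        if f == "lognormal":
            return stats.lognorm(s=p[1], scale=np.exp(p[0]))
        raise ValueError(f"unknown prior family {self.family!r}")

    @property
    def mean(self) -> float:
        return float(self._dist().mean())

    def logpdf(self, a):
        return self._dist().logpdf(a)

    def rvs(self, size: int, rng) -> np.ndarray:
        return self._dist().rvs(size=size, random_state=rng)

    def grid(self, n: int = 2001) -> np.ndarray:
        """Quadrature nodes over mean +/- 8 sd, clipped to the support."""
        d = self._dist()
        m, s = d.mean(), d.std()
        lo, hi = d.support()
        lo = max(lo, m - 8.0 * s)
        hi = min(hi, m + 8.0 * s)
        return np.linspace(lo, hi, n)


@dataclass
class PosteriorSummary:
    """Posterior of the model parameter on a fixed quadrature grid."""

    grid: np.ndarray
    density: np.ndarray
    mean_a: float
    model: ModelSpec
    dose_estimates: np.ndarray | None = None

    def cdf(self) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid

        c = cumulative_trapezoid(self.density, self.grid, initial=0.0)
        return c / c[-1]

    def quantile(self, q: float) -> float:
        return float(np.interp(q, self.cdf(), self.grid))


def log_likelihood(
    history: TrialHistory,
    model: ModelSpec,
    a_grid: np.ndarray,
    T: float | None = None,
) -> np.ndarray:
    """Weighted log-likelihood evaluated on a vector of parameter values.

    Fully observed records at the same dose are aggregated into counts so
    the cost is O(K * len(a_grid)) regardless of the number of patients.
    """
    a_grid = np.atleast_1d(np.asarray(a_grid, dtype=float))
    out = np.zeros_like(a_grid)
    x, y, w = history.arrays(T)
    if x.size == 0:
        return out
    full = w == 1.0
    if np.any(full):
        doses, inv = np.unique(x[full], return_inverse=True)
        n_dlt = np.bincount(inv, weights=y[full], minlength=doses.size)
        n_tot = np.bincount(inv, minlength=doses.size).astype(float)
        for d, s, t in zip(doses, n_dlt, n_tot):
            psi = dlt_probability(model, d, a_grid)
            psi = np.clip(psi, 1e-300, 1.0 - 1e-16)
            out += s * np.log(psi) + (t - s) * np.log1p(-psi)
    for xi, yi, wi in zip(x[~full], y[~full], w[~full]):
        if wi == 0.0:
            continue  # no information yet
        psi = np.clip(wi * dlt_probability(model, xi, a_grid), 1e-300, 1 - 1e-16)
        out += yi * np.log(psi) + (1.0 - yi) * np.log1p(-psi)
    return out


def likelihood(
    history: TrialHistory,
    model: ModelSpec,
    params,
    T: float | None = None,
) -> float:
    """The weighted likelihood itself; 1 for an empty history."""
    if model.family == "logistic2":
        x, y, w = history.arrays(T)
        psi = np.array([dlt_probability(model, xi, params) for xi in x])
        terms = np.where(y == 1, w * psi, 1.0 - w * psi)
        return float(np.prod(terms)) if terms.size else 1.0
    return float(np.exp(log_likelihood(history, model, np.asarray(params), T))[0])


def bayes_posterior(
    history: TrialHistory,
    model: ModelSpec,
    prior: PriorSpec,
    T: float | None = None,
    n_nodes: int = 2001,
) -> PosteriorSummary:
    """Posterior density of the model parameter by trapezoid quadrature.

    The density is prior x likelihood normalized by the marginal; with an
    empty history it reduces to the prior.  Computation is in log space to
    survive extreme parameter values.
    """
    a = prior.grid(n_nodes)
    logpost = prior.logpdf(a) + log_likelihood(history, model, a, T)
    m = np.max(logpost)
    if not np.isfinite(m):
        raise FloatingPointError("posterior is identically zero on the grid")
    dens = np.exp(logpost - m)
    norm = np.trapezoid(dens, a)
    if norm <= 0:
        raise FloatingPointError("posterior failed to normalize")
    dens /= norm
    mean_a = float(np.trapezoid(a * dens, a))
    return PosteriorSummary(grid=a, density=dens, mean_a=mean_a, model=model)


def dose_tox_estimates(
    posterior: PosteriorSummary,
    grid: DoseGrid,
    mode: str = "plugin",
) -> np.ndarray:
    """Per-level DLT probability estimates from a parameter posterior.

    ``plugin`` evaluates psi(x_i, a_hat) at the posterior mean (the
    convention of the classic CRM software); ``integrated`` computes the
    posterior expectation  E[psi(x_i, a)]  by quadrature.
    """
    if mode == "plugin":
        est = dlt_probability(
            posterior.model, grid.standardized_doses, [posterior.mean_a]
        )
    elif mode == "integrated":
        est = np.array(
            [
                np.trapezoid(
                    dlt_probability(posterior.model, x, posterior.grid)
                    * posterior.density,
                    posterior.grid,
                )
                for x in grid.standardized_doses
            ]
        )
    else:
        raise ValueError("mode must be 'plugin' or 'integrated'")
    est = np.asarray(est, dtype=float)
    posterior.dose_estimates = est
    return est


def mle_estimate(
    history: TrialHistory,
    model: ModelSpec,
    T: float | None = None,
    bounds: tuple[float, float] = (-10.0, 10.0),
) -> float:
    """Maximum-likelihood estimate of the one-parameter model.

    Raises :class:`NoHeterogeneityError` until the history contains at
    least one DLT and one non-DLT with positive weight, since the
    likelihood is monotone in the parameter until then.
    """
    if model.family == "logistic2":
        raise ValueError("MLE is defined here for one-parameter families")
    if len(history) == 0:
        raise ValueError("empty history")
    x, y, w = history.arrays(T)
    eff = w > 0
    if not (np.any(y[eff] == 1) and np.any(y[eff] == 0)):
        raise NoHeterogeneityError(
            "need at least one DLT and one non-DLT to maximize the likelihood"
        )
    res = minimize_scalar(
        lambda a: -log_likelihood(history, model, np.array([a]), T)[0],
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)
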