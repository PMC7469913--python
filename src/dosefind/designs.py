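"""Next-dose selection and stopping logic for the five supported designs.

CRMB / CRML / TITE-CRM pick the level whose estimated DLT probability is
closest to the target theta (ties broken to the lower, safer, level).
EWOC / TITE-EWOC instead control overdose: they pick the highest level x
whose posterior probability of exceeding the MTD, pi(x) = P(MTD <= x | data),
stays at or below the feasibility bound alpha.

The EWOC posterior uses the standard reparameterization of the
two-parameter logistic model in terms of (rho0, gamma): the DLT probability
at the lowest dose and the MTD on the standardized-dose axis.  The slope
constraint a1 > 0 translates to rho0 < theta and gamma > x_1, which is the
region covered by the default independent uniform priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .models import DoseGrid, ModelSpec, Skeleton, dlt_probability, standardized_doses
from .inference import (
    NoHeterogeneityError,
    PosteriorSummary,
    PriorSpec,
    TrialHistory,
    bayes_posterior,
    dose_tox_estimates,
    mle_estimate,
)

__all__ = [
    "METHODS",
    "DesignConfig",
    "StoppingRule",
    "DoseRecommendation",
    "EwocPosterior",
    "EwocPriors",
    "TrialDesign",
    "crm_next_dose",
    "crml_run_in",
    "ewoc_posterior",
    "ewoc_next_dose",
    "check_stopping",
]

METHODS = ("CRMB", "CRML", "TITE_CRM", "EWOC", "TITE_EWOC")
TITE_METHODS = ("TITE_CRM", "TITE_EWOC")
EWOC_METHODS = ("EWOC", "TITE_EWOC")


@dataclass(frozen=True)
class StoppingRule:
    """Stop at a maximum sample size, or once a level holds enough patients.

    ``max_n`` stops enrollment when the sample size is reached;
    ``m_at_level`` stops when the level about to be recommended has already
    treated ``m`` patients (a fixed level may be given instead via
    ``level_scope``).
    """

    kind: str
    max_n: int | None = None
    m: int | None = None
    level_scope: int | None = None  # None => the currently recommended level

    def __post_init__(self) -> None:
        if self.kind == "max_n":
            if not self.max_n or self.max_n < 1:
                raise ValueError("max_n rule needs max_n >= 1")
        elif self.kind == "m_at_level":
            if not self.m or self.m < 1:
                raise ValueError("m_at_level rule needs m >= 1")
        else:
            raise ValueError(f"unknown stopping rule kind {self.kind!r}")


@dataclass(frozen=True)
class DesignConfig:
    """Which design runs the trial, and its conduct parameters."""

    method: str = "CRMB"
    theta: float = 0.2
    alpha: float | None = None
    observation_window_T: float | None = None
    start_level: int = 1
    no_skip: bool = True
    stopping: tuple[StoppingRule, ...] = ()
    run_in_cohort: int = 1
    run_in_deescalate: bool = False
    estimate_mode: str = "plugin"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie in (0, 1)")
        if self.method in EWOC_METHODS:
            if self.alpha is None or not (0.0 < self.alpha <= 0.5):
                raise ValueError("EWOC designs need alpha in (0, 0.5]")
        elif self.alpha is not None:
            raise ValueError("alpha applies only to EWOC designs")
        if self.method in TITE_METHODS:
            if self.observation_window_T is None or self.observation_window_T <= 0:
                raise ValueError("TITE designs need a positive observation window")

    @property
    def is_tite(self) -> bool:
        return self.method in TITE_METHODS

    @property
    def T(self) -> float | None:
        return self.observation_window_T if self.is_tite else None


@dataclass(frozen=True)
class DoseRecommendation:
    level: int
    estimates: np.ndarray | None = None
    constrained_by: str = "none"  # none | no_skip | overdose_control
    stop: bool = False
    stop_reason: str | None = None


def crm_next_dose(
    estimates: np.ndarray,
    theta: float,
    current_max_tried: int = 0,
    no_skip: bool = True,
) -> DoseRecommendation:
    """Level whose estimated DLT probability is closest to theta.

    Ties break to the lower level; with ``no_skip`` the recommendation is
    capped one level above the highest level tried so far.
    """
    estimates = np.asarray(estimates, dtype=float)
    dist = np.abs(estimates - theta)
    # tie tolerance so 0.15 vs 0.25 at theta=0.2 breaks to the lower level
    best = int(np.nonzero(dist <= dist.min() + 1e-12)[0][0]) + 1
    constrained = "none"
    if no_skip and current_max_tried >= 1:
        cap = min(current_max_tried + 1, estimates.size)
        if best > cap:
            best, constrained = cap, "no_skip"
    return DoseRecommendation(level=best, estimates=estimates, constrained_by=constrained)


def crml_run_in(
    history: TrialHistory,
    start_level: int,
    K: int,
    cohort: int = 1,
    deescalate_on_dlt: bool = False,
) -> DoseRecommendation:
    """Algorithmic run-in used before the likelihood has a maximiser.

    Escalates one level per DLT-free cohort from the starting level without
    skipping; after the first DLT it holds the current level (or steps down
    when ``deescalate_on_dlt``) until both outcome kinds have been seen and
    model-based selection can take over.
    """
    if len(history) == 0:
        return DoseRecommendation(level=start_level)
    last = history.records[-1].dose_level
    any_dlt = any(r.outcome == 1 for r in history)
    if not any_dlt:
        at_last = sum(1 for r in history if r.dose_level == last)
        if at_last >= cohort:
            return DoseRecommendation(level=min(last + 1, K))
        return DoseRecommendation(level=last)
    if deescalate_on_dlt and history.records[-1].outcome == 1:
        return DoseRecommendation(level=max(last - 1, 1))
    return DoseRecommendation(level=last)


@dataclass(frozen=True)
class EwocPriors:
    """Independent priors on (rho0, gamma); defaults U(0, theta) x U(x1, xK)."""

    rho0: PriorSpec | None = None
    gamma: PriorSpec | None = None

    def log_density(self, rho: np.ndarray, gam: np.ndarray, theta, x1, xK):
        lp = np.zeros((rho.size, gam.size))
        if self.rho0 is not None:
            lp += self.rho0.logpdf(rho)[:, None]
        if self.gamma is not None:
            lp += self.gamma.logpdf(gam)[None, :]
        return lp  # None => flat over the grid box (the default uniforms)


@dataclass
class EwocPosterior:
    """Joint posterior of (rho0, gamma) on a rectangular grid."""

    rho_grid: np.ndarray
    gamma_grid: np.ndarray
    joint: np.ndarray  # density, rho along axis 0
    gamma_marginal: np.ndarray
    gamma_cdf: np.ndarray

    def prob_overdose(self, x: float) -> float:
        """pi(x) = P(MTD <= x | data) from the gamma marginal CDF."""
        return float(np.interp(x, self.gamma_grid, self.gamma_cdf))

    def mtd_quantile(self, q: float) -> float:
        return float(np.interp(q, self.gamma_cdf, self.gamma_grid))


def _ewoc_param_maps(theta: float, x1: float, rho: np.ndarray, gam: np.ndarray):
    """(a0, a1) fields over the (rho0, gamma) grid."""
    a1 = (logit(theta) - logit(rho)[:, None]) / (gam[None, :] - x1)
    a0 = logit(rho)[:, None] - a1 * x1
    return a0, a1


class _EwocTables:
    """Cached per-level log psi / log(1-psi) fields on the (rho0, gamma) grid."""

    def __init__(self, grid: DoseGrid, theta: float, n_rho: int, n_gamma: int):
        x1, xK = grid.standardized_doses[0], grid.standardized_doses[-1]
        # rho0 nodes on the logit scale: the likelihood has boundary layers
        # at rho0 -> 0 and rho0 -> theta that a uniform grid cannot resolve
        t = np.linspace(-25.0, 25.0, n_rho)
        self.rho = theta * expit(t)
        # open at the singular edge gamma = x1 (infinite slope)
        self.gamma = np.linspace(x1, xK, n_gamma + 1)[1:]
        a0, a1 = _ewoc_param_maps(theta, x1, self.rho, self.gamma)
        self.psi = {}
        self.logpsi = {}
        self.log1mpsi = {}
        for lvl, x in enumerate(grid.standardized_doses, start=1):
            p = np.clip(expit(a0 + a1 * x), 1e-300, 1.0 - 1e-16)
            self.psi[lvl] = p
            self.logpsi[lvl] = np.log(p)
            self.log1mpsi[lvl] = np.log1p(-p)


_EWOC_CACHE: dict[tuple, _EwocTables] = {}


def _ewoc_tables(grid: DoseGrid, theta: float, n_rho: int, n_gamma: int):
    key = (tuple(grid.standardized_doses), theta, n_rho, n_gamma)
    if key not in _EWOC_CACHE:
        if len(_EWOC_CACHE) > 8:
            _EWOC_CACHE.clear()
        _EWOC_CACHE[key] = _EwocTables(grid, theta, n_rho, n_gamma)
    return _EWOC_CACHE[key]


def ewoc_posterior(
    history: TrialHistory,
    grid: DoseGrid,
    theta: float,
    priors: EwocPriors | None = None,
    T: float | None = None,
    n_rho: int = 201,
    n_gamma: int = 201,
) -> EwocPosterior:
    """Joint posterior of (rho0, gamma) by 2-D trapezoid quadrature.

    The two-parameter logistic likelihood (optionally TITE-weighted) is
    evaluated on a fixed grid over rho0 in (0, theta) and gamma in
    (x_1, x_K]; the marginal CDF of gamma is the overdose-control curve
    pi(x) = P(MTD <= x | data).
    """
    priors = priors or EwocPriors()
    tab = _ewoc_tables(grid, theta, n_rho, n_gamma)
    logpost = priors.log_density(
        tab.rho, tab.gamma, theta, grid.standardized_doses[0],
        grid.standardized_doses[-1],
    ).copy()
    for r in history:
        w = r.weight(T)
        if w == 0.0:
            continue
        y = 0 if r.pending else r.outcome
        if w == 1.0:
            logpost += tab.logpsi[r.dose_level] if y else tab.log1mpsi[r.dose_level]
        else:
            wp = np.clip(w * tab.psi[r.dose_level], 1e-300, 1.0 - 1e-16)
            logpost += np.log(wp) if y else np.log1p(-wp)
    logpost -= np.max(logpost)
    joint = np.exp(logpost)
    norm = np.trapezoid(np.trapezoid(joint, tab.gamma, axis=1), tab.rho)
    if norm <= 0:
        raise FloatingPointError("EWOC posterior failed to normalize")
    joint /= norm
    marg = np.trapezoid(joint, tab.rho, axis=0)
    from scipy.integrate import cumulative_trapezoid

    cdf = cumulative_trapezoid(marg, tab.gamma, initial=0.0)
    cdf /= cdf[-1]
    return EwocPosterior(
        rho_grid=tab.rho, gamma_grid=tab.gamma, joint=joint,
        gamma_marginal=marg, gamma_cdf=cdf,
    )


def ewoc_next_dose(
    posterior: EwocPosterior,
    alpha: float,
    grid: DoseGrid,
    no_skip: bool = True,
    current_max_tried: int = 0,
) -> DoseRecommendation:
    """Highest level with P(MTD <= x | data) <= alpha; level 1 if none.

    The no-skip cap is applied after overdose control, so the final level
    is never above either constraint.
    """
    pi = np.array([posterior.prob_overdose(x) for x in grid.standardized_doses])
    ok = np.nonzero(pi <= alpha + 1e-12)[0]
    if ok.size:
        level, constrained = int(ok[-1]) + 1, "overdose_control"
    else:
        level, constrained = 1, "overdose_control"
    if no_skip and current_max_tried >= 1:
        cap = min(current_max_tried + 1, grid.K)
        if level > cap:
            level, constrained = cap, "no_skip"
    return DoseRecommendation(level=level, estimates=pi, constrained_by=constrained)


def check_stopping(
    history: TrialHistory,
    rules: tuple[StoppingRule, ...],
    next_recommendation: DoseRecommendation,
) -> tuple[bool, str | None]:
    """First firing rule wins; (False, None) when none fires."""
    n = len(history)
    for rule in rules:
        if rule.kind == "max_n" and n >= rule.max_n:
            return True, f"max_n={rule.max_n} reached"
        if rule.kind == "m_at_level":
            lvl = rule.level_scope or next_recommendation.level
            treated = sum(1 for r in history if r.dose_level == lvl)
            if treated >= rule.m:
                return True, f"{treated} patients already treated at level {lvl}"
    return False, None


@dataclass(frozen=True)
class TrialDesign:
    """A complete, runnable design: config + skeleton + model + priors.

    This is the object trial conduct and simulation share; its
    :meth:`recommend` method reproduces the same dose sequence wherever it
    is called from.
    """

    config: DesignConfig
    skeleton: Skeleton
    model: ModelSpec = ModelSpec("empiric")
    prior: PriorSpec = PriorSpec("normal", (0.0, 1.34**2))
    ewoc_priors: EwocPriors = field(default_factory=EwocPriors)
    n_nodes: int = 2001
    ewoc_grid: tuple[int, int] = (201, 201)

    def __post_init__(self) -> None:
        if self.config.method in EWOC_METHODS:
            if self.model.family != "logistic2":
                object.__setattr__(self, "model", ModelSpec("logistic2"))
        elif self.model.family == "logistic2":
            raise ValueError("CRM designs use a one-parameter model")
        if not 1 <= self.config.start_level <= self.skeleton.K:
            raise ValueError("start_level outside the dose grid")

    @property
    def grid(self) -> DoseGrid:
        return standardized_doses(self.skeleton, self.model)

    def max_tried(self, history: TrialHistory) -> int:
        return max((r.dose_level for r in history), default=0)

    def recommend(self, history: TrialHistory) -> DoseRecommendation:
        """Model-based next-dose recommendation from the current history."""
        cfg = self.config
        if len(history) == 0:
            return DoseRecommendation(level=cfg.start_level)
        if not cfg.is_tite and any(r.pending for r in history):
            raise PendingOutcomeError(
                "non-TITE designs need all outcomes resolved before the next "
                "model-based recommendation"
            )
        mt = self.max_tried(history)
        if cfg.method in EWOC_METHODS:
            post = ewoc_posterior(
                history, self.grid, cfg.theta, self.ewoc_priors,
                T=cfg.T, n_rho=self.ewoc_grid[0], n_gamma=self.ewoc_grid[1],
            )
            return ewoc_next_dose(post, cfg.alpha, self.grid, cfg.no_skip, mt)
        if cfg.method == "CRML":
            try:
                a_hat = mle_estimate(history, self.model, T=cfg.T)
            except NoHeterogeneityError:
                rec = crml_run_in(
                    history, cfg.start_level, self.skeleton.K,
                    cohort=cfg.run_in_cohort,
                    deescalate_on_dlt=cfg.run_in_deescalate,
                )
                if cfg.no_skip and rec.level > mt + 1:
                    rec = DoseRecommendation(level=mt + 1, constrained_by="no_skip")
                return rec
            est = dlt_probability(self.model, self.grid.standardized_doses, [a_hat])
            return crm_next_dose(est, cfg.theta, mt, cfg.no_skip)
        # CRMB / TITE_CRM
        post = bayes_posterior(history, self.model, self.prior, T=cfg.T,
                               n_nodes=self.n_nodes)
        est = dose_tox_estimates(post, self.grid, mode=cfg.estimate_mode)
        return crm_next_dose(est, cfg.theta, mt, cfg.no_skip)

    def recommend_and_check(self, history: TrialHistory):
        rec = self.recommend(history)
        stop, reason = check_stopping(history, self.config.stopping, rec)
        if stop:
            rec = DoseRecommendation(
                level=rec.level, estimates=rec.estimates,
                constrained_by=rec.constrained_by, stop=True, stop_reason=reason,
            )
        return rec


class PendingOutcomeError(RuntimeError):
    """A non-TITE design cannot estimate while an outcome is pending."""
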