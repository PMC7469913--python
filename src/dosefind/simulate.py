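"""Monte-Carlo operating characteristics of a dose-escalation design.

A scenario fixes the *true* per-level DLT probabilities; each simulated
trial enrolls patients at the design's running recommendation, draws their
outcomes from the truth, and records the final MTD recommendation and the
per-level allocation.  Aggregating over many replicates gives the
operating characteristics a protocol team looks at: where the design lands
its MTD, how many patients each level receives, and how often patients are
treated above the true MTD.

Replicates use independent substreams spawned from one root seed, so
results do not depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import TrialDesign
from .inference import PatientRecord, TrialHistory

__all__ = [
    "Scenario",
    "TrialResult",
    "OperatingCharacteristics",
    "run_single_trial",
    "simulate_tite_timeline",
    "run_batch",
]


@dataclass(frozen=True)
class Scenario:
    """True state of nature plus simulation bookkeeping.

    ``accrual_gap`` (TITE only) is the fixed inter-arrival time; the
    default of one third of the observation window enrolls three patients
    per window.  Given a DLT, its onset time is uniform on (0, T].
    """

    true_probs: np.ndarray
    n: int = 25
    n_trials: int = 1000
    seed: int = 0
    accrual_gap: float | None = None
    dlt_time_model: str = "uniform"

    def __post_init__(self) -> None:
        p = np.asarray(self.true_probs, dtype=float)
        object.__setattr__(self, "true_probs", p)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("true DLT probabilities must lie in [0, 1]")
        if np.any(np.diff(p) < 0):
            warnings.warn("true DLT probabilities are not nondecreasing",
                          stacklevel=2)
        if self.n_trials < 1 or self.n < 1:
            raise ValueError("need n >= 1 and n_trials >= 1")

    @property
    def K(self) -> int:
        return int(self.true_probs.size)

    def true_mtd_level(self, theta: float) -> int:
        """Level whose true DLT probability is closest to the target."""
        return int(np.argmin(np.abs(self.true_probs - theta))) + 1


@dataclass(frozen=True)
class TrialResult:
    recommended_level: int
    n_per_level: np.ndarray
    dlt_per_level: np.ndarray
    levels: np.ndarray = None  # per-patient assigned level, in order
    outcomes: np.ndarray = None

    @property
    def n_enrolled(self) -> int:
        return int(self.n_per_level.sum())

    @property
    def n_dlt(self) -> int:
        return int(self.dlt_per_level.sum())


@dataclass(frozen=True)
class Timeline:
    """Pre-drawn randomness for one TITE trial.

    ``tox_u`` are per-patient uniforms: patient j has a DLT at the level
    eventually assigned iff tox_u[j] < true_prob[level].  Onset times are
    drawn on (0, T] and only take effect for patients whose draw converts
    to a DLT.
    """

    arrivals: np.ndarray
    tox_u: np.ndarray
    dlt_times: np.ndarray


def simulate_tite_timeline(scenario: Scenario, rng: np.random.Generator,
                           T: float) -> Timeline:
    gap = scenario.accrual_gap if scenario.accrual_gap is not None else T / 3.0
    if gap < 0:
        raise ValueError("accrual gap must be nonnegative")
    arrivals = gap * np.arange(scenario.n, dtype=float)
    tox_u = rng.random(scenario.n)
    if scenario.dlt_time_model != "uniform":
        raise ValueError("only the uniform time-to-DLT model is implemented")
    # uniform on (0, T]
    dlt_times = T * (1.0 - rng.random(scenario.n))
    return Timeline(arrivals=arrivals, tox_u=tox_u, dlt_times=dlt_times)


def _tite_trial(design: TrialDesign, scenario: Scenario,
                rng: np.random.Generator) -> TrialResult:
    T = design.config.observation_window_T
    tl = simulate_tite_timeline(scenario, rng, T)
    levels = np.zeros(scenario.n, dtype=int)
    level = design.config.start_level
    for j in range(scenario.n):
        if j > 0:
            now = tl.arrivals[j]
            records = []
            for i in range(j):
                u = min(now - tl.arrivals[i], T)
                has_dlt = tl.tox_u[i] < scenario.true_probs[levels[i] - 1]
                if has_dlt and tl.dlt_times[i] <= u:
                    rec = PatientRecord(i + 1, int(levels[i]),
                                        design.grid.dose(int(levels[i])),
                                        outcome=1, followup=tl.dlt_times[i])
                elif u >= T:
                    rec = PatientRecord(i + 1, int(levels[i]),
                                        design.grid.dose(int(levels[i])),
                                        outcome=0, followup=T)
                else:
                    rec = PatientRecord(i + 1, int(levels[i]),
                                        design.grid.dose(int(levels[i])),
                                        outcome=None, followup=u)
                records.append(rec)
            level = design.recommend(TrialHistory(tuple(records))).level
        levels[j] = level
    # final analysis with everyone followed through the full window
    dlt = tl.tox_u < scenario.true_probs[levels - 1]
    records = tuple(
        PatientRecord(i + 1, int(levels[i]), design.grid.dose(int(levels[i])),
                      outcome=int(dlt[i]),
                      followup=tl.dlt_times[i] if dlt[i] else T)
        for i in range(scenario.n)
    )
    final = design.recommend(TrialHistory(records)).level
    K = design.skeleton.K
    return TrialResult(
        recommended_level=final,
        n_per_level=np.bincount(levels, minlength=K + 1)[1:],
        dlt_per_level=np.bincount(levels[dlt], minlength=K + 1)[1:],
        levels=levels,
        outcomes=dlt.astype(int),
    )


def run_single_trial(design: TrialDesign, scenario: Scenario,
                     rng: np.random.Generator) -> TrialResult:
    """Simulate one trial under the scenario's true DLT probabilities.

    Non-TITE designs resolve each outcome before the next enrollment; TITE
    designs enroll on the accrual clock with partial follow-up weights.
    """
    if design.skeleton.K != scenario.K:
        raise ValueError("scenario and design disagree on the number of levels")
    if design.config.is_tite:
        return _tite_trial(design, scenario, rng)
    level = design.config.start_level
    history = TrialHistory()
    rec = None
    for j in range(1, scenario.n + 1):
        y = int(rng.random() < scenario.true_probs[level - 1])
        history = history.append(
            PatientRecord(j, level, design.grid.dose(level), outcome=y)
        )
        rec = design.recommend_and_check(history)
        if rec.stop:
            break
        level = rec.level
    K = design.skeleton.K
    lv = np.array([r.dose_level for r in history])
    yy = np.array([r.outcome for r in history], dtype=bool)
    return TrialResult(
        recommended_level=rec.level,
        n_per_level=np.bincount(lv, minlength=K + 1)[1:],
        dlt_per_level=np.bincount(lv[yy], minlength=K + 1)[1:],
        levels=lv,
        outcomes=yy.astype(int),
    )


@dataclass
class OperatingCharacteristics:
    """Aggregated results over simulated trials."""

    mtd_dist: np.ndarray          # fraction of trials recommending each level
    avg_patients: np.ndarray      # mean treated count per level
    avg_dlts: float               # mean DLT count per trial
    pct_under: float              # mean fraction treated below the true MTD
    pct_at: float
    pct_over: float
    true_mtd_level: int
    n_trials_completed: int
    mtd_dist_se: np.ndarray = None        # binomial MC standard errors
    avg_patients_se: np.ndarray = None    # per-trial SD / sqrt(n_trials)

    def to_frame(self) -> pd.DataFrame:
        K = self.mtd_dist.size
        return pd.DataFrame(
            {
                "dose_level": np.arange(1, K + 1),
                "mtd_pct": np.round(100 * self.mtd_dist, 1),
                "avg_patients": self.avg_patients,
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_trials": self.n_trials_completed,
                    "avg_dlts": self.avg_dlts,
                    "true_mtd_level": self.true_mtd_level,
                    "pct_under": np.round(100 * self.pct_under, 1),
                    "pct_at": np.round(100 * self.pct_at, 1),
                    "pct_over": np.round(100 * self.pct_over, 1),
                }
            ]
        )


def run_batch(design: TrialDesign, scenario: Scenario,
              progress: bool = False) -> OperatingCharacteristics:
    """Operating characteristics over ``scenario.n_trials`` replicates."""
    streams = np.random.SeedSequence(scenario.seed).spawn(scenario.n_trials)
    K = design.skeleton.K
    mtd_counts = np.zeros(K)
    pat = np.zeros(K)
    pat_sq = np.zeros(K)
    dlts = 0.0
    under = at = over = 0.0
    true_mtd = scenario.true_mtd_level(design.config.theta)
    for s in streams:
        res = run_single_trial(design, scenario, np.random.Generator(
            np.random.PCG64(s)))
        mtd_counts[res.recommended_level - 1] += 1
        pat += res.n_per_level
        pat_sq += res.n_per_level.astype(float) ** 2
        dlts += res.n_dlt
        n = res.n_enrolled
        under += res.n_per_level[: true_mtd - 1].sum() / n
        at += res.n_per_level[true_mtd - 1] / n
        over += res.n_per_level[true_mtd:].sum() / n
    m = scenario.n_trials
    mtd_dist = mtd_counts / m
    avg_patients = pat / m
    pat_var = np.maximum(pat_sq / m - avg_patients**2, 0.0)
    return OperatingCharacteristics(
        mtd_dist=mtd_dist,
        avg_patients=avg_patients,
        avg_dlts=dlts / m,
        pct_under=under / m,
        pct_at=at / m,
        pct_over=over / m,
        true_mtd_level=true_mtd,
        n_trials_completed=m,
        mtd_dist_se=np.sqrt(mtd_dist * (1.0 - mtd_dist) / m),
        avg_patients_se=np.sqrt(pat_var / m),
    )
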