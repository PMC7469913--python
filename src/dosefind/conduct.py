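"""Stateful conduct of a dose-escalation trial.

A :class:`Trial` wraps a :class:`~dosefind.designs.TrialDesign` plus the
accumulating history.  Every mutation appends to an audit log; the design
configuration freezes when the first patient is included; and every
recommendation is recomputed from the raw history, so reloading a saved
trial reproduces the recommendation sequence exactly.

Persistence is a single JSON document per trial (schema-versioned).
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .designs import (
    DesignConfig,
    DoseRecommendation,
    EwocPriors,
    StoppingRule,
    TrialDesign,
)
from .inference import PatientRecord, PriorSpec, TrialHistory
from .models import ModelSpec, Skeleton

__all__ = ["Trial", "TrialClosedError", "ConfigFrozenError", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class TrialClosedError(RuntimeError):
    """Inclusion attempted after the trial stopped."""


class ConfigFrozenError(RuntimeError):
    """Parameter change attempted after the first inclusion."""


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class Trial:
    """One trial: design, history, status, audit trail."""

    design: TrialDesign
    history: TrialHistory = field(default_factory=TrialHistory)
    status: str = "setup"  # setup | open | stopped
    audit: list[dict] = field(default_factory=list)
    recommendations: list[int] = field(default_factory=list)

    # -- conduct ----------------------------------------------------------

    def _log(self, action: str, **payload) -> None:
        self.audit.append({"time": _now(), "action": action, **payload})

    def recommend(self) -> DoseRecommendation:
        """Current model-based recommendation (start level before data)."""
        return self.design.recommend_and_check(self.history)

    def include_patient(
        self,
        dose_level: int,
        outcome: int | None,
        followup: float | None = None,
    ) -> DoseRecommendation:
        """Enroll a patient at a dose level; returns the next recommendation.

        The clinician may give any in-range level, not only the recommended
        one; the override is visible in the audit trail.  In a non-TITE
        design a pending outcome is accepted but defers the model-based
        recommendation until it is resolved.
        """
        cfg = self.design.config
        if self.status == "stopped":
            raise TrialClosedError("the trial has stopped; no further inclusions")
        K = self.design.skeleton.K
        if not 1 <= dose_level <= K:
            raise ValueError(f"dose level {dose_level} outside [1, {K}]")
        T = cfg.observation_window_T
        if T is not None and followup is not None and followup > T:
            raise ValueError("follow-up exceeds the observation window")
        if outcome is None and cfg.is_tite and followup is not None and followup >= T:
            raise ValueError("pending outcome requires follow-up below T")
        rec_before = self._safe_recommend()
        record = PatientRecord(
            id=len(self.history) + 1,
            dose_level=dose_level,
            dose_value=self.design.grid.dose(dose_level),
            outcome=outcome,
            followup=followup,
        )
        self.history = self.history.append(record)
        if self.status == "setup":
            self.status = "open"
        self._log(
            "include", patient=record.id, level=dose_level,
            outcome="pending" if outcome is None else outcome,
            followup=followup,
            recommended=None if rec_before is None else rec_before.level,
            override=rec_before is not None and dose_level != rec_before.level,
        )
        return self._after_change()

    def _safe_recommend(self) -> DoseRecommendation | None:
        from .designs import PendingOutcomeError

        try:
            return self.design.recommend(self.history)
        except PendingOutcomeError:
            return None

    def _after_change(self) -> DoseRecommendation | None:
        from .designs import PendingOutcomeError

        # corrections replay the whole history, so the stored sequence is
        # always exactly what a from-scratch recomputation yields
        self.recommendations = self.replay_recommendations()
        try:
            rec = self.design.recommend_and_check(self.history)
        except PendingOutcomeError:
            return None
        if rec.stop and self.status == "open":
            self.status = "stopped"
            self._log("stop", reason=rec.stop_reason)
        return rec

    def update_config(self, **changes) -> None:
        """Change design parameters; only allowed before the first inclusion."""
        if self.status != "setup":
            raise ConfigFrozenError(
                "study parameters can no longer be modified after the first "
                "patient is included"
            )
        self.design = replace(
            self.design, config=replace(self.design.config, **changes)
        )

    def update_pending(
        self, patient_id: int, outcome: int | None, followup: float | None = None
    ) -> None:
        """Resolve a pending outcome, or extend a TITE follow-up."""
        rec = self._find(patient_id)
        cfg = self.design.config
        if not rec.pending and not cfg.is_tite:
            raise ValueError(
                "record already resolved; use modify_patient for corrections"
            )
        if followup is not None:
            if rec.followup is not None and followup < rec.followup:
                raise ValueError("follow-up cannot decrease")
            T = cfg.observation_window_T
            if T is not None and followup > T:
                raise ValueError("follow-up exceeds the observation window")
        new = PatientRecord(
            id=rec.id, dose_level=rec.dose_level, dose_value=rec.dose_value,
            outcome=outcome,
            followup=rec.followup if followup is None else followup,
        )
        self._replace_record(new)
        self._log("update", patient=patient_id,
                  outcome="pending" if outcome is None else outcome,
                  followup=new.followup)
        self._after_change()

    def modify_patient(self, patient_id: int, *, reason: str,
                       dose_level: int | None = None,
                       outcome: int | None = ...,
                       followup: float | None = ...) -> None:
        """Correct an existing record; requires an audited reason."""
        if not reason:
            raise ValueError("a correction reason is required")
        old = self._find(patient_id)
        lvl = old.dose_level if dose_level is None else dose_level
        new = PatientRecord(
            id=old.id, dose_level=lvl, dose_value=self.design.grid.dose(lvl),
            outcome=old.outcome if outcome is ... else outcome,
            followup=old.followup if followup is ... else followup,
        )
        self._replace_record(new)
        self._log("modify", patient=patient_id, reason=reason)
        self._after_change()

    def batch_include(self, rows) -> None:
        """Include several patients atomically (TITE designs).

        ``rows`` is an iterable of (dose_level, outcome, followup); any
        malformed row rejects the whole batch, leaving the state unchanged.
        """
        if not self.design.config.is_tite:
            raise ValueError("batch inclusion applies to TITE designs")
        rows = list(rows)
        K = self.design.skeleton.K
        T = self.design.config.observation_window_T
        for lvl, outcome, fu in rows:  # validate everything first
            if not 1 <= int(lvl) <= K:
                raise ValueError(f"dose level {lvl} outside [1, {K}]")
            if outcome not in (0, 1, None):
                raise ValueError(f"bad outcome {outcome!r}")
            if fu is not None and (fu < 0 or fu > T):
                raise ValueError(f"follow-up {fu} outside [0, T]")
        for lvl, outcome, fu in rows:
            self.include_patient(int(lvl), outcome, fu)

    def _find(self, patient_id: int) -> PatientRecord:
        for r in self.history:
            if r.id == patient_id:
                return r
        raise KeyError(f"no patient with id {patient_id}")

    def _replace_record(self, new: PatientRecord) -> None:
        recs = tuple(new if r.id == new.id else r for r in self.history)
        self.history = TrialHistory(records=recs)

    # -- summaries --------------------------------------------------------

    def summarize(self):
        """(per-patient table, per-dose table, escalation trajectory)."""
        T = self.design.config.T
        rows = [
            {
                "id": r.id,
                "dose_level": r.dose_level,
                "outcome": "pending" if r.pending else r.outcome,
                "followup": r.followup,
                "weight": r.weight(T) if (T is not None or not r.pending) else 0.0,
            }
            for r in self.history
        ]
        per_patient = pd.DataFrame(
            rows, columns=["id", "dose_level", "outcome", "followup", "weight"]
        )
        est = None
        rec = self._safe_recommend()
        if rec is not None and rec.estimates is not None:
            est = np.asarray(rec.estimates)
        dose_rows = []
        for lvl in range(1, self.design.skeleton.K + 1):
            treated = [r for r in self.history if r.dose_level == lvl]
            n = len(treated)
            ndlt = sum(1 for r in treated if r.outcome == 1)
            dose_rows.append(
                {
                    "dose_level": lvl,
                    "prior_prob": self.design.skeleton.probs[lvl - 1],
                    "n_treated": n,
                    "n_dlt": ndlt,
                    "observed_rate": ndlt / n if n else np.nan,
                    "model_estimate": est[lvl - 1] if est is not None else np.nan,
                }
            )
        per_dose = pd.DataFrame(dose_rows)
        trajectory = [(r.id, r.dose_level) for r in self.history]
        return per_patient, per_dose, trajectory

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        d = self.design
        cfg = d.config
        return {
            "schema_version": SCHEMA_VERSION,
            "status": self.status,
            "config": {
                "method": cfg.method,
                "theta": cfg.theta,
                "alpha": cfg.alpha,
                "observation_window_T": cfg.observation_window_T,
                "start_level": cfg.start_level,
                "no_skip": cfg.no_skip,
                "stopping": [asdict(r) for r in cfg.stopping],
                "run_in_cohort": cfg.run_in_cohort,
                "run_in_deescalate": cfg.run_in_deescalate,
                "estimate_mode": cfg.estimate_mode,
            },
            "skeleton": {
                "probs": list(d.skeleton.probs),
                "theta": d.skeleton.theta,
                "nu": d.skeleton.nu,
            },
            "model": {"family": d.model.family,
                      "fixed_intercept": d.model.fixed_intercept},
            "prior": {"family": d.prior.family, "params": list(d.prior.params)},
            "history": [
                {
                    "id": r.id, "dose_level": r.dose_level,
                    "dose_value": r.dose_value,
                    "outcome": r.outcome, "followup": r.followup,
                }
                for r in self.history
            ],
            "recommendations": list(self.recommendations),
            "audit": self.audit,
        }

    def save(self, path: str) -> None:
        """Atomic write (write-then-rename) of the trial JSON."""
        payload = json.dumps(self.to_dict(), indent=1)
        directory = os.path.dirname(os.path.abspath(path))
        fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        finally:
            if os.path.exists(tmp):
                os.unlink(tmp)

    @classmethod
    def from_dict(cls, doc: dict) -> "Trial":
        version = doc.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported trial schema version {version!r} "
                f"(this build reads version {SCHEMA_VERSION})"
            )
        c = doc["config"]
        cfg = DesignConfig(
            method=c["method"], theta=c["theta"], alpha=c["alpha"],
            observation_window_T=c["observation_window_T"],
            start_level=c["start_level"], no_skip=c["no_skip"],
            stopping=tuple(StoppingRule(**r) for r in c["stopping"]),
            run_in_cohort=c["run_in_cohort"],
            run_in_deescalate=c["run_in_deescalate"],
            estimate_mode=c["estimate_mode"],
        )
        sk = Skeleton(probs=np.array(doc["skeleton"]["probs"]),
                      theta=doc["skeleton"]["theta"], nu=doc["skeleton"]["nu"])
        model = ModelSpec(**doc["model"])
        prior = PriorSpec(doc["prior"]["family"], tuple(doc["prior"]["params"]))
        design = TrialDesign(config=cfg, skeleton=sk, model=model, prior=prior)
        hist = TrialHistory(records=tuple(
            PatientRecord(**r) for r in doc["history"]
        ))
        return cls(
            design=design, history=hist, status=doc["status"],
            audit=list(doc["audit"]),
            recommendations=list(doc["recommendations"]),
        )

    @classmethod
    def load(cls, path: str) -> "Trial":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replay_recommendations(self) -> list[int]:
        """Recompute the whole recommendation sequence from the raw history."""
        out = []
        partial = TrialHistory()
        from .designs import PendingOutcomeError

        for r in self.history:
            partial = partial.append(r)
            try:
                out.append(self.design.recommend(partial).level)
            except PendingOutcomeError:
                out.append(0)
        return out
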