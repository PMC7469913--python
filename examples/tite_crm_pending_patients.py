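"""TITE-CRM: enrolling while earlier patients are still on follow-up.

Patients without a resolved outcome contribute partial information through
the linear weight u/T (follow-up over observation window); a DLT always
carries full weight.  This lets accrual continue instead of suspending
between cohorts.
"""

from dosefind import (
    DesignConfig,
    StoppingRule,
    Trial,
    TrialDesign,
    calibrate_skeleton,
)

skeleton = calibrate_skeleton(theta=0.2, delta=0.05, nu=3, K=6)
config = DesignConfig(
    method="TITE_CRM", theta=0.2, start_level=3, observation_window_T=12.0,
    stopping=(StoppingRule("max_n", max_n=25),),
)
trial = Trial(design=TrialDesign(config=config, skeleton=skeleton))

trial.include_patient(3, outcome=0, followup=12.0)   # fully observed
trial.include_patient(4, outcome=None, followup=6.0)  # half the window
rec = trial.include_patient(4, outcome=None, followup=3.0)

per_patient, _, _ = trial.summarize()
print(per_patient.to_string(index=False))
print(f"\nnext recommended level: {rec.level}")

# weights: 1.0 for the resolved patient, 6/12 and 3/12 for the pending
# ones.  Updating a pending patient re-weights the likelihood:
trial.update_pending(2, outcome=None, followup=9.0)
print(f"after follow-up update (patient 2 at 9/12): weight "
      f"{trial.history.records[1].weight(12.0):.2f}, "
      f"recommendation {trial.recommend().level}")
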