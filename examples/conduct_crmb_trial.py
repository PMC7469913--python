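"""Conduct a Bayesian CRM trial patient by patient.

Each inclusion records the dose given and the DLT outcome; the posterior
of the model parameter is then updated and the next patient is assigned
the level whose estimated DLT probability is closest to the 20% target.
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
    method="CRMB", theta=0.2, start_level=3,
    stopping=(StoppingRule("max_n", max_n=25),),
)
trial = Trial(design=TrialDesign(config=config, skeleton=skeleton))

print(f"first patient treated at level {trial.recommend().level}")

# a short illustrative outcome sequence: clean escalation, then a DLT
outcomes = [(3, 0), (4, 0), (5, 0), (6, 0), (6, 1), (5, 0)]
for level, dlt in outcomes:
    rec = trial.include_patient(level, outcome=dlt)
    print(f"patient {len(trial.history):>2}: level {level}, DLT={dlt}"
          f" -> next recommended level {rec.level}")

per_patient, per_dose, trajectory = trial.summarize()
print("\nper-dose summary:")
print(per_dose.to_string(index=False,
                         float_format=lambda v: f"{v:.3f}"))

# After the DLT at level 6 the model steps back to level 5; the per-dose
# table shows treated counts, observed DLT rates and the current model
# estimate of P(DLT) at every level.
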