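"""Operating characteristics of CRMB under an assumed true toxicity curve.

Simulates repeated 25-patient trials where outcomes are drawn from true
per-level DLT probabilities, and summarises where the design lands its MTD
recommendation and how patients are allocated.  (The full reference run
uses 1000 replicates; 200 keeps this example quick.)
"""

import numpy as np

from dosefind import (
    DesignConfig,
    Scenario,
    StoppingRule,
    TrialDesign,
    calibrate_skeleton,
    run_batch,
)

skeleton = calibrate_skeleton(theta=0.2, delta=0.05, nu=3, K=6)
config = DesignConfig(
    method="CRMB", theta=0.2, start_level=3,
    stopping=(StoppingRule("max_n", max_n=25),),
)
design = TrialDesign(config=config, skeleton=skeleton)

scenario = Scenario(
    true_probs=np.array([0.003, 0.016, 0.047, 0.107, 0.196, 0.305]),
    n=25, n_trials=200, seed=42,
)
oc = run_batch(design, scenario)

print(oc.to_frame().to_string(index=False))
print()
print(oc.summary_frame().to_string(index=False))

# "mtd_pct" is the share of trials recommending each level as the MTD;
# level 5 (true P(DLT)=0.196, closest to the 20% target) should dominate.
# "avg_patients" shows the allocation; pct_over is the average fraction
# of patients treated above the true MTD.
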