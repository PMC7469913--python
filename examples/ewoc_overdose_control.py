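"""EWOC: pick the highest dose whose overdose probability stays below alpha.

The two-parameter logistic model is reparameterised as (rho0, gamma): the
DLT probability at the lowest dose and the MTD on the dose axis.  The
design recommends the highest level x with P(MTD <= x | data) <= alpha,
so at most a fraction alpha of patients is expected above the MTD.
"""

import numpy as np

from dosefind import (
    DesignConfig,
    PatientRecord,
    TrialDesign,
    TrialHistory,
    calibrate_skeleton,
    ewoc_next_dose,
    ewoc_posterior,
)

skeleton = calibrate_skeleton(theta=0.2, delta=0.05, nu=3, K=6)
design = TrialDesign(
    config=DesignConfig(method="EWOC", theta=0.2, alpha=0.25, start_level=3),
    skeleton=skeleton,
)
grid = design.grid

pairs = [(3, 0), (4, 0), (5, 0), (5, 1), (4, 0), (4, 0)]
history = TrialHistory(tuple(
    PatientRecord(j + 1, lvl, grid.dose(lvl), outcome=y)
    for j, (lvl, y) in enumerate(pairs)
))

posterior = ewoc_posterior(history, grid, theta=0.2)
print("level  P(MTD <= x | data)")
for level, x in enumerate(grid.standardized_doses, start=1):
    print(f"{level:>5}  {posterior.prob_overdose(x):.3f}")

for alpha in (0.10, 0.25, 0.40):
    rec = ewoc_next_dose(posterior, alpha, grid, no_skip=True,
                         current_max_tried=5)
    print(f"alpha = {alpha:.2f} -> recommend level {rec.level}")

# Lower feasibility bounds give more conservative recommendations: the
# recommended level is nondecreasing in alpha.
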