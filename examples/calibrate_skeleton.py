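"""Calibrate a skeleton of prior DLT probabilities.

The indifference-interval construction anchors the prior-MTD level at the
target toxicity and spaces the remaining levels one indifference interval
[theta - delta, theta + delta] apart on the model scale.
"""

import numpy as np

from dosefind import calibrate_skeleton

skeleton = calibrate_skeleton(theta=0.2, delta=0.05, nu=3, K=6)

print("level  prior P(DLT)")
for level, p in enumerate(skeleton.probs, start=1):
    marker = "  <- prior MTD (= target 0.2)" if level == skeleton.nu else ""
    print(f"{level:>5}  {p:.3f}{marker}")

# The six values are the working prior for every design in this package:
# level 3 sits exactly at the 20% target, and each neighbouring level is
# one indifference interval (0.15 - 0.25) away under the empiric model.
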