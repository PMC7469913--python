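import numpy as np
import pytest

from dosefind import (
    DesignConfig,
    ModelSpec,
    PatientRecord,
    StoppingRule,
    TrialDesign,
    TrialHistory,
    calibrate_skeleton,
)

MOTIVATING_TRUE_PROBS = np.array([0.003, 0.016, 0.047, 0.107, 0.196, 0.305])


@pytest.fixture(scope="session")
def skeleton():
    """The six-level skeleton anchored at theta=0.2 on level 3."""
    return calibrate_skeleton(theta=0.2, delta=0.05, nu=3, K=6)


@pytest.fixture(scope="session")
def empiric():
    return ModelSpec("empiric")


@pytest.fixture()
def crmb_design(skeleton):
    cfg = DesignConfig(
        method="CRMB", theta=0.2, start_level=3,
        stopping=(StoppingRule("max_n", max_n=25),),
    )
    return TrialDesign(config=cfg, skeleton=skeleton)


@pytest.fixture()
def ewoc_design(skeleton):
    cfg = DesignConfig(
        method="EWOC", theta=0.2, alpha=0.25, start_level=3,
        stopping=(StoppingRule("max_n", max_n=25),),
    )
    return TrialDesign(config=cfg, skeleton=skeleton)


def make_history(rng, grid, n, p_dlt=0.25, T=None):
    """A random fully observed history on the given dose grid."""
    records = []
    for j in range(1, n + 1):
        lvl = int(rng.integers(1, grid.K + 1))
        y = int(rng.random() < p_dlt)
        records.append(
            PatientRecord(j, lvl, grid.dose(lvl), outcome=y,
                          followup=T if T is not None else None)
        )
    return TrialHistory(tuple(records))
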