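import numpy as np
import pandas as pd
import pytest

from gutdea import synth
from gutdea.dea import DEAProblem

COHORT_10K_SEED = 20240927


@pytest.fixture(scope="session")
def cohort_10k() -> pd.DataFrame:
    """One large synthetic cohort shared by the fidelity checks."""
    cfg = synth.default_config()
    cfg.n = 10_000
    cfg.seed = COHORT_10K_SEED
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cfg():
    return synth.default_config()


@pytest.fixture()
def problem_3dmu() -> DEAProblem:
    """Hand-solvable 1-input/1-output VRS case: C sits below the A-B segment."""
    return DEAProblem(X=[[1.0], [3.0], [2.0]], Y=[[1.0], [4.0], [2.0]])


# Published worked example of the lack-of-output decomposition for the most
# inefficient participant: per-peer lambda, raw outputs, lambda-weighted
# outputs, column sums, and the unit's own outputs.  Output order:
# Bacillus, Lactobacillus, Lactococcus, Streptococcus, Faith's PD.
# Peer 6's lambda is quoted as 0.041 but its weighted row implies 0.0041
# (a documented scale typo); the corrected value is used where the weights
# must form a convex combination.
WORKED_OUTPUT_NAMES = [
    "bacillus",
    "lactobacillus",
    "lactococcus",
    "streptococcus",
    "faith_pd",
]
WORKED_LAMBDAS = np.array([0.239, 0.273, 0.334, 0.088, 0.062, 0.0041])
WORKED_PEER_OUTPUTS = np.array(
    [
        [0.277, 3.702, 3.669, 0.308, 6.878],
        [0.277, 0.616, 0.067, 0.820, 6.357],
        [0.277, 2.063, 0.067, 0.308, 6.218],
        [1.739, 3.269, 0.067, 0.308, 7.529],
        [1.981, 2.611, 0.067, 0.308, 6.084],
        [1.038, 2.747, 0.067, 0.308, 7.017],
    ]
)
WORKED_WEIGHTED = np.array(
    [
        [0.066, 0.884, 0.876, 0.073, 1.643],
        [0.076, 0.168, 0.018, 0.224, 1.737],
        [0.092, 0.688, 0.022, 0.103, 2.074],
        [0.153, 0.287, 0.006, 0.027, 0.661],
        [0.124, 0.163, 0.004, 0.019, 0.380],
        [0.004, 0.011, 0.000, 0.001, 0.029],
    ]
)
WORKED_COMPOSITE = np.array([0.515, 2.202, 0.927, 0.448, 6.524])
WORKED_OWN = np.array([0.277, 0.616, 0.067, 0.308, 3.509])
WORKED_LACK = np.array([0.238, 1.586, 0.860, 0.140, 3.015])


@pytest.fixture()
def worked_example():
    return {
        "names": WORKED_OUTPUT_NAMES,
        "lambdas": WORKED_LAMBDAS,
        "peer_outputs": WORKED_PEER_OUTPUTS,
        "weighted": WORKED_WEIGHTED,
        "composite": WORKED_COMPOSITE,
        "own": WORKED_OWN,
        "lack": WORKED_LACK,
    }
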