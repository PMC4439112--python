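import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ripseed.scoring import AbundanceMatrix
from ripseed.synthetic_data import SimulationConfig, simulate_study

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

STUDY_SEED = 1


@pytest.fixture(scope="session")
def noisy_study():
    """Full-size simulated study at the default (noisy) conditions."""
    return simulate_study(SimulationConfig(rng_seed=STUDY_SEED))


@pytest.fixture(scope="session")
def noisefree_study():
    """Full-size simulated study with replicate noise switched off."""
    return simulate_study(
        SimulationConfig(replicate_noise_sd=0.0, rng_seed=STUDY_SEED)
    )


@pytest.fixture(scope="session")
def small_study():
    """A quick 400-gene study for I/O and CLI tests."""
    return simulate_study(
        SimulationConfig(n_genes=400, n_true_targets=40, rng_seed=7)
    )


@pytest.fixture()
def toy_matrix_design():
    """Four genes x eight samples (2 replicates per class), hand-valued."""
    design = pd.DataFrame(
        {
            "sample_id": [
                "expression_treatment_1", "expression_treatment_2",
                "expression_control_1", "expression_control_2",
                "rip_treatment_1", "rip_treatment_2",
                "rip_control_1", "rip_control_2",
            ],
            "assay": ["expression"] * 4 + ["rip"] * 4,
            "condition": ["treatment", "treatment", "control", "control"] * 2,
            "replicate": [1, 2, 1, 2] * 2,
        }
    )
    values = pd.DataFrame(
        {
            "expression_treatment_1": [2.0, 4.0, 1.0, 5.0],
            "expression_treatment_2": [2.0, 4.0, 1.0, 5.0],
            "expression_control_1": [6.0, 4.0, 1.0, 5.0],
            "expression_control_2": [6.0, 4.0, 1.0, 5.0],
            "rip_treatment_1": [9.0, 8.0, 1.0, 5.0],
            "rip_treatment_2": [9.0, 8.0, 1.0, 5.0],
            "rip_control_1": [2.0, 4.0, 1.0, 5.0],
            "rip_control_2": [2.0, 4.0, 1.0, 5.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    return AbundanceMatrix(values), design
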