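import numpy as np
import pytest

from myelodiv.deconvolution import FractionProfile
from myelodiv.synthetic_cohort import SimulationConfig, _ground_truth, simulate_bulk


@pytest.fixture
def small_config():
    """Small, fast cohort configuration used across tests."""
    return SimulationConfig(
        n_subgroups=4,
        n_marker_genes_per_subgroup=5,
        n_background_genes=30,
        n_cells_per_subgroup=25,
        n_bulk_samples=60,
        n_surrogate_genes=3,
        n_module_noise_genes=20,
        seed=7,
    )


@pytest.fixture
def truth_and_bulk(small_config):
    truth = _ground_truth(small_config)
    bulk = simulate_bulk(small_config, truth)
    return truth, bulk


def fractions_from_truth(truth) -> FractionProfile:
    return FractionProfile(
        truth.sample_ids,
        truth.subgroup_ids,
        truth.true_fractions,
        np.zeros(len(truth.sample_ids), bool),
    )
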