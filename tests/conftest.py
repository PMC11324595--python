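import numpy as np
import pytest

from bwaspipe.synthetic import (
    CircuitEffect,
    SimulationConfig,
    block_cluster,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_effect_config(seed=0, r_cn=0.6, r_scd=0.2, n_per_group=(40, 40),
                       n_timepoints=200):
    """10x10x6 grid, two 30-voxel blocks in separate atlas slabs."""
    return SimulationConfig(
        grid_shape=(10, 10, 6),
        n_timepoints=n_timepoints,
        n_subjects_per_group=n_per_group,
        signal_clusters={
            "A": block_cluster((0, 2, 1), (2, 5, 3)),
            "B": block_cluster((8, 2, 1), (2, 5, 3)),
        },
        circuit_effects=[CircuitEffect("A", "B", r_cn, r_scd)],
        seed=seed,
    )


def make_null_config(seed=0, n_voxels_shape=(5, 4, 3), n_timepoints=150,
                     n_per_group=(25, 25)):
    """Null cohort: clusters exist but carry no group difference."""
    return SimulationConfig(
        grid_shape=n_voxels_shape,
        n_timepoints=n_timepoints,
        n_subjects_per_group=n_per_group,
        signal_clusters={
            "A": block_cluster((0, 0, 0), (2, 2, 2)),
            "B": block_cluster((3, 2, 1), (2, 2, 2)),
        },
        circuit_effects=[CircuitEffect("A", "B", 0.4, 0.4)],
        seed=seed,
    )


@pytest.fixture(scope="session")
def effect_cohort():
    """One generated cohort with a strong injected circuit effect."""
    return generate_cohort(make_effect_config(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(make_null_config(seed=11))
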