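import numpy as np
import pytest

from fgconn.cohort import (
    CohortConfig,
    make_family_structure,
    make_parcellation,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 subjects, 6 regions x 10 vertices, 2 x 120 timepoints."""
    config = CohortConfig(
        family_histogram={1: 4, 2: 5, 3: 2},
        n_vertices=60,
        n_regions=6,
        n_timepoints_per_run=120,
        seed=42,
    )
    families = make_family_structure(config.family_histogram, seed=1)
    parcellation = make_parcellation(config.n_vertices, config.n_regions, seed=2)
    subjects, traits, transforms = simulate_cohort(config, families, parcellation)
    return {
        "config": config,
        "families": families,
        "parcellation": parcellation,
        "subjects": subjects,
        "traits": traits,
        "transforms": transforms,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
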