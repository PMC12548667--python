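import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

import connrel as cr


@pytest.fixture(scope="session")
def toy_parcellation():
    """6 nodes, two networks of 3."""
    return cr.make_parcellation(6, [3, 3], "toy")


@pytest.fixture(scope="session")
def parcellation20():
    return cr.make_parcellation(20, [5, 5, 5, 5], "toy20")


@pytest.fixture(scope="session")
def quiet_spec():
    """Small cohort without motion or nuisance structure."""
    return cr.CohortSpec(
        n_subjects_per_group={"groupA": 5, "groupB": 4},
        n_volumes=80,
        motion_fd_mean_by_group={"groupA": 0.0, "groupB": 0.0},
        spike_rate=0.0,
        nuisance_amplitudes={"global": 0.0, "wm": 0.0, "csf": 0.0},
        seed=11,
    )


@pytest.fixture(scope="session")
def quiet_cohort(quiet_spec, parcellation20):
    runs, gt = cr.simulate_cohort(quiet_spec, parcellation20)
    return runs, gt


@pytest.fixture(scope="session")
def noisy_run(parcellation20):
    """One realistic run: motion, spikes and nuisance components present."""
    spec = cr.CohortSpec(
        n_subjects_per_group={"groupA": 1},
        n_volumes=300,
        seed=21,
    )
    runs, _ = cr.simulate_cohort(spec, parcellation20)
    return runs[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
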