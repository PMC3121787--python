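import numpy as np
import pytest

import isoturn as it

#: Blood sampling schedule of the emulated experiment.
SCHEDULE = np.array([0, 4, 7, 11, 15, 19, 23, 28, 35, 55, 70], dtype=float)

#: Canonical one-compartment parameters with a 9-day half-life
#: (phi3 = ln(ln 2 / 9)).
PHI3_9D = float(np.log(np.log(2) / 9.0))


@pytest.fixture
def canonical_params():
    return it.OneCompartmentParams(16.0, 8.0, PHI3_9D)


@pytest.fixture
def schedule():
    return SCHEDULE.copy()


@pytest.fixture
def plasma_truth():
    return it.default_trajectory_truth("plasma", "d13C")


@pytest.fixture
def shifted_dataset(plasma_truth):
    """One simulated diet-shifted arm (20 individuals, full schedule)."""
    return it.simulate_trajectories(it.PopulationSpec(20, 20), plasma_truth, seed=42)
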