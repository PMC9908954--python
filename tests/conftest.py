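"""Shared fixtures: leg geometry, footpaths, and cached protocol runs."""

import numpy as np
import pytest

from cssim.experiments import ExperimentSpec, run_experiment
from cssim.kinematics import default_leg, generate_footpath, path_to_angles
from cssim.synthetic_leg import SegmentSection

N_STEPS = 20
SEED = 1


@pytest.fixture(scope="session")
def leg():
    return default_leg()


@pytest.fixture(scope="session")
def section():
    return SegmentSection()


@pytest.fixture(scope="session")
def footpath():
    return generate_footpath()


@pytest.fixture(scope="session")
def footpath_angles(footpath, leg):
    return path_to_angles(footpath, leg)


@pytest.fixture(scope="session")
def stepping_results():
    """20-step treadmill runs at the three load conditions, fixed seed."""
    return {
        m: run_experiment(
            ExperimentSpec("stepping_load", {"added_mass": m, "n_steps": N_STEPS}, seed=SEED)
        )
        for m in (0.0, 0.5, 1.0)
    }


@pytest.fixture(scope="session")
def slip_result():
    return run_experiment(ExperimentSpec("slip", {"n_steps": N_STEPS}, seed=SEED))


@pytest.fixture(scope="session")
def transient_result():
    return run_experiment(ExperimentSpec("transient_load", {"n_steps": N_STEPS}, seed=SEED))


def window_mask(t, events, label):
    """Boolean mask of samples inside any event window with ``label``."""
    mask = np.zeros(len(t), dtype=bool)
    for _, ev in events[events.label == label].iterrows():
        mask |= (t >= ev.t0) & (t <= ev.t1)
    return mask
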