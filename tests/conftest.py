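import numpy as np
import pytest

import hfnca as h


@pytest.fixture(scope="session")
def methyl_frame():
    return h.make_idealized_geometry("methyl")


@pytest.fixture(scope="session")
def methyl_topology(methyl_frame):
    return h.build_topology(methyl_frame)


@pytest.fixture(scope="session")
def methyl_trajectory(methyl_frame):
    """Short synthetic methyl trajectory with the default oscillations."""
    truth = h.default_ground_truth("methyl", seed=11)
    return h.simulate_trajectory(methyl_frame, truth, 120, seed=11)


@pytest.fixture(scope="session")
def methyl_features(methyl_trajectory, methyl_topology):
    series = h.evaluate_series(methyl_trajectory, methyl_topology)
    return h.make_feature_table(series)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
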