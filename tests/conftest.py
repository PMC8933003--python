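import numpy as np
import pytest

import polycolo as pc


@pytest.fixture()
def small_sim_config():
    """25 um^2 field at the default cluster densities — fast but non-trivial."""
    return pc.SimulationConfig(roi_width_nm=5000.0, roi_height_nm=5000.0, seed=11)


@pytest.fixture()
def segmented_pair(small_sim_config):
    """Two segmented channel maps plus their ground truth."""
    t1, t2, truth = pc.simulate_localizations(small_sim_config)
    roi = (0.0, 0.0, small_sim_config.roi_width_nm, small_sim_config.roi_height_nm)
    m1 = pc.segment_clusters(t1, roi=roi, channel="ch1")
    m2 = pc.segment_clusters(t2, roi=roi, channel="ch2")
    return m1, m2, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
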