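import numpy as np
import pytest

from trend.benchmarks import three_region_benchmark
from trend.graph import NetworkGraph
from trend.params import ConnectivityParams, NeuronalParams
from trend.stimulus import StimulusDesign, default_block_design


@pytest.fixture(scope="session")
def three_region():
    return three_region_benchmark()


@pytest.fixture(scope="session")
def three_region_obs(three_region):
    """Noiseless BOLD generated by the P-DCM forward model."""
    return three_region.generate()


@pytest.fixture(scope="session")
def two_region():
    """Small 2-region instance (one driven region feeding the other)."""
    a_mask = np.array([[0, 0], [1, 0]], dtype=np.int8)
    c_mask = np.array([[1], [0]], dtype=np.int8)
    graph = NetworkGraph(2, a_mask, c_mask=c_mask)
    A = np.zeros((2, 2))
    A[1, 0] = 0.4
    neuronal = NeuronalParams.default(2)
    conn = ConnectivityParams(A, [], c_mask.astype(float))
    design = default_block_design(n_driving=1, total_duration=120.0)
    return graph, neuronal, conn, design


@pytest.fixture()
def single_region_design():
    return StimulusDesign(
        n_channels=1,
        channel_role=["driving"],
        events=[[(10.0, 40.0, 1.0)]],
        total_duration=120.0,
        dt_sim=0.01,
    )


@pytest.fixture()
def single_region_setup(single_region_design):
    graph = NetworkGraph(1, np.zeros((1, 1)), c_mask=np.ones((1, 1), dtype=np.int8))
    neuronal = NeuronalParams.default(1)
    conn = ConnectivityParams(np.zeros((1, 1)), [], np.ones((1, 1)))
    return graph, neuronal, conn, single_region_design
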