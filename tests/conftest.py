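import numpy as np
import pytest

from tmwsnet.network import NetConfig
from tmwsnet.synthetic import PlotSpec, TreeSpec, sample_plot


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tree_spec():
    return TreeSpec(trunk_height=5.0, trunk_radius=0.15,
                    crown_semi_axes=(2.0, 2.0, 3.0), crown_base_height=5.0)


@pytest.fixture
def small_plot(tree_spec):
    """One coarse-segmented sample of ~3000 points with both classes."""
    return sample_plot(PlotSpec(tree=tree_spec, n_tree_points=2000,
                                n_ground_points=600, n_neighbor_points=400,
                                seed=3))


@pytest.fixture
def tiny_net_cfg():
    """A network small enough for CPU unit tests."""
    return NetConfig(channels=(8, 8, 8, 8), blocks_per_stage=1, G=8, k=8,
                     n_heads=2, L=1, M=1, d_state=4, seed=0,
                     grid_sizes=(0.05, 0.1, 0.2, 0.4))
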