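import numpy as np
import pytest

from emrl.maze_env import build_tunnel_maze
from emrl.observation_codec import ProjectedCodec, StateEncoder


@pytest.fixture(scope="session")
def maze1():
    return build_tunnel_maze(1)


@pytest.fixture(scope="session")
def maze4():
    return build_tunnel_maze(4)


@pytest.fixture(scope="session")
def encoder1(maze1):
    return StateEncoder(maze1, dim=64, seed=7)


@pytest.fixture(scope="session")
def codec1(encoder1):
    return ProjectedCodec(encoder1, projection_seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
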