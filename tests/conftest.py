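import numpy as np
import pytest

from dyadsim import AgentParams, PlantConfig, build_dyad


@pytest.fixture
def plant():
    return PlantConfig(M=1.0, dt=0.01)


@pytest.fixture
def agents():
    return (AgentParams(label="agent1"), AgentParams(label="agent2"))


@pytest.fixture
def dyad(agents, plant):
    return build_dyad(agents[0], agents[1], plant)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stable_system(rng, n=4, m=1):
    """A random Schur-stable discrete system with PSD state weights."""
    A = rng.normal(size=(n, n))
    A *= 0.9 / max(1e-9, np.max(np.abs(np.linalg.eigvals(A))))
    B = rng.normal(size=(n, m))
    q = rng.uniform(0.0, 2.0, size=n)
    Q = np.diag(q)
    R = np.eye(m) * rng.uniform(0.5, 2.0)
    return A, B, Q, R
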