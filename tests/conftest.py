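import numpy as np
import pytest

from synglove import JOINT_ORDER, N_DOF, SynergyPrior


def random_spd_prior(rng: np.random.Generator, scale: float = 10.0) -> SynergyPrior:
    """A random nonsingular 19x19 synergy prior (degrees^2)."""
    A = rng.standard_normal((N_DOF, N_DOF))
    cov = scale * (A @ A.T / N_DOF + 0.1 * np.eye(N_DOF))
    return SynergyPrior(mu=rng.uniform(-30, 60, N_DOF), cov=cov)


def random_joint_subset(rng: np.random.Generator, m: int) -> tuple[str, ...]:
    idx = np.sort(rng.choice(N_DOF, size=m, replace=False))
    return tuple(JOINT_ORDER[i] for i in idx)


def random_spd(rng: np.random.Generator, m: int, scale: float = 1.0) -> np.ndarray:
    A = rng.standard_normal((m, m))
    return scale * (A @ A.T / m + 0.1 * np.eye(m))


@pytest.fixture
def rng():
    return np.random.default_rng(1905)
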