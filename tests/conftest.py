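import numpy as np
import pytest

from akronkf import UnderdeterminedSystem


def make_planted_system(rng, n, p, n_nonzero, mag_range=(1.0, 2.0), noise_sigma=0.0):
    """Random full-rank system with a planted sparse solution.

    Returns ``(system, x0)`` where ``x0`` has ``n_nonzero`` entries with
    magnitudes in ``mag_range`` (random signs) and ``y = Phi x0 (+ noise)``.
    """
    while True:
        phi = rng.standard_normal((n, p))
        if np.linalg.matrix_rank(phi) == n:
            break
    support = rng.choice(p, size=n_nonzero, replace=False)
    x0 = np.zeros(p)
    x0[support] = rng.uniform(*mag_range, size=n_nonzero) * rng.choice(
        [-1.0, 1.0], size=n_nonzero
    )
    y = phi @ x0
    eps = 0.0
    if noise_sigma > 0:
        v = rng.normal(0.0, noise_sigma, size=n)
        y = y + v
        eps = float(np.linalg.norm(v))
    return UnderdeterminedSystem(phi, y, noise_eps=eps), x0


@pytest.fixture
def planted_system():
    return make_planted_system


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
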