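import numpy as np
import pytest

from trajtensor import ExpressionMatrix, TemporalTensor


def unit(v):
    return v / np.linalg.norm(v)


def rank1_tensor(m=20, n=15, n_times=30, lam=2.0, xi=None, seed=0,
                 noise_sd=0.0):
    """Noiseless (or noisy) rank-1 tensor on a common grid, with its truth."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_times)
    a = unit(rng.normal(size=m))
    b = unit(rng.normal(size=n))
    xi = xi or (lambda t: np.ones_like(t))
    values = [lam * a[i] * np.outer(xi(grid), b) for i in range(m)]
    if noise_sd > 0:
        values = [v + rng.normal(0.0, noise_sd, size=v.shape) for v in values]
    tensor = TemporalTensor([f"s{i}" for i in range(m)],
                            [f"g{j}" for j in range(n)],
                            [grid] * m, values)
    return tensor, {"a": a, "b": b, "xi": xi, "lam": lam, "grid": grid}


@pytest.fixture
def small_expression():
    rng = np.random.default_rng(7)
    values = rng.normal(size=(6, 4))
    return ExpressionMatrix(values,
                            [f"c{i}" for i in range(6)],
                            [f"g{j}" for j in range(4)])


@pytest.fixture
def simple_tensor():
    """3 samples x 2 genes, irregular grids, hand-set values."""
    return TemporalTensor(
        ["s1", "s2", "s3"],
        ["g1", "g2"],
        [np.array([0.1, 0.2]), np.array([0.5]), np.array([0.3, 0.6, 0.9])],
        [np.array([[1.0, 2.0], [3.0, 4.0]]),
         np.array([[5.0, 6.0]]),
         np.array([[7.0, 8.0], [9.0, 10.0], [11.0, 12.0]])],
    )
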