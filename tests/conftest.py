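import numpy as np
import pytest


@pytest.fixture
def toy_pairs():
    """Fixed 3-pair (6 individual) dataset for exact two-route checks."""
    y = np.array([[0.3, -1.2], [1.5, 0.7], [-0.4, 0.9]])
    g = np.array([[0, 1], [2, 1], [1, 0]])
    z = np.array([[0.1, -0.5], [1.0, 0.2], [-0.3, 0.8]])
    return y, g, z


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def dense_sigma(n_pairs: int, r: float) -> np.ndarray:
    """Block-diagonal pair covariance with unit diagonal and off-diagonal r."""
    out = np.zeros((2 * n_pairs, 2 * n_pairs))
    for i in range(n_pairs):
        out[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = [[1.0, r], [r, 1.0]]
    return out


def dense_symmetric_score(y2: np.ndarray, g2: np.ndarray, X2: np.ndarray, W: np.ndarray) -> float:
    """Independent dense-matrix route for the GLS score statistic.

    T = N (g'Py)^2 / ((g'Pg)(y'Py)),  P = W^-1 - W^-1 X (X'W^-1 X)^-1 X'W^-1,
    with family-major flattening of the (n, 2) arrays.
    """
    y = np.asarray(y2, float).ravel()
    g = np.asarray(g2, float).ravel()
    X = X2
    Wi = np.linalg.inv(W)
    P = Wi - Wi @ X @ np.linalg.solve(X.T @ Wi @ X, X.T @ Wi)
    return len(y) * float(g @ P @ y) ** 2 / (float(g @ P @ g) * float(y @ P @ y))
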