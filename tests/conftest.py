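import numpy as np
import pytest

from ndfawm import ModelSpec


@pytest.fixture
def three_block_spec():
    """Heterogeneous-theta 3-community spec with well-separated blocks."""
    rng = np.random.default_rng(42)
    n, K = 30, 3
    labels = np.repeat([1, 2, 3], n // K)
    theta = rng.uniform(0.3, 1.0, n)
    P = np.array([[1.0, 0.2, 0.3],
                  [0.2, 0.8, 0.2],
                  [0.3, 0.2, 0.9]])
    return ModelSpec(n=n, K=K, labels=labels, theta=theta, P=P, family="poisson")


@pytest.fixture
def signed_toy():
    """Fixed 6-node symmetric matrix with mixed-sign weights."""
    A = np.array([
        [0.0,  2.0, -1.0,  0.0,  0.5,  0.0],
        [2.0,  0.0,  1.5, -0.5,  0.0,  0.0],
        [-1.0, 1.5,  0.0,  0.0, -2.0,  1.0],
        [0.0, -0.5,  0.0,  0.0,  3.0, -1.5],
        [0.5,  0.0, -2.0,  3.0,  0.0,  0.25],
        [0.0,  0.0,  1.0, -1.5,  0.25, 0.0],
    ])
    return A


def all_partitions(n, max_blocks):
    """Every set partition of range(n) into at most max_blocks blocks,
    as 1-based label vectors (restricted-growth enumeration)."""
    out = []

    def grow(prefix, used):
        if len(prefix) == n:
            out.append(np.array(prefix, dtype=np.int64))
            return
        for lab in range(1, min(used + 1, max_blocks) + 1):
            grow(prefix + [lab], max(used, lab))

    grow([1], 1)
    return out


def brute_force_modularity(A, labels):
    """Literal evaluation of the signed-modularity double sums over all
    ordered pairs (i, j), including i = j."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    Ap = np.maximum(0.0, A)
    Am = np.maximum(0.0, -A)
    dp = Ap.sum(axis=1)
    dm = Am.sum(axis=1)
    two_mp = dp.sum()
    two_mm = dm.sum()
    qp = qm = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            if two_mp > 0:
                qp += (Ap[i, j] - dp[i] * dp[j] / two_mp) / two_mp
            if two_mm > 0:
                qm += (Am[i, j] - dm[i] * dm[j] / two_mm) / two_mm
    return (two_mp * qp - two_mm * qm) / (two_mp + two_mm)
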