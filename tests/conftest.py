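import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260412)


def make_sparse_instance(seed, n_rows=20, n_cols=8, sparsity=2, noise=0.0):
    """Random unit-column Gaussian design with a sparse +/-1 coefficient
    vector; the standard small recovery instance used across the suite."""
    rng = np.random.default_rng(seed)
    Psi = rng.standard_normal((n_rows, n_cols))
    Psi /= np.linalg.norm(Psi, axis=0)
    support = np.sort(rng.choice(n_cols, size=sparsity, replace=False))
    a = np.zeros(n_cols)
    a[support] = rng.choice([-1.0, 1.0], size=sparsity)
    z = Psi @ a
    if noise > 0:
        z = z + noise * rng.standard_normal(n_rows)
    return Psi, a, set(int(q) for q in support), z
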