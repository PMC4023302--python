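import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gsnca import ExpressionDataset


def make_dataset(p=6, n1=5, n2=5, seed=0, scale=1.0, shift=0.0):
    """Random two-condition dataset with labelled genes/samples."""
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((p, n1 + n2)) * scale + shift
    return ExpressionDataset(
        values=values,
        gene_ids=[f"g{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n1 + n2)],
        condition=["A"] * n1 + ["B"] * n2,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


def power_iteration(M, tol=1e-14, max_iter=100000):
    """Independent leading-eigenpair oracle for symmetric non-negative M."""
    M = np.asarray(M, dtype=float)
    v = np.ones(M.shape[0]) / np.sqrt(M.shape[0])
    lam = 0.0
    for _ in range(max_iter):
        nv = M @ v
        nlam = np.linalg.norm(nv)
        nv = nv / nlam
        if np.linalg.norm(nv - v) < tol:
            return nlam, nv
        v, lam = nv, nlam
    return lam, v
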