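"""Covariance designs and Monte-Carlo power/size estimation.

Two block-correlated multivariate-normal designs probe complementary
alternatives.  In the first, condition 1 is spherical (Sigma1 = I) while
condition 2 carries one block of round(gamma * p) genes pairwise correlated
at r: the detection call gamma is the fraction of truly coexpressed genes
and r their correlation strength.  With gamma = 1 both conditions share the
uniform leading eigenvector, so the weight-based test is blind to r by
design.  In the second, both conditions tile the diagonal with blocks of
size round(beta * p); within each block round(gamma * beta * p) genes are
correlated at r, occupying the block's upper-left corner in condition 1 and
its lower-right corner in condition 2, so the coexpressed membership (not
the average correlation) shifts between conditions.  When gamma > 0.5 the
two memberships overlap in 2*round(gamma*beta*p) - round(beta*p) genes per
block; at gamma <= 0.5 they are exclusive.

Datasets are drawn as N(0, Sigma) via Cholesky factors; rejection rates are
the fraction of independent replicate datasets whose permutation p-value
falls at or below alpha, with a binomial standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import as_rng, permutation_test
from .dataset import ExpressionDataset

__all__ = [
    "SimulationScenario",
    "RejectionRate",
    "scenario1_covariances",
    "scenario2_covariances",
    "scenario2_structure",
    "sample_dataset",
    "estimate_rejection_rate",
    "write_scenario",
    "read_scenario",
]


def _round_half_up(x: float) -> int:
    """Round half away from zero (for non-negative design fractions)."""
    return int(np.floor(x + 0.5))


@dataclass
class SimulationScenario:
    """Parameter bundle for one covariance design.

    scenario : {'null', 'one', 'two'}
    p : genes per set; gamma : detection call in (0, 1]; r : intergene
    correlation in [0, 1); beta : block fraction (scenario two only);
    n_per_group : samples per condition; background : off-block correlation
    (scenario two, default 0).
    """

    scenario: str
    p: int
    gamma: float = 1.0
    r: float = 0.0
    beta: float | None = None
    n_per_group: int = 20
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.scenario not in ("null", "one", "two"):
            raise ValueError(f"scenario must be 'null', 'one' or 'two', got {self.scenario!r}")
        if self.p < 2:
            raise ValueError("p must be at least 2")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be at least 3")
        if self.scenario == "two" and self.beta is None:
            raise ValueError("scenario two requires beta")

    def covariances(self) -> tuple[np.ndarray, np.ndarray]:
        if self.scenario == "null":
            eye = np.eye(self.p)
            return eye, eye.copy()
        if self.scenario == "one":
            return scenario1_covariances(self.p, self.gamma, self.r)
        return scenario2_covariances(self.p, self.beta, self.gamma, self.r, self.background)


def scenario1_covariances(p: int, gamma: float, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Spherical condition 1 vs one coexpressed block in condition 2.

    Sigma1 = I; Sigma2 = I except that the first round(gamma*p) genes are
    pairwise correlated at r.  gamma = 1 gives the equicorrelated matrix.
    """
    if not (0 < gamma <= 1):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    if not (0 <= r < 1):
        raise ValueError(f"r must be in [0, 1), got {r}")
    k = _round_half_up(gamma * p)
    if k < 1:
        raise ValueError(f"gamma*p rounds to {k}; need at least 1 coexpressed gene")
    S1 = np.eye(p)
    S2 = np.eye(p)
    S2[:k, :k] = r
    np.fill_diagonal(S2, 1.0)
    return S1, S2


def scenario2_structure(p: int, beta: float, gamma: float) -> dict:
    """Block geometry of the second design (sizes, counts, overlaps).

    Returns block_size, n_blocks, coexpressed_per_block, and
    common_per_block / common_total (genes coexpressed in both conditions).
    """
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    if not (0 < gamma <= 1):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    b = _round_half_up(beta * p)
    if b < 1 or p % b != 0:
        raise ValueError(f"block size round(beta*p) = {b} does not tile p = {p} genes exactly")
    k = _round_half_up(gamma * b)
    if k < 1:
        raise ValueError(f"round(gamma*beta*p) = {k}; need at least 1 coexpressed gene per block")
    if k > b:
        raise ValueError(f"coexpressed group size {k} exceeds block size {b}")
    n_blocks = p // b
    common = max(0, 2 * k - b)
    return {
        "block_size": b,
        "n_blocks": n_blocks,
        "coexpressed_per_block": k,
        "common_per_block": common,
        "common_total": common * n_blocks,
    }


def scenario2_covariances(
    p: int, beta: float, gamma: float, r: float, background: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Block designs with shifted coexpressed membership between conditions.

    Both matrices tile the diagonal with blocks of size round(beta*p);
    within each block, round(gamma*beta*p) genes are pairwise correlated at
    r — the first ones in Sigma1, the last ones in Sigma2.  Off-block
    entries are ``background`` (zero or a small value).
    """
    if not (0 <= r < 1):
        raise ValueError(f"r must be in [0, 1), got {r}")
    if not (0 <= background < max(r, 1e-12) or background == r == 0):
        raise ValueError(f"background correlation {background} must be small relative to r = {r}")
    geom = scenario2_structure(p, beta, gamma)
    b, k = geom["block_size"], geom["coexpressed_per_block"]
    S1 = np.full((p, p), background)
    S2 = np.full((p, p), background)
    for start in range(0, p, b):
        blk1 = np.zeros((b, b))
        blk1[:k, :k] = r
        blk2 = np.zeros((b, b))
        blk2[b - k :, b - k :] = r
        S1[start : start + b, start : start + b] = blk1
        S2[start : start + b, start : start + b] = blk2
    np.fill_diagonal(S1, 1.0)
    np.fill_diagonal(S2, 1.0)
    return S1, S2


def sample_dataset(
    Sigma1: np.ndarray, Sigma2: np.ndarray, n_per_group: int, seed=None
) -> ExpressionDataset:
    """Draw a two-condition dataset from N(0, Sigma1) and N(0, Sigma2).

    Each group of ``n_per_group`` samples is L @ Z with L the Cholesky
    factor of its covariance and Z standard normal; identical seeds give
    identical datasets.
    """
    S1 = np.asarray(Sigma1, dtype=float)
    S2 = np.asarray(Sigma2, dtype=float)
    if S1.shape != S2.shape or S1.ndim != 2 or S1.shape[0] != S1.shape[1]:
        raise ValueError("covariances must be square matrices of identical size")
    p = S1.shape[0]
    chol = []
    for name, S in (("Sigma1", S1), ("Sigma2", S2)):
        try:
            chol.append(np.linalg.cholesky(S))
        except np.linalg.LinAlgError:
            lam = float(np.linalg.eigvalsh(S)[0])
            raise ValueError(
                f"{name} is not positive definite (smallest eigenvalue {lam:.6g})"
            ) from None
    rng = as_rng(seed)
    X1 = chol[0] @ rng.standard_normal((p, n_per_group))
    X2 = chol[1] @ rng.standard_normal((p, n_per_group))
    width = len(str(p))
    genes = [f"g{i + 1:0{width}d}" for i in range(p)]
    samples = [f"s{j + 1}" for j in range(2 * n_per_group)]
    condition = ["cond1"] * n_per_group + ["cond2"] * n_per_group
    return ExpressionDataset(
        values=np.hstack([X1, X2]), gene_ids=genes, sample_ids=samples, condition=condition
    )


@dataclass(frozen=True)
class RejectionRate:
    """Monte-Carlo rejection-rate estimate with its binomial standard error."""

    rate: float
    se: float
    n_sim: int
    n_rejected: int


def estimate_rejection_rate(
    sc: SimulationScenario,
    test: str = "gsnca",
    n_sim: int = 1000,
    alpha: float = 0.05,
    n_permutations: int = 500,
    seed=None,
    method: str = "pearson",
) -> RejectionRate:
    """Fraction of replicate datasets rejected at level alpha.

    Each of the ``n_sim`` replicates draws a fresh dataset from the
    scenario's covariances and runs the permutation test on it; replicate
    streams are split from the master seed with SeedSequence.spawn so they
    are independent and reproducible.  Under the null design this estimates
    the Type-I error; under an alternative it estimates power.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    if not (0 <= alpha < 1):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    S1, S2 = sc.covariances()
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rejected = 0
    for child in master.spawn(n_sim):
        s_data, s_perm = child.spawn(2)
        ds = sample_dataset(S1, S2, sc.n_per_group, seed=s_data)
        res = permutation_test(
            ds, statistic=test, n_permutations=n_permutations, seed=s_perm, method=method
        )
        if res.p_value <= alpha:
            rejected += 1
    rate = rejected / n_sim
    se = float(np.sqrt(rate * (1.0 - rate) / n_sim))
    return RejectionRate(rate=rate, se=se, n_sim=n_sim, n_rejected=rejected)


# -- flat key-value scenario configs ----------------------------------------


def write_scenario(sc: SimulationScenario, path) -> None:
    """One ``key = value`` line per parameter, for provenance."""
    with open(path, "w") as fh:
        for key, val in asdict(sc).items():
            fh.write(f"{key} = {val}\n")


def read_scenario(path) -> SimulationScenario:
    fields = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    kwargs: dict = {"scenario": fields.pop("scenario"), "p": int(fields.pop("p"))}
    for key, cast in (
        ("gamma", float),
        ("r", float),
        ("beta", float),
        ("n_per_group", int),
        ("background", float),
    ):
        if key in fields:
            raw = fields.pop(key)
            kwargs[key] = None if raw == "None" else cast(raw)
    if fields:
        raise ValueError(f"unknown scenario keys: {sorted(fields)}")
    return SimulationScenario(**kwargs)
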