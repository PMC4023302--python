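"""Gene-set net-correlation testing.

For a gene set of p genes measured in two phenotypes, each gene i is given a
weight factor w_i proportional to its cross-correlations with all other set
members.  Requiring every gene's weight to equal the weighted sum of its
absolute correlations simultaneously is an eigenvector problem: by the
Perron-Frobenius theorem a non-negative irreducible correlation matrix R has
a simple largest eigenvalue lambda* whose eigenvector v* is strictly
positive, and w = v* is the unique positive solution.  Scaling w by the L1
norm of v* puts the weights "around one" (an equicorrelated set gets weight
exactly 1 for every gene), which makes weight vectors comparable across
conditions and set sizes.

The GSNCA test statistic is the L1 distance between the two conditions'
scaled weight vectors; the comparator GSCA statistic is the root-mean-square
difference of the signed pairwise correlations.  Both are calibrated by
permuting sample labels across the pooled samples and recomputing the
statistic from scratch for every relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as _sla
from scipy import stats as _sstats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dataset import ExpressionDataset

__all__ = [
    "CorrelationStructure",
    "WeightSolution",
    "TestResult",
    "correlation_structure",
    "gene_weights",
    "gsnca_statistic",
    "gsca_statistic",
    "permutation_test",
]

_METHODS = ("pearson", "spearman")


def as_rng(seed) -> np.random.Generator:
    """Build a reproducible generator from a seed.

    Uses the counter-based Philox bit generator so identical seeds give
    identical permutation streams across platforms.  Accepts an int, a
    SeedSequence, an existing Generator, or None.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.Philox(seed))


@dataclass(frozen=True)
class CorrelationStructure:
    """Signed and absolute views of a gene-gene correlation matrix.

    ``signed_corr`` is the ordinary symmetric correlation matrix with unit
    diagonal; ``abs_corr`` is its elementwise absolute value with the
    diagonal zeroed (the matrix whose leading eigenvector defines the gene
    weights, and whose entries define correlation distances 1 - |r|).
    """

    signed_corr: np.ndarray
    abs_corr: np.ndarray
    method: str

    @property
    def p(self) -> int:
        return self.signed_corr.shape[0]


@dataclass(frozen=True)
class WeightSolution:
    """Solution of the weight eigenproblem for one condition.

    ``unit_eigenvector`` is the positive unit-L2 Perron eigenvector v* of
    the unit-diagonal absolute-correlation matrix; ``weights`` is
    v* * ||v*||_1 (so the entries sit around one); ``lambda_star`` is the
    associated largest eigenvalue, always >= 1.
    """

    weights: np.ndarray
    lambda_star: float
    unit_eigenvector: np.ndarray


@dataclass(frozen=True)
class TestResult:
    """Observed statistic, permutation null and p-value for one gene set."""

    statistic: float
    p_value: float
    n_permutations: int
    null_statistics: np.ndarray
    weights_cond1: WeightSolution | None = None
    weights_cond2: WeightSolution | None = None
    hub_cond1: str | None = None
    hub_cond2: str | None = None


def correlation_structure(
    X: np.ndarray,
    method: str = "pearson",
    gene_ids: list[str] | None = None,
) -> CorrelationStructure:
    """Correlation matrix of a genes x samples block, in both views.

    Parameters
    ----------
    X : ndarray of shape (p, n)
        Expression of the p set members over the n samples of one condition;
        n >= 3 and every row must have nonzero variance.
    method : {'pearson', 'spearman'}
    gene_ids : optional
        Used only to name offending genes in error messages.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D genes x samples array")
    p, n = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples to estimate correlations, got {n}")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        names = gene_ids if gene_ids is not None else [str(i) for i in range(p)]
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance gene(s) in correlation input: {bad}")
    if method == "spearman":
        X = _sstats.rankdata(X, axis=1)
    C = np.corrcoef(X)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    A = np.abs(C)
    np.fill_diagonal(A, 0.0)
    return CorrelationStructure(signed_corr=C, abs_corr=A, method=method)


def gene_weights(C: CorrelationStructure, gene_ids: list[str] | None = None) -> WeightSolution:
    """Solve the weight eigenproblem for one condition's correlations.

    Returns the positive unit-L2 leading eigenvector v* of the
    unit-diagonal absolute-correlation matrix (the zero-diagonal matrix
    shares its eigenvectors; its eigenvalues are shifted down by one),
    scaled as weights = v* * ||v*||_1.

    Raises
    ------
    ValueError
        If p < 3, or the absolute-correlation matrix is reducible (its
        nonzero pattern is a disconnected graph), which breaks the
        Perron uniqueness/positivity guarantee.
    """
    A = C.abs_corr
    p = A.shape[0]
    if p < 3:
        raise ValueError(
            f"gene weights need at least 3 genes, got {p} "
            "(the 2-gene problem has a constant eigenvector and carries no signal)"
        )
    ncomp, labels = connected_components(csr_matrix(A != 0), directed=False)
    if ncomp > 1:
        names = gene_ids if gene_ids is not None else [str(i) for i in range(p)]
        counts = np.bincount(labels)
        main = int(np.argmax(counts))
        isolated = [names[i] for i in np.flatnonzero(labels != main)]
        raise ValueError(
            "absolute-correlation matrix is reducible; genes disconnected "
            f"from the largest component: {isolated}"
        )
    M = A + np.eye(p)
    try:
        evals, evecs = np.linalg.eigh(M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK failure
        raise ValueError(f"eigensolver failed to converge: {exc}") from exc
    lam = float(evals[-1])
    v = np.abs(evecs[:, -1])
    v = v / np.linalg.norm(v)
    return WeightSolution(weights=v * v.sum(), lambda_star=lam, unit_eigenvector=v)


def _weights_vector(w) -> np.ndarray:
    return w.weights if isinstance(w, WeightSolution) else np.asarray(w, dtype=float)


def gsnca_statistic(w1, w2) -> float:
    """L1 distance between two conditions' scaled weight vectors."""
    a, b = _weights_vector(w1), _weights_vector(w2)
    if a.shape != b.shape:
        raise ValueError(f"weight vectors differ in length: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


def gsca_statistic(C1: CorrelationStructure, C2: CorrelationStructure) -> float:
    """Size-adjusted Euclidean distance between signed pairwise correlations.

    sqrt( (1/K) * sum_k (rho_k^(1) - rho_k^(2))^2 ) over the K = p(p-1)/2
    unordered gene pairs.
    """
    if C1.p != C2.p:
        raise ValueError(f"correlation matrices differ in size: {C1.p} vs {C2.p}")
    if C1.p < 2:
        raise ValueError("need at least 2 genes for pairwise correlations")
    iu = np.triu_indices(C1.p, k=1)
    d = C1.signed_corr[iu] - C2.signed_corr[iu]
    return float(np.sqrt(np.mean(d * d)))


# ---------------------------------------------------------------------------
# Batched permutation machinery.  The null distribution requires recomputing
# per-group correlations (and, for GSNCA, the leading eigenvector) for every
# relabeling; both steps vectorize over the permutation axis.
# ---------------------------------------------------------------------------


def _batched_corr(X: np.ndarray, idx: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrices for many column subsets at once.

    Parameters
    ----------
    X : (p, n) data; idx : (B, m) column indices per permutation.

    Returns
    -------
    C : (B, p, p) unit-diagonal signed correlation matrices and
    ``bad`` : (B,) flags marking permutations in which some gene had zero
    variance within the subset (those C slices are unusable).

    For Pearson, all subset covariances come from two matrix products
    against 0/1 membership vectors (sums and sums-of-products over each
    subset), which turns the per-permutation work into single large GEMMs.
    Spearman ranks depend on the subset, so it takes the direct path.
    """
    B, m = idx.shape
    p, n = X.shape
    if method == "spearman":
        sub = _sstats.rankdata(np.moveaxis(X[:, idx], 0, 1), axis=-1)
        sub = sub - sub.mean(axis=-1, keepdims=True)
        norm = np.sqrt(np.einsum("bpm,bpm->bp", sub, sub))
        bad = (norm == 0).any(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = sub / norm[..., None]
        C = Z @ np.swapaxes(Z, -1, -2)
        C = np.clip(C, -1.0, 1.0)
        C[:, np.arange(p), np.arange(p)] = 1.0
        return C, bad
    # Global per-gene centering leaves within-subset covariances unchanged
    # but avoids catastrophic cancellation in E[xy] - E[x]E[y].
    X0 = X - X.mean(axis=1, keepdims=True)
    W = np.zeros((B, n))
    W[np.arange(B)[:, None], idx] = 1.0
    S1 = W @ X0.T                                  # (B, p) subset sums
    P = (X0.T[:, :, None] * X0.T[:, None, :]).reshape(n, p * p)
    S2 = (W @ P).reshape(B, p, p)                  # subset sums of products
    tol = 1e-12 * (X0 * X0).sum(axis=1)            # per-gene magnitude
    return _corr_from_sums(S1, S2, m, tol)


def _corr_from_sums(S1: np.ndarray, S2: np.ndarray, m: int, tol: np.ndarray):
    """Unit-diagonal correlations from per-subset sums and product sums.

    S1 : (B, p) subset sums; S2 : (B, p, p) subset sums of products over
    subsets of size m (modified in place); tol : per-gene threshold below
    which the (m-scaled) variance counts as zero.
    """
    B, p = S1.shape
    S2 -= (S1[:, :, None] / m) @ S1[:, None, :]
    var = S2[:, np.arange(p), np.arange(p)]        # (B, p), scaled by m
    bad = (var <= tol[None, :]).any(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / np.sqrt(np.maximum(var, 0.0))
        S2 *= inv[:, :, None]
        S2 *= inv[:, None, :]
    np.clip(S2, -1.0, 1.0, out=S2)
    S2[:, np.arange(p), np.arange(p)] = 1.0
    return S2, bad


def _pair_corr(X: np.ndarray, perms: np.ndarray, n1: int, method: str):
    """Per-group correlation stacks for permuted two-group splits.

    ``perms`` holds B permutations of all n column indices; the first n1
    entries of each row form group 1 and the rest group 2.  For Pearson the
    second group's sums are the pooled totals minus the first group's, so
    only one set of GEMMs is needed per batch.
    """
    B, n = perms.shape
    p = X.shape[0]
    n2 = n - n1
    if method == "spearman":
        C1, bad1 = _batched_corr(X, perms[:, :n1], method)
        C2, bad2 = _batched_corr(X, perms[:, n1:], method)
        return C1, C2, bad1 | bad2
    X0 = X - X.mean(axis=1, keepdims=True)
    W = np.zeros((B, n))
    W[np.arange(B)[:, None], perms[:, :n1]] = 1.0
    P = (X0.T[:, :, None] * X0.T[:, None, :]).reshape(n, p * p)
    tot1 = X0.sum(axis=1)
    tot2 = P.sum(axis=0).reshape(p, p)
    S1a = W @ X0.T                                 # (B, p)
    S2a = (W @ P).reshape(B, p, p)
    S1b = tot1[None, :] - S1a
    S2b = tot2[None, :, :] - S2a
    tol = 1e-12 * np.diag(tot2)
    C1, bad1 = _corr_from_sums(S1a, S2a, n1, tol)
    C2, bad2 = _corr_from_sums(S1b, S2b, n2, tol)
    return C1, C2, bad1 | bad2


def _leading_eigenvectors(M: np.ndarray) -> np.ndarray:
    """Leading eigenvector of each matrix in a (B, p, p) symmetric stack.

    Small matrices go through the batched LAPACK gufunc; for larger p a
    subset eigensolver computing only the top eigenpair per matrix wins.
    """
    p = M.shape[-1]
    if p < 50:
        _, vecs = np.linalg.eigh(M)
        return np.abs(vecs[..., -1])
    out = np.empty(M.shape[:-1])
    for b in range(M.shape[0]):
        _, vec = _sla.eigh(M[b], subset_by_index=[p - 1, p - 1], driver="evx")
        out[b] = np.abs(vec[:, 0])
    return out


def _batched_gsnca(C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    """GSNCA statistics for stacks of per-condition correlation matrices."""
    p = C1.shape[-1]

    def weights(C: np.ndarray) -> np.ndarray:
        M = np.abs(C, out=C)  # signed view not needed once the stat is weight-based
        v = _leading_eigenvectors(M)
        return v * v.sum(axis=-1, keepdims=True)

    return np.abs(weights(C1) - weights(C2)).sum(axis=-1)


def _batched_gsca(C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    p = C1.shape[-1]
    iu = np.triu_indices(p, k=1)
    d = C1[:, iu[0], iu[1]] - C2[:, iu[0], iu[1]]
    return np.sqrt(np.mean(d * d, axis=-1))


def permutation_test(
    ds: ExpressionDataset,
    gene_subset: list[str] | None = None,
    statistic: str = "gsnca",
    n_permutations: int = 1000,
    seed=None,
    method: str = "pearson",
) -> TestResult:
    """Two-sample differential-coexpression permutation test on one gene set.

    The observed statistic is computed on the true labels; the null is built
    from ``n_permutations`` random relabelings of the pooled samples into
    groups of the original sizes, recomputing correlations (and weights, for
    GSNCA) for every relabeling.  The p-value uses the add-one correction
    (1 + #{null >= observed}) / (1 + B), so it is never exactly zero.

    Permutations that give some gene zero variance within a group are
    redrawn (up to 10x the requested count in total) so the statistic stays
    defined on near-constant genes.
    """
    if statistic not in ("gsnca", "gsca"):
        raise ValueError(f"statistic must be 'gsnca' or 'gsca', got {statistic!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    sub = ds if gene_subset is None else ds.subset(list(gene_subset))
    p = sub.n_genes
    if statistic == "gsnca" and p < 3:
        raise ValueError(f"GSNCA needs at least 3 genes, got {p}")
    if statistic == "gsca" and p < 2:
        raise ValueError(f"GSCA needs at least 2 genes, got {p}")

    lev1, lev2 = sub.condition_levels
    X = sub.values
    cols1, cols2 = sub.group_columns(lev1), sub.group_columns(lev2)
    n1, n2 = len(cols1), len(cols2)

    # Observed statistic on the true labels, via the scalar-path functions.
    C1 = correlation_structure(X[:, cols1], method=method, gene_ids=sub.gene_ids)
    C2 = correlation_structure(X[:, cols2], method=method, gene_ids=sub.gene_ids)
    w1 = w2 = None
    hub1 = hub2 = None
    if statistic == "gsnca":
        w1 = gene_weights(C1, gene_ids=sub.gene_ids)
        w2 = gene_weights(C2, gene_ids=sub.gene_ids)
        observed = gsnca_statistic(w1, w2)
        hub1 = sub.gene_ids[int(np.argmax(w1.weights))]
        hub2 = sub.gene_ids[int(np.argmax(w2.weights))]
    else:
        observed = gsca_statistic(C1, C2)

    # Null distribution over random relabelings of the pooled samples.
    rng = as_rng(seed)
    pooled = np.concatenate([cols1, cols2])
    n = n1 + n2
    B = n_permutations
    null = np.empty(B)
    filled = 0
    budget = 10 * B
    while filled < B:
        need = B - filled
        if budget <= 0:
            raise RuntimeError(
                "could not find enough permutations without zero-variance "
                f"genes within a group (requested {B})"
            )
        draw = min(need, budget)
        perms = rng.permuted(np.tile(np.arange(n), (draw, 1)), axis=1)
        budget -= draw
        P1, P2, bad = _pair_corr(X, pooled[perms], n1, method)
        if bad.all():
            continue
        if not bad.any():
            Q1, Q2 = P1, P2
        else:
            ok = ~bad
            Q1, Q2 = P1[ok], P2[ok]
        vals = _batched_gsnca(Q1, Q2) if statistic == "gsnca" else _batched_gsca(Q1, Q2)
        take = min(len(vals), need)
        null[filled : filled + take] = vals[:take]
        filled += take

    p_value = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + B)
    return TestResult(
        statistic=observed,
        p_value=float(p_value),
        n_permutations=B,
        null_statistics=null,
        weights_cond1=w1,
        weights_cond2=w2,
        hub_cond1=hub1,
        hub_cond2=hub2,
    )
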