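"""Correlation structures, weight eigenproblem and permutation tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gsnca import (
    CorrelationStructure,
    correlation_structure,
    gene_weights,
    gsca_statistic,
    gsnca_statistic,
    permutation_test,
)
from gsnca.core import _batched_corr

from conftest import make_dataset, power_iteration


def abs_structure(S):
    """CorrelationStructure from a hand-specified signed matrix."""
    S = np.asarray(S, dtype=float)
    A = np.abs(S).copy()
    np.fill_diagonal(A, 0.0)
    return CorrelationStructure(signed_corr=S, abs_corr=A, method="pearson")


class TestCorrelationStructure:
    def test_affine_dependence_gives_unit_correlation(self):
        g1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = np.vstack([g1, 2 * g1 + 1, -g1])
        C = correlation_structure(X)
        assert C.signed_corr[0, 1] == pytest.approx(1.0)
        assert C.signed_corr[0, 2] == pytest.approx(-1.0)
        assert C.abs_corr[0, 1] == pytest.approx(1.0)
        assert C.abs_corr[0, 2] == pytest.approx(1.0)

    def test_matches_textbook_pearson_formula(self):
        rng = np.random.default_rng(7)
        X = rng.normal(5.0, 2.0, size=(3, 6))

        def pearson(x, y):
            xm, ym = x - x.mean(), y - y.mean()
            return (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())

        C = correlation_structure(X)
        for i in range(3):
            for j in range(i + 1, 3):
                assert C.signed_corr[i, j] == pytest.approx(pearson(X[i], X[j]), abs=1e-12)

    def test_spearman_is_rank_pearson(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 8))
        from scipy.stats import spearmanr

        C = correlation_structure(X, method="spearman")
        ref = spearmanr(X, axis=1).statistic
        np.testing.assert_allclose(C.signed_corr, ref, atol=1e-12)

    def test_structure_invariants(self):
        C = correlation_structure(np.random.default_rng(2).standard_normal((5, 9)))
        np.testing.assert_allclose(C.signed_corr, C.signed_corr.T)
        np.testing.assert_allclose(np.diag(C.signed_corr), 1.0)
        np.testing.assert_allclose(np.diag(C.abs_corr), 0.0)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(C.abs_corr[off], np.abs(C.signed_corr[off]))
        assert (C.abs_corr >= 0).all() and (C.abs_corr <= 1).all()

    def test_zero_variance_gene_is_named(self):
        X = np.random.default_rng(0).standard_normal((3, 6))
        X[1] = 4.2
        with pytest.raises(ValueError, match="geneB"):
            correlation_structure(X, gene_ids=["geneA", "geneB", "geneC"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_structure(np.ones((4, 2)))


class TestGeneWeights:
    @pytest.mark.parametrize("p,r", [(3, 0.2), (5, 0.7), (10, 0.05)])
    def test_equicorrelated_weights_are_one(self, p, r):
        S = np.full((p, p), r)
        np.fill_diagonal(S, 1.0)
        w = gene_weights(abs_structure(S))
        np.testing.assert_allclose(w.weights, 1.0, atol=1e-10)
        assert w.lambda_star == pytest.approx(1 + (p - 1) * r)

    def test_three_gene_example_matches_power_iteration(self):
        S = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        w = gene_weights(abs_structure(S))
        # strongest cross-correlated genes get the largest weights
        assert w.weights[0] == pytest.approx(w.weights[1])
        assert w.weights[0] > w.weights[2]
        M = np.abs(S)
        lam, v = power_iteration(M)
        assert w.lambda_star == pytest.approx(lam, rel=1e-12)
        np.testing.assert_allclose(w.weights, v * v.sum(), rtol=1e-12)

    def test_oracle_equivalence_on_random_instances(self):
        """Leading eigenpair agrees with power iteration to 1e-9."""
        rng = np.random.default_rng(11)
        for trial in range(100):
            p = int(rng.integers(3, 11))
            X = rng.standard_normal((p, 12))
            C = correlation_structure(X)
            w = gene_weights(C)
            M = C.abs_corr + np.eye(p)
            lam, v = power_iteration(M)
            assert abs(w.lambda_star - lam) <= 1e-9 * lam
            np.testing.assert_allclose(w.unit_eigenvector, v, rtol=1e-9, atol=1e-9)

    def test_perron_properties_against_full_spectrum(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = int(rng.integers(3, 11))
            C = correlation_structure(rng.standard_normal((p, 8)))
            w = gene_weights(C)
            assert (w.weights > 0).all()
            assert w.lambda_star >= 1.0
            evals = np.linalg.eigvalsh(C.abs_corr + np.eye(p))
            assert w.lambda_star == pytest.approx(evals[-1])
            assert (evals[:-1] < w.lambda_star - 1e-12).all()
            # scaling identity: sum of squared weights = ||v*||_1 ** 2
            assert (w.weights**2).sum() == pytest.approx(
                np.abs(w.unit_eigenvector).sum() ** 2
            )

    def test_gene_order_equivariance(self):
        rng = np.random.default_rng(3)
        C = correlation_structure(rng.standard_normal((6, 10)))
        w = gene_weights(C)
        perm = rng.permutation(6)
        Cp = CorrelationStructure(
            signed_corr=C.signed_corr[np.ix_(perm, perm)],
            abs_corr=C.abs_corr[np.ix_(perm, perm)],
            method="pearson",
        )
        wp = gene_weights(Cp)
        np.testing.assert_allclose(wp.weights, w.weights[perm], rtol=1e-9)

    def test_reducible_matrix_identifies_isolated_genes(self):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.5
        S[2, 3] = S[3, 2] = 0.4
        with pytest.raises(ValueError, match="reducible"):
            gene_weights(abs_structure(S), gene_ids=list("abcd"))

    def test_two_gene_set_rejected(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError, match="at least 3"):
            gene_weights(abs_structure(S))


class TestStatistics:
    def test_gsnca_arithmetic_and_symmetry(self):
        w1 = np.array([1.0, 1.0, 1.0])
        w2 = np.array([1.2, 0.9, 0.9])
        assert gsnca_statistic(w1, w2) == pytest.approx(0.4)
        assert gsnca_statistic(w2, w1) == pytest.approx(0.4)
        assert gsnca_statistic(w1, w1) == 0.0
        with pytest.raises(ValueError, match="length"):
            gsnca_statistic(w1, np.ones(4))

    def test_gsca_examples(self):
        C1 = abs_structure([[1.0, 0.8], [0.8, 1.0]])
        C2 = abs_structure([[1.0, 0.3], [0.3, 1.0]])
        assert gsca_statistic(C1, C2) == pytest.approx(0.5)
        assert gsca_statistic(C1, C1) == 0.0
        # p = 3 with pairwise differences (0.2, -0.2, 0.4)
        A = abs_structure([[1, 0.5, 0.1], [0.5, 1, 0.6], [0.1, 0.6, 1]])
        B = abs_structure([[1, 0.3, 0.3], [0.3, 1, 0.2], [0.3, 0.2, 1]])
        assert gsca_statistic(A, B) == pytest.approx(np.sqrt(0.24 / 3))
        with pytest.raises(ValueError, match="size"):
            gsca_statistic(C1, A)


class TestPermutationTest:
    def test_duplicated_conditions_give_zero_statistic_and_p_one(self):
        rng = np.random.default_rng(4)
        half = rng.standard_normal((5, 6))
        ds = make_dataset(p=5, n1=6, n2=6)
        ds.values = np.hstack([half, half])
        for stat in ("gsnca", "gsca"):
            res = permutation_test(ds, statistic=stat, n_permutations=99, seed=0)
            assert res.statistic == 0.0
            assert res.p_value == 1.0

    def test_p_value_lattice(self):
        ds = make_dataset(p=4, n1=5, n2=5, seed=9)
        res = permutation_test(ds, statistic="gsnca", n_permutations=19, seed=1)
        lattice = np.arange(1, 21) / 20.0
        assert np.isclose(lattice, res.p_value).any()
        assert res.p_value >= 1.0 / 20.0

    def test_seed_reproducibility(self):
        ds = make_dataset(p=5, n1=6, n2=7, seed=2)
        r1 = permutation_test(ds, statistic="gsnca", n_permutations=100, seed=33)
        r2 = permutation_test(ds, statistic="gsnca", n_permutations=100, seed=33)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_statistics, r2.null_statistics)

    def test_invalid_gene_ids_listed(self):
        ds = make_dataset()
        with pytest.raises(KeyError, match="nope"):
            permutation_test(ds, gene_subset=["g0", "nope"], n_permutations=10)

    def test_gsnca_needs_three_genes(self):
        ds = make_dataset(p=4)
        with pytest.raises(ValueError, match="at least 3"):
            permutation_test(ds, gene_subset=["g0", "g1"], statistic="gsnca")

    def test_statistics_invariant_to_per_gene_affine_rescaling(self):
        ds = make_dataset(p=5, n1=6, n2=6, seed=12)
        rng = np.random.default_rng(0)
        scale = rng.uniform(0.5, 3.0, size=5)[:, None]
        shift = rng.normal(size=5)[:, None]
        ds2 = make_dataset(p=5, n1=6, n2=6, seed=12)
        ds2.values = ds.values * scale + shift
        for stat in ("gsnca", "gsca"):
            a = permutation_test(ds, statistic=stat, n_permutations=50, seed=5)
            b = permutation_test(ds2, statistic=stat, n_permutations=50, seed=5)
            assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
            np.testing.assert_allclose(a.null_statistics, b.null_statistics, atol=1e-10)

    def test_statistic_invariant_to_gene_reordering(self):
        ds = make_dataset(p=6, n1=5, n2=5, seed=8)
        res = permutation_test(ds, statistic="gsnca", n_permutations=10, seed=2)
        shuffled = list(np.random.default_rng(1).permutation(ds.gene_ids))
        res2 = permutation_test(ds, gene_subset=shuffled, statistic="gsnca",
                                n_permutations=10, seed=2)
        assert res.statistic == pytest.approx(res2.statistic, abs=1e-12)

    def test_hub_genes_reported(self):
        ds = make_dataset(p=5, n1=8, n2=8, seed=21)
        res = permutation_test(ds, statistic="gsnca", n_permutations=20, seed=0)
        assert res.hub_cond1 in ds.gene_ids and res.hub_cond2 in ds.gene_ids
        i1 = ds.gene_ids.index(res.hub_cond1)
        assert res.weights_cond1.weights[i1] == res.weights_cond1.weights.max()

    def test_batched_corr_agrees_with_corrcoef(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((7, 16)) * 3 + 10
        idx = np.stack([rng.permutation(16)[:8] for _ in range(20)])
        for method in ("pearson", "spearman"):
            C, bad = _batched_corr(X, idx, method)
            assert not bad.any()
            for b in range(20):
                ref = correlation_structure(X[:, idx[b]], method=method).signed_corr
                np.testing.assert_allclose(C[b], ref, atol=1e-10)

    def test_null_calibration_smoke(self):
        """Type-I error within 3 binomial SE of nominal at reduced scale."""
        from gsnca import SimulationScenario, estimate_rejection_rate

        sc = SimulationScenario("null", p=10, n_per_group=10)
        est = estimate_rejection_rate(
            sc, "gsnca", n_sim=200, alpha=0.05, n_permutations=199, seed=77
        )
        band = 3 * np.sqrt(0.05 * 0.95 / 200)
        assert abs(est.rate - 0.05) <= band


@given(st.integers(min_value=3, max_value=8), st.integers(min_value=0, max_value=10**6))
def test_weight_permutation_equivariance_property(p, seed):
    """Relabeling genes permutes weights identically (property-based)."""
    rng = np.random.default_rng(seed)
    C = correlation_structure(rng.standard_normal((p, p + 4)))
    w = gene_weights(C)
    perm = rng.permutation(p)
    Cp = CorrelationStructure(
        signed_corr=C.signed_corr[np.ix_(perm, perm)],
        abs_corr=C.abs_corr[np.ix_(perm, perm)],
        method="pearson",
    )
    np.testing.assert_allclose(gene_weights(Cp).weights, w.weights[perm], rtol=1e-8)
    assert (w.weights > 0).all()
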