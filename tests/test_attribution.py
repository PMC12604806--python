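"""Shapley estimators: oracle agreement, axioms, backgrounds, cohort API."""

import numpy as np
import pandas as pd
import pytest

import chromshap as cs
from chromshap.attribution import (
    BackgroundSet,
    attribute_cohort,
    build_background,
    exact_shapley,
    kernel_shapley,
    linear_shapley,
)
from chromshap.ingest import GeneFeatureTable
from chromshap.regression import fit_linear, fit_mlp


def make_background(rng, k, m, weights=None):
    w = np.ones(k) / k if weights is None else weights
    return BackgroundSet(rng.normal(size=(k, m)), w)


class TestBackground:
    def test_k1_centroid_is_the_mean_of_eligible_rows(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 4)), index=[f"g{i}" for i in range(30)])
        bg = build_background(frame, frame.index, excluded_ids=["g0", "g1"], k=1, seed=0)
        assert np.allclose(bg.data[0], frame.iloc[2:].mean(axis=0))
        assert bg.weights[0] == 1.0

    def test_excluded_genes_never_contribute(self, rng):
        ids = [f"g{i}" for i in range(40)]
        frame = pd.DataFrame(rng.normal(size=(40, 3)), index=ids)
        bg_ref = build_background(frame, ids, excluded_ids=ids[:5], k=4, seed=1)
        # blowing up the excluded rows must leave the centroids untouched
        loud = frame.copy()
        loud.iloc[:5] += 1e6
        bg_loud = build_background(loud, ids, excluded_ids=ids[:5], k=4, seed=1)
        assert np.allclose(bg_ref.data, bg_loud.data)

    def test_weights_sum_to_one_and_reflect_cluster_sizes(self, rng):
        for trial in range(100):
            local = np.random.default_rng(trial)
            n = int(local.integers(12, 40))
            frame = pd.DataFrame(local.normal(size=(n, 3)),
                                 index=[f"g{i}" for i in range(n)])
            bg = build_background(frame, frame.index, k=3, seed=trial)
            assert bg.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert (bg.weights >= 0).all()
            assert sum(bg.provenance["cluster_sizes"]) == n

    def test_too_few_eligible_rows_is_an_error(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="eligible"):
            build_background(frame, frame.index, excluded_ids=frame.index[:8], k=5, seed=0)


class TestExact:
    def test_constant_model_gets_zero_attribution(self, rng):
        bg = make_background(rng, 3, 4)
        phi = exact_shapley(lambda X: np.full((len(X), 2), 7.0), rng.normal(size=4), bg)
        assert np.abs(phi).max() < 1e-12

    def test_linear_closed_form_example(self):
        # f = 2*x1 + 0*x2, background mean (0, 0), x = (3, 5) -> phi = (6, 0)
        bg = BackgroundSet(np.zeros((1, 2)), np.ones(1))
        phi = exact_shapley(lambda X: np.asarray(X) @ np.array([[2.0], [0.0]]),
                            np.array([3.0, 5.0]), bg)
        assert np.allclose(phi[:, 0], [6.0, 0.0], atol=1e-12)

    def test_product_model_splits_credit_symmetrically(self):
        bg = BackgroundSet(np.zeros((1, 2)), np.ones(1))
        phi = exact_shapley(lambda X: (np.asarray(X)[:, 0] * np.asarray(X)[:, 1])[:, None],
                            np.array([1.0, 1.0]), bg)
        assert np.allclose(phi[:, 0], [0.5, 0.5], atol=1e-12)

    def test_feature_count_above_cap_is_refused(self, rng):
        bg = make_background(rng, 2, 25)
        with pytest.raises(ValueError, match="kernel"):
            exact_shapley(lambda X: np.asarray(X).sum(1, keepdims=True),
                          rng.normal(size=25), bg)

    def test_ignored_feature_gets_exactly_zero(self, rng):
        bg = make_background(rng, 4, 5)

        def f(X):
            X = np.asarray(X)
            return np.column_stack([np.sin(X[:, 0]) + X[:, 1], X[:, 2] ** 2])

        phi = exact_shapley(f, rng.normal(size=5), bg)
        assert np.abs(phi[3]).max() < 1e-9 and np.abs(phi[4]).max() < 1e-9

    def test_tied_duplicate_features_receive_equal_credit(self, rng):
        bg_rows = rng.normal(size=(4, 3))
        bg_rows[:, 1] = bg_rows[:, 0]  # duplicated feature in the background too
        bg = BackgroundSet(bg_rows, np.ones(4) / 4)

        def f(X):  # tied coefficients on the duplicated pair
            X = np.asarray(X)
            return (1.5 * X[:, 0] + 1.5 * X[:, 1] - X[:, 2])[:, None]

        x = np.array([2.0, 2.0, 1.0])
        phi = exact_shapley(f, x, bg)
        assert abs(phi[0, 0] - phi[1, 0]) < 1e-9


class TestKernel:
    def fit_small_mlp(self, rng, m=6):
        X = rng.normal(size=(250, m))
        Y = np.column_stack([np.tanh(X[:, 0]) + X[:, 1] * X[:, 2], X[:, 3] ** 2])
        return fit_mlp(X, Y, cs.MLPParams(hidden_layer_sizes=(16,), max_epochs=150,
                                          patience=40, tol=1e-6), seed=2)

    def test_full_enumeration_matches_exact_oracle(self, rng):
        model = self.fit_small_mlp(rng)
        bg = make_background(rng, 5, 6)
        x = rng.normal(size=6)
        pe = exact_shapley(model, x, bg)
        pk = kernel_shapley(model, x, bg, n_samples=2**6)
        assert np.abs(pe - pk).max() < 1e-6

    def test_constant_model_gets_zero(self, rng):
        bg = make_background(rng, 3, 4)
        phi = kernel_shapley(lambda X: np.ones((len(X), 1)), rng.normal(size=4), bg,
                             n_samples=64, seed=0)
        assert np.abs(phi).max() < 1e-9

    def test_underdetermined_budget_is_an_error(self, rng):
        bg = make_background(rng, 3, 6)
        with pytest.raises(ValueError, match="underdetermined"):
            kernel_shapley(lambda X: np.ones((len(X), 1)), rng.normal(size=6), bg,
                           n_samples=5, seed=0)

    def test_deterministic_under_seed_when_sampling(self, rng):
        model = self.fit_small_mlp(rng, m=8)
        bg = make_background(rng, 4, 8)
        x = rng.normal(size=8)
        a = kernel_shapley(model, x, bg, n_samples=60, seed=9)
        b = kernel_shapley(model, x, bg, n_samples=60, seed=9)
        assert (a == b).all()

    def test_local_accuracy_enforced_even_when_sampling(self, rng):
        model = self.fit_small_mlp(rng, m=8)
        bg = make_background(rng, 4, 8)
        x = rng.normal(size=8)
        phi, diag = kernel_shapley(model, x, bg, n_samples=64, seed=3,
                                   return_diagnostics=True)
        assert not diag["enumerated"]
        v = model.predict(x[None])[0]
        base = bg.weights @ model.predict(bg.data)
        assert np.abs(phi.sum(axis=0) + base - v).max() < 1e-8


class TestLinearShapley:
    def test_formula_examples(self):
        fit = fit_linear(np.random.default_rng(0).normal(size=(50, 2)),
                         np.random.default_rng(0).normal(size=(50, 2)))
        fit.coef = np.array([[1.0, -2.0], [0.5, 0.5]])
        bg = BackgroundSet(np.zeros((1, 2)), np.ones(1))
        phi = linear_shapley(fit, np.array([1.0, 1.0]), bg)
        assert np.allclose(phi[:, 0], [1.0, -2.0])
        # x equal to the background mean -> zero vector
        assert np.abs(linear_shapley(fit, np.zeros(2), bg)).max() == 0.0

    def test_matches_exact_enumeration_on_random_problems(self):
        for trial in range(100):
            rng = np.random.default_rng(trial)
            m = int(rng.integers(2, 11))
            X = rng.normal(size=(m + 20, m))
            Y = X @ rng.normal(size=(m, 2)) + rng.normal(size=2)
            fit = fit_linear(X, Y)
            bg = BackgroundSet(rng.normal(size=(3, m)), np.array([0.5, 0.3, 0.2]))
            x = rng.normal(size=m)
            assert np.abs(
                linear_shapley(fit, x, bg) - exact_shapley(fit, x, bg)
            ).max() < 1e-10


class TestAttributeCohort:
    def table(self, rng, n, ids=None):
        ids = ids or [f"g{i:03d}" for i in range(n)]
        data = pd.DataFrame(rng.normal(size=(n, 8)), index=ids)
        data.columns = pd.MultiIndex.from_tuples(
            [(a, c) for a in ["w", "x", "y", "z"] for c in ["promoter", "body"]]
        )
        return GeneFeatureTable(data, "standardized")

    def test_shapes_and_base_values(self, rng):
        test = self.table(rng, 20)
        bg = make_background(rng, 5, 8)
        model = lambda X: np.asarray(X)[:, :2] * np.array([1.0, -1.0])
        mat = attribute_cohort(model, test, bg, method="exact")
        assert mat.values.shape == (20, 8, 2)
        assert mat.base_values.shape == (2,)

    def test_training_gene_in_test_input_is_a_leakage_error(self, rng):
        test = self.table(rng, 10)
        bg = make_background(rng, 3, 8)
        with pytest.raises(ValueError, match="training gene"):
            attribute_cohort(lambda X: np.asarray(X)[:, :2], test, bg,
                             method="exact", train_ids=["g003"])

    def test_local_accuracy_residuals_are_tiny(self, rng, quick_mlp_params):
        X = rng.normal(size=(150, 8))
        Y = np.column_stack([X[:, 0] * X[:, 1], X[:, 2]])
        model = fit_mlp(X, Y, quick_mlp_params, seed=0)
        test = self.table(rng, 15)
        bg = make_background(rng, 4, 8)
        for method, tol in [("exact", 1e-6), ("kernel", 1e-3)]:
            mat = attribute_cohort(model, test, bg, method=method, n_samples=2**8)
            assert np.abs(mat.residuals).mean() < tol

    def test_own_layer_reads_context_matched_output(self, rng):
        test = self.table(rng, 5)
        bg = BackgroundSet(np.zeros((1, 8)), np.ones(1))

        def f(X):  # promoter output uses col 0, body output uses col 1
            X = np.asarray(X)
            return np.column_stack([X[:, 0], X[:, 1]])

        mat = attribute_cohort(f, test, bg, method="exact")
        own = mat.own_layer()
        assert np.allclose(own[("w", "promoter")], test.data[("w", "promoter")])
        assert np.allclose(own[("w", "body")], test.data[("w", "body")])

    def test_pooling_disjoint_and_deduped(self, rng):
        bg = make_background(rng, 3, 8)
        model = lambda X: np.asarray(X)[:, :2]
        m1 = attribute_cohort(model, self.table(rng, 5, [f"a{i}" for i in range(5)]), bg)
        m2 = attribute_cohort(model, self.table(rng, 5, [f"b{i}" for i in range(5)]), bg)
        pooled = cs.AttributionMatrix.concat([m1, m2])
        assert len(pooled.gene_ids) == 10
        overlap = attribute_cohort(model, self.table(rng, 5, [f"a{i}" for i in range(5)]), bg)
        with pytest.raises(ValueError, match="dedupe"):
            cs.AttributionMatrix.concat([m1, overlap])
        deduped = cs.AttributionMatrix.concat([m1, overlap], dedupe=True)
        assert len(deduped.gene_ids) == 5


def test_kernel_error_decreases_monotonically_with_budget(rng):
    """Monte-Carlo consistency: mean |error| vs the exact oracle shrinks as
    the coalition budget grows (3 budgets x 50 seeds)."""
    m = 10
    X = rng.normal(size=(200, m))
    Y = np.column_stack([X[:, 0] * X[:, 1] + X[:, 2], np.abs(X[:, 3])])
    model = fit_mlp(X, Y, cs.MLPParams(hidden_layer_sizes=(16,), max_epochs=120,
                                       patience=30, tol=1e-6), seed=4)
    bg = make_background(rng, 4, m)
    x = rng.normal(size=m)
    oracle = exact_shapley(model, x, bg)
    errors = []
    for budget in (64, 128, 256):
        est = np.array([kernel_shapley(model, x, bg, n_samples=budget, seed=s)
                        for s in range(50)])
        errors.append(np.abs(est - oracle[None]).mean())
    assert errors[0] > errors[1] > errors[2]
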