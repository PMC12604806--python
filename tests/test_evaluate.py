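"""Degron-validation statistics: stratification, contrasts, capture, audit."""

import numpy as np
import pandas as pd
import pytest

import chromshap as cs
from chromshap.attribution import AttributionMatrix
from chromshap.evaluate import (
    GeneLabels,
    balanced_group_importance,
    coefficient_contrast,
    cross_dataset_eval,
    feature_correlation_audit,
    rank_capture,
    shap_lfc_correlation,
    shap_scores,
    signal_scores,
    stratify_genes,
)
from chromshap.ingest import DegronTable, GeneFeatureTable, PolIITargets
from chromshap.regression import fit_linear


def degron_from(padj, log2fc=None):
    ids = [f"g{i:03d}" for i in range(len(padj))]
    return DegronTable(pd.DataFrame({
        "log2fc": log2fc if log2fc is not None else np.zeros(len(padj)),
        "padj": padj,
    }, index=ids))


def attribution_from(values, feature_ids=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, m, _ = values.shape
    feature_ids = feature_ids or [(f"f{j}", "promoter" if j % 2 == 0 else "body")
                                  for j in range(m)]
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n)]
    return AttributionMatrix(
        gene_ids=gene_ids, feature_ids=feature_ids, values=values,
        base_values=np.zeros(2), residuals=np.zeros((n, 2)), method="test",
    )


class TestStratify:
    def test_threshold_semantics(self):
        labels = stratify_genes(degron_from([0.01, 0.5, np.nan]))
        assert list(labels.labels) == ["direct_target", "random", "excluded"]

    def test_padj_exactly_alpha_is_excluded(self):
        labels = stratify_genes(degron_from([0.05, 0.01]))
        assert labels.labels.iloc[0] == "excluded"

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError, match="no stratifiable"):
            stratify_genes(degron_from([np.nan, np.nan]))

    def test_alpha_outside_unit_interval_is_an_error(self):
        with pytest.raises(ValueError, match="alpha"):
            stratify_genes(degron_from([0.1]), alpha=1.5)


class TestBalancedImportance:
    def labels(self, n, n_targets):
        padj = np.concatenate([np.full(n_targets, 0.01), np.full(n - n_targets, 0.5)])
        return stratify_genes(degron_from(padj))

    def test_zero_attributions_give_zero_means_and_dispersion(self, rng):
        labels = self.labels(60, 20)
        gi = balanced_group_importance(attribution_from(np.zeros((60, 4, 2))),
                                       labels, size=10, n_repeats=10, seed=0)
        assert (gi.table == 0).all().all()

    def test_deterministic_under_seed(self, rng):
        attr = attribution_from(rng.normal(size=(80, 4, 2)))
        labels = self.labels(80, 30)
        a = balanced_group_importance(attr, labels, size=20, n_repeats=20, seed=1)
        b = balanced_group_importance(attr, labels, size=20, n_repeats=20, seed=1)
        assert (a.table == b.table).all().all()

    def test_size_reduced_to_smallest_group(self, rng, caplog):
        attr = attribution_from(rng.normal(size=(30, 2, 2)))
        gi = balanced_group_importance(attr, self.labels(30, 5), size=50, n_repeats=5, seed=0)
        assert gi.size == 5

    def test_empty_group_is_an_error(self, rng):
        attr = attribution_from(rng.normal(size=(10, 2, 2)))
        with pytest.raises(ValueError, match="empty group"):
            balanced_group_importance(attr, self.labels(10, 0), seed=0)

    def test_defaults_match_protocol(self):
        import inspect

        sig = inspect.signature(balanced_group_importance)
        assert sig.parameters["size"].default == 50
        assert sig.parameters["n_repeats"].default == 50

    def test_group_means_stable_when_repeats_grow(self, rng):
        attr = attribution_from(rng.normal(size=(200, 3, 2)))
        labels = self.labels(200, 80)
        small = balanced_group_importance(attr, labels, size=50, n_repeats=50, seed=3)
        big = balanced_group_importance(attr, labels, size=50, n_repeats=500, seed=3)
        diff = (small.table["target_mean"] - big.table["target_mean"]).abs()
        assert (diff < small.table["target_sd"]).all()


class TestRankCapture:
    def test_perfect_ranking_curve(self):
        padj = [0.01] * 5 + [0.5] * 15
        labels = stratify_genes(degron_from(padj))
        scores = pd.Series(
            [1.0] * 5 + [0.0] * 15, index=labels.labels.index
        )
        curve = rank_capture(scores, labels).curve
        assert (curve["fraction"][:5] == 1.0).all()
        assert curve["fraction"].iloc[9] == pytest.approx(0.5)

    def test_endpoint_equals_prevalence_exactly(self, rng):
        padj = rng.uniform(size=200)
        labels = stratify_genes(degron_from(padj))
        scores = pd.Series(rng.normal(size=200), index=labels.labels.index)
        curve = rank_capture(scores, labels)
        assert curve.prevalence == pytest.approx(labels.prevalence, abs=1e-12)

    def test_random_scores_capture_about_prevalence(self, rng):
        padj = np.concatenate([np.full(40, 0.01), np.full(160, 0.5)])
        labels = stratify_genes(degron_from(padj))
        fracs = []
        for perm in range(200):
            local = np.random.default_rng(perm)
            scores = pd.Series(local.normal(size=200), index=labels.labels.index)
            fracs.append(rank_capture(scores, labels).fraction_at(0.25))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.2) < 2 * se + 1e-2

    def test_ties_break_lexicographically(self):
        padj = [0.01, 0.5, 0.01]
        labels = stratify_genes(degron_from(padj))
        scores = pd.Series([1.0, 1.0, 1.0], index=labels.labels.index)
        curve = rank_capture(scores, labels).curve
        # g000 (target), g001 (random), g002 (target) in id order
        assert list(curve["fraction"].round(4)) == [1.0, 0.5, round(2 / 3, 4)]

    def test_empty_score_features_is_an_error(self, rng):
        attr = attribution_from(rng.normal(size=(10, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            shap_scores(attr, [])


class TestLfcCorrelation:
    def test_phi_proportional_to_lfc_gives_unit_correlation(self, rng):
        lfc = rng.normal(size=50)
        values = np.zeros((50, 2, 2))
        values[:, 0, 0] = np.abs(lfc) * 3.0
        attr = attribution_from(values)
        degron = degron_from(np.full(50, 0.01), log2fc=lfc)
        out = shap_lfc_correlation([attr], degron)
        assert out.loc[[("f0", "promoter")], "shap_r_mean"].item() == pytest.approx(1.0)

    def test_constant_phi_is_reported_missing(self, rng):
        attr = attribution_from(np.ones((20, 2, 2)))
        degron = degron_from(np.full(20, 0.5), log2fc=rng.normal(size=20))
        out = shap_lfc_correlation([attr], degron)
        assert out["shap_r_mean"].isna().all()

    def test_too_few_genes_is_an_error(self, rng):
        attr = attribution_from(rng.normal(size=(2, 2, 2)))
        degron = degron_from([0.5, 0.5], log2fc=[1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            shap_lfc_correlation([attr], degron)


class TestCoefficientContrast:
    def tables(self, rng, n=300, shift=0.0):
        ids = [f"g{i:04d}" for i in range(2 * n)]
        X = rng.normal(size=(2 * n, 4))
        beta = np.array([1.0, -0.5, 0.3, 0.8])
        y = X @ beta + rng.normal(size=2 * n)
        y[:n] += shift * X[:n, 0]  # group-specific slope change on feature 0
        data = pd.DataFrame(X, index=ids)
        data.columns = pd.MultiIndex.from_tuples(
            [("a", "promoter"), ("a", "body"), ("b", "promoter"), ("b", "body")]
        )
        feats = GeneFeatureTable(data, "standardized")
        pol = PolIITargets(pd.DataFrame({"promoter": y, "body": y}, index=ids),
                           "standardized")
        padj = np.concatenate([np.full(n, 0.01), np.full(n, 0.5)])
        labels = GeneLabels(pd.Series(
            np.where(padj < 0.05, "direct_target", "random"), index=ids))
        return feats, pol, labels

    def test_same_process_is_mostly_indistinguishable(self):
        # averaged over several data draws: disjoint 95% CIs under the null
        # are rare, so almost all coefficients are indistinguishable
        rates = []
        for seed in range(5):
            feats, pol, labels = self.tables(np.random.default_rng(seed), n=500)
            out = coefficient_contrast(feats, pol, labels)
            rates.append((~out["distinguishable"]).mean())
        assert np.mean(rates) >= 0.9

    def test_large_planted_difference_is_detected(self, rng):
        feats, pol, labels = self.tables(rng, shift=0.5)
        out = coefficient_contrast(feats, pol, labels)
        hit = out[(out["assay"] == "a") & (out["context"] == "promoter")]
        assert hit["distinguishable"].all()

    def test_small_group_is_an_error_with_required_n(self, rng):
        feats, pol, labels = self.tables(rng, n=3)
        with pytest.raises(ValueError, match="need more than"):
            coefficient_contrast(feats, pol, labels)


class TestCrossDataset:
    def test_identity_transfer_reproduces_within_dataset_result(self, rng):
        attr = attribution_from(rng.normal(size=(100, 3, 2)))
        padj = np.concatenate([np.full(40, 0.01), np.full(60, 0.5)])
        labels = stratify_genes(degron_from(padj))
        within = balanced_group_importance(attr, labels, size=20, n_repeats=10, seed=5)
        transfer = cross_dataset_eval(attr, labels, size=20, n_repeats=10, seed=5)
        assert np.allclose(within.table, transfer.table)
        assert transfer.intersection == 100

    def test_disjoint_universes_are_an_error(self, rng):
        attr = attribution_from(rng.normal(size=(10, 2, 2)),
                                gene_ids=[f"x{i}" for i in range(10)])
        labels = stratify_genes(degron_from([0.01, 0.5]))
        with pytest.raises(ValueError, match="shared"):
            cross_dataset_eval(attr, labels)


class TestCorrelationAudit:
    def table(self, values, feats):
        data = pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))])
        data.columns = pd.MultiIndex.from_tuples(feats)
        return GeneFeatureTable(data, "standardized")

    def test_duplicated_feature_is_flagged_at_unit_correlation(self, rng):
        x = rng.normal(size=200)
        tbl = self.table(np.column_stack([x, x, rng.normal(size=200)]),
                         [("a", "promoter"), ("a", "body"), ("b", "promoter")])
        audit = feature_correlation_audit(tbl)
        assert any(r == pytest.approx(1.0) for _, _, r in audit.flagged)

    def test_independent_features_stay_below_point_one(self, rng):
        tbl = self.table(rng.normal(size=(5000, 4)),
                         [("a", "promoter"), ("a", "body"),
                          ("b", "promoter"), ("b", "body")])
        audit = feature_correlation_audit(tbl)
        off = audit.matrix.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1
        assert not audit.flagged

    def test_matrix_symmetric_with_unit_diagonal(self, rng):
        tbl = self.table(rng.normal(size=(50, 3)),
                         [("a", "promoter"), ("b", "promoter"), ("c", "promoter")])
        m = feature_correlation_audit(tbl).matrix.to_numpy()
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)

    def test_zero_variance_feature_is_an_error(self, rng):
        vals = rng.normal(size=(30, 2))
        vals[:, 1] = 2.0
        tbl = self.table(vals, [("a", "promoter"), ("b", "promoter")])
        with pytest.raises(ValueError, match="zero-variance"):
            feature_correlation_audit(tbl)


def test_evaluation_invariant_to_gene_row_permutation(rng):
    """Shuffling input rows must not change any evaluation statistic."""
    n = 120
    padj = np.concatenate([np.full(50, 0.01), np.full(70, 0.5)])
    degron = degron_from(padj)
    labels = stratify_genes(degron)
    attr = attribution_from(rng.normal(size=(n, 3, 2)))
    perm = rng.permutation(n)
    attr_perm = AttributionMatrix(
        gene_ids=[attr.gene_ids[i] for i in perm],
        feature_ids=attr.feature_ids,
        values=attr.values[perm],
        base_values=attr.base_values,
        residuals=attr.residuals[perm],
        method="test",
    )
    a = balanced_group_importance(attr, labels, size=30, n_repeats=20, seed=7).table
    b = balanced_group_importance(attr_perm, labels, size=30, n_repeats=20, seed=7).table
    assert np.allclose(a, b)
    ca = rank_capture(shap_scores(attr, attr.feature_ids), labels).curve
    cb = rank_capture(shap_scores(attr_perm, attr.feature_ids), labels).curve
    assert (ca["fraction"] == cb["fraction"]).all()
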