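"""Validation statistics contrasting attributions with degron ground truth.

Genes are stratified by the degron experiment's adjusted p-value into
direct targets (padj < alpha) and random genes (padj > alpha); genes with
missing padj — or padj exactly equal to alpha, which the strict
inequalities leave undefined — are excluded from contrasts.  The central
statistic is the balanced subsampled group contrast of mean absolute
Shapley values (50 repeats of 50 targets + 50 randoms by default), plus
rank-capture curves against a raw-signal baseline, |phi|–|log2FC|
correlations with split-wise dispersion, separate per-group linear fits
with interval overlap verdicts, cross-dataset transfer and the pairwise
feature-correlation audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .attribution import AttributionMatrix
from .ingest import CONTEXTS, DegronTable, GeneFeatureTable, PolIITargets
from .regression import OUTPUT_NAMES, fit_linear

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@dataclass
class GeneLabels:
    """gene_id -> direct_target / random / excluded, with provenance."""

    labels: pd.Series
    alpha: float = 0.05
    source: str = "degron"

    def genes(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def n_targets(self) -> int:
        return int((self.labels == "direct_target").sum())

    @property
    def prevalence(self) -> float:
        labelled = (self.labels != "excluded").sum()
        return self.n_targets / labelled if labelled else float("nan")


def stratify_genes(degron: DegronTable, alpha: float = 0.05) -> GeneLabels:
    """Label genes by the degron adjusted p-value threshold."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if degron.data.empty:
        raise ValueError("degron table is empty")
    padj = degron.data["padj"]
    labels = pd.Series("excluded", index=padj.index, dtype=object)
    labels[padj < alpha] = "direct_target"
    labels[padj > alpha] = "random"
    if (labels == "excluded").all():
        raise ValueError("no stratifiable genes: every padj is missing or equals alpha")
    counts = labels.value_counts().to_dict()
    logger.info("stratify_genes(alpha=%g): %s", alpha, counts)
    return GeneLabels(labels=labels, alpha=alpha, source=degron.name)


# ---------------------------------------------------------------------------
# balanced group importance
# ---------------------------------------------------------------------------


@dataclass
class GroupImportance:
    """Across-repeat mean and SD of mean |phi| per feature and group."""

    table: pd.DataFrame  # index: feature (assay, context); columns below
    size: int
    n_repeats: int
    intersection: int | None = None

    def separation(self) -> pd.Series:
        """(target mean - random mean) / pooled across-repeat SD."""
        t = self.table
        pooled = np.sqrt((t["target_sd"] ** 2 + t["random_sd"] ** 2) / 2.0)
        return (t["target_mean"] - t["random_mean"]) / pooled


def balanced_group_importance(
    attr: AttributionMatrix,
    labels: GeneLabels,
    size: int = 50,
    n_repeats: int = 50,
    seed: int = 0,
) -> GroupImportance:
    """Balanced subsampled contrast of mean |phi| between targets and randoms.

    Each repeat draws ``size`` direct targets and ``size`` random genes
    without replacement (within the repeat) among attributed genes, and
    records the mean |phi| per feature (own output layer) per group; the
    across-repeat mean and standard deviation are reported.  If either
    group has fewer than ``size`` attributed genes the subsample size drops
    to the smaller group count with a logged warning.
    """
    phi = attr.own_layer().abs()
    lab = labels.labels.reindex(phi.index)
    # sorted so the subsample draws are invariant to input row order
    targets = sorted(phi.index[lab == "direct_target"])
    randoms = sorted(phi.index[lab == "random"])
    if not targets or not randoms:
        raise ValueError(
            f"empty group among attributed genes: {len(targets)} targets, "
            f"{len(randoms)} randoms"
        )
    eff_size = min(size, len(targets), len(randoms))
    if eff_size < size:
        logger.warning(
            "balanced_group_importance: subsample size reduced %d -> %d "
            "(group counts %d/%d)", size, eff_size, len(targets), len(randoms),
        )
    rng = np.random.default_rng(seed)
    t_means, r_means = [], []
    for _ in range(n_repeats):
        t_draw = rng.choice(targets, size=eff_size, replace=False)
        r_draw = rng.choice(randoms, size=eff_size, replace=False)
        t_means.append(phi.loc[t_draw].mean(axis=0))
        r_means.append(phi.loc[r_draw].mean(axis=0))
    t_df, r_df = pd.DataFrame(t_means), pd.DataFrame(r_means)
    table = pd.DataFrame(
        {
            "target_mean": t_df.mean(axis=0),
            "target_sd": t_df.std(axis=0, ddof=1),
            "random_mean": r_df.mean(axis=0),
            "random_sd": r_df.std(axis=0, ddof=1),
        }
    )
    return GroupImportance(table=table, size=eff_size, n_repeats=n_repeats)


def cross_dataset_eval(
    attr: AttributionMatrix,
    labels_other: GeneLabels,
    size: int = 50,
    n_repeats: int = 50,
    seed: int = 0,
) -> GroupImportance:
    """Transfer contrast: attributions from one dataset, labels from another.

    Restricts to the intersection of attributed and labelled genes, then
    delegates to :func:`balanced_group_importance`.
    """
    shared = [g for g in attr.gene_ids if g in labels_other.labels.index]
    if not shared:
        raise ValueError("no genes shared between attributions and labels")
    idx = [attr.gene_ids.index(g) for g in shared]
    sub = AttributionMatrix(
        gene_ids=shared,
        feature_ids=attr.feature_ids,
        values=attr.values[idx],
        base_values=attr.base_values,
        residuals=attr.residuals[idx],
        method=attr.method,
        provenance=dict(attr.provenance, transfer_source=labels_other.source),
    )
    out = balanced_group_importance(sub, labels_other, size, n_repeats, seed)
    out.intersection = len(shared)
    logger.info("cross_dataset_eval: %d shared genes", len(shared))
    return out


# ---------------------------------------------------------------------------
# rank capture
# ---------------------------------------------------------------------------


@dataclass
class CaptureCurve:
    """Fraction of direct targets among the top-k ranked genes, for all k."""

    curve: pd.DataFrame  # columns: k, fraction
    source: str

    @property
    def prevalence(self) -> float:
        return float(self.curve["fraction"].iloc[-1])

    def fraction_at(self, frac_top: float) -> float:
        k = max(1, int(round(frac_top * len(self.curve))))
        return float(self.curve["fraction"].iloc[k - 1])


def rank_capture(scores: pd.Series, labels: GeneLabels, source: str = "shap") -> CaptureCurve:
    """Capture curve of a gene ranking against direct-target labels.

    Genes sort by descending score with lexicographic gene-id tie-breaking;
    only labelled (non-excluded) genes participate, so the curve's endpoint
    equals the global prevalence exactly.
    """
    if scores.empty:
        raise ValueError("empty score vector")
    lab = labels.labels.reindex(scores.index)
    keep = lab.isin(["direct_target", "random"])
    if not keep.any():
        raise ValueError("no labelled genes among the scored genes")
    scores, lab = scores[keep], lab[keep]
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    is_target = (lab.loc[order] == "direct_target").to_numpy()
    frac = np.cumsum(is_target) / np.arange(1, len(order) + 1)
    return CaptureCurve(
        curve=pd.DataFrame({"k": np.arange(1, len(order) + 1), "fraction": frac}),
        source=source,
    )


def shap_scores(attr: AttributionMatrix, score_features) -> pd.Series:
    """Summed |phi| over the named features, both output layers."""
    feats = list(score_features)
    if not feats:
        raise ValueError("score_features is empty")
    return attr.summed_importance(feats)


def signal_scores(
    features_std: GeneFeatureTable, assays, contexts=CONTEXTS
) -> pd.Series:
    """Raw-signal baseline: summed normalised (log10 + z-score) signal of the
    degraded assay(s) over the requested contexts."""
    if features_std.transform != "standardized":
        raise ValueError("signal baseline expects standardized features")
    cols = [(a, c) for a in assays for c in contexts]
    missing = [c for c in cols if c not in features_std.feature_ids]
    if missing:
        raise KeyError(f"unknown feature(s) {missing}")
    return features_std.data[cols].sum(axis=1)


# ---------------------------------------------------------------------------
# |phi| - log2FC correlation
# ---------------------------------------------------------------------------


def shap_lfc_correlation(
    attrs: list[AttributionMatrix],
    degron: DegronTable,
    features_std: GeneFeatureTable | None = None,
) -> pd.DataFrame:
    """Per-feature |Pearson r| between per-gene |phi| and |log2FC|.

    For each feature the per-gene summed |phi| across both output layers is
    correlated with |log2FC| over that split's attributed genes; the table
    reports the mean and SD over splits.  When ``features_std`` is given
    the baseline comparator — |standardized signal| correlated identically —
    is included.  Zero-variance cases yield NaN (logged).
    """
    lfc = degron.data["log2fc"].abs()
    feats = attrs[0].feature_ids
    rows = {f: {"shap": [], "signal": []} for f in feats}
    for attr in attrs:
        genes = [g for g in attr.gene_ids if g in lfc.index]
        if len(genes) < 3:
            raise ValueError("need at least 3 genes with both phi and log2FC")
        y = lfc.loc[genes].to_numpy()
        for j, f in enumerate(feats):
            idx = [attr.gene_ids.index(g) for g in genes]
            x = np.abs(attr.values[idx, j, :]).sum(axis=1)
            rows[f]["shap"].append(_abs_pearson(x, y, f, "shap"))
            if features_std is not None:
                s = features_std.data[f].reindex(genes).abs().to_numpy()
                rows[f]["signal"].append(_abs_pearson(s, y, f, "signal"))
    out = {}
    for f, d in rows.items():
        rec = {
            "shap_r_mean": np.nanmean(d["shap"]),
            "shap_r_sd": np.nanstd(d["shap"], ddof=1) if len(d["shap"]) > 1 else np.nan,
        }
        if features_std is not None:
            rec["signal_r_mean"] = np.nanmean(d["signal"])
            rec["signal_r_sd"] = (
                np.nanstd(d["signal"], ddof=1) if len(d["signal"]) > 1 else np.nan
            )
        out[f] = rec
    return pd.DataFrame(out).T


def _abs_pearson(x, y, feature, kind) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning(
            "correlation undefined for %s (%s): zero variance", feature, kind
        )
        return np.nan
    return abs(float(stats.pearsonr(x, y)[0]))


# ---------------------------------------------------------------------------
# per-group linear fits
# ---------------------------------------------------------------------------


def coefficient_contrast(
    features_std: GeneFeatureTable,
    polII_std: PolIITargets,
    labels: GeneLabels,
) -> pd.DataFrame:
    """Separate OLS fits on targets vs randoms with 95% CI overlap verdicts.

    A coefficient is "distinguishable" iff its two 95% intervals are
    disjoint.  Requires both groups to exceed n_features + 2 genes.
    """
    m = len(features_std.feature_ids)
    fits = {}
    for group in ("direct_target", "random"):
        genes = [g for g in features_std.gene_ids if labels.labels.get(g) == group]
        if len(genes) <= m + 2:
            raise ValueError(
                f"group {group!r} has {len(genes)} genes; need more than {m + 2}"
            )
        fits[group] = fit_linear(
            features_std.data.loc[genes].to_numpy(),
            polII_std.data.loc[genes].to_numpy(),
            feature_names=features_std.feature_ids,
        )
    rows = []
    for k, out in enumerate(OUTPUT_NAMES):
        for j, feat in enumerate(features_std.feature_ids):
            t, r = fits["direct_target"], fits["random"]
            lo_t, hi_t = t.conf_int[k, j]
            lo_r, hi_r = r.conf_int[k, j]
            rows.append({
                "assay": feat[0], "context": feat[1], "output": out,
                "coef_target": t.coef[k, j], "ci_lo_target": lo_t, "ci_hi_target": hi_t,
                "coef_random": r.coef[k, j], "ci_lo_random": lo_r, "ci_hi_random": hi_r,
                "distinguishable": bool(hi_t < lo_r or hi_r < lo_t),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature correlation audit
# ---------------------------------------------------------------------------


@dataclass
class CorrelationAudit:
    matrix: pd.DataFrame
    order: list
    flagged: list = field(default_factory=list)  # pairs with |r| > threshold


def feature_correlation_audit(
    features: GeneFeatureTable, flag_threshold: float = 0.9
) -> CorrelationAudit:
    """Pairwise Pearson correlations with average-linkage ordering.

    Flags feature pairs with |r| above ``flag_threshold``.  Zero-variance
    features are an error.
    """
    data = features.data
    if data.shape[1] < 2:
        raise ValueError("need at least 2 features to audit")
    sd = data.std(axis=0, ddof=0)
    tiny = sd <= 1e-12 * np.maximum(1.0, data.mean(axis=0).abs())
    if tiny.any():
        bad = [str(tuple(c)) for c in sd.index[tiny]]
        raise ValueError(f"zero-variance feature(s): {bad}")
    corr = data.corr()
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    link = hierarchy.linkage(np.clip(condensed, 0, None), method="average")
    order = [features.feature_ids[i] for i in hierarchy.leaves_list(link)]
    flagged = []
    feats = features.feature_ids
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            r = float(corr.iloc[i, j])
            if abs(r) > flag_threshold:
                flagged.append((feats[i], feats[j], r))
    return CorrelationAudit(matrix=corr, order=order, flagged=flagged)
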