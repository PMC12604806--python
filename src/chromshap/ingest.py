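"""Readers, containers and preprocessing for per-gene occupancy tables.

The pipeline consumes the tabular outputs of a standard ChIP-seq
quantification workflow: per-assay signal tables (mean fold-enrichment over
promoter and gene-body intervals, as written by ``bigWigAverageOverBed``), a
BED-like gene annotation, and differential-expression result tables from
degron experiments.  This module turns those files into the in-memory
containers the model consumes, applies the log10 + z-score transform with
train-set-only statistics, and builds the stratified train/validation/test
splits.

Coordinates are 0-based half-open throughout (BED native).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("promoter", "body")

#: Column names of the six-column ``bigWigAverageOverBed`` output.
QUANT_COLUMNS = ("name", "size", "covered", "sum", "mean0", "mean")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def canonical_feature_order(feature_ids) -> list[tuple[str, str]]:
    """Sort (assay, context) pairs: assay alphabetical, promoter before body."""
    rank = {c: i for i, c in enumerate(CONTEXTS)}
    return sorted(feature_ids, key=lambda f: (f[0], rank[f[1]]))


@dataclass
class GeneFeatureTable:
    """Genes x (assay, context) signal matrix with an explicit transform state.

    ``data`` is indexed by gene id with a two-level column index
    ``(assay, context)``.  ``transform`` tracks the state machine
    raw -> log10 -> standardized; fitted means/scales live on the
    :class:`Scaler` that produced a standardized table.
    """

    data: pd.DataFrame
    transform: str = "raw"

    def __post_init__(self) -> None:
        if self.transform not in ("raw", "log10", "standardized"):
            raise ValueError(f"unknown transform state {self.transform!r}")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[tuple[str, str]]:
        return [tuple(c) for c in self.data.columns]

    @property
    def assays(self) -> list[str]:
        seen: dict[str, None] = {}
        for assay, _ in self.feature_ids:
            seen.setdefault(assay)
        return list(seen)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def loc(self, gene_ids) -> "GeneFeatureTable":
        return GeneFeatureTable(self.data.loc[list(gene_ids)], self.transform)


@dataclass
class PolIITargets:
    """Per-gene Pol-II signal at the promoter and across the gene body."""

    data: pd.DataFrame  # columns: promoter, body
    transform: str = "raw"

    def __post_init__(self) -> None:
        missing = [c for c in CONTEXTS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Pol-II table lacks columns {missing}")
        self.data = self.data[list(CONTEXTS)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def loc(self, gene_ids) -> "PolIITargets":
        return PolIITargets(self.data.loc[list(gene_ids)], self.transform)


@dataclass
class DegronTable:
    """log2 fold change and adjusted p-value from an acute-depletion DE table."""

    data: pd.DataFrame  # index gene_id; columns log2fc, padj
    name: str = "degron"

    def __post_init__(self) -> None:
        for col in ("log2fc", "padj"):
            if col not in self.data.columns:
                raise ValueError(f"degron table lacks column {col!r}")
        padj = self.data["padj"]
        bad = padj.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("padj values outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SplitSpec:
    """One train/validation/test partition of the gene set."""

    split_index: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int = 42

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split partitions overlap")

    @property
    def all_ids(self) -> list[str]:
        return self.train_ids + self.val_ids + self.test_ids


# ---------------------------------------------------------------------------
# annotation and region derivation
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """BED6-style gene annotation (0-based half-open, strand-resolved)."""

    data: pd.DataFrame  # columns chrom, start, end, gene_id, strand

    def __post_init__(self) -> None:
        d = self.data
        if d["gene_id"].duplicated().any():
            dupes = d.loc[d["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in annotation: {dupes[:5]}")
        if (d["start"] >= d["end"]).any():
            bad = d.loc[d["start"] >= d["end"], "gene_id"].tolist()
            raise ValueError(f"start >= end for genes {bad[:5]}")
        if not d["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")


def read_annotation(path) -> GeneAnnotation:
    """Read a BED6 annotation (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"annotation {path} has {df.shape[1]} columns, BED6 expected")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
    return GeneAnnotation(df[["chrom", "start", "end", "gene_id", "strand"]])


def derive_regions(
    annotation: GeneAnnotation,
    promoter_halfwidth: int = 1000,
    body_offset: int = 1000,
):
    """Derive promoter and gene-body intervals from a gene annotation.

    Promoter: TSS +/- ``promoter_halfwidth``; gene body: TSS + ``body_offset``
    to the TES, both strand-resolved and clipped at coordinate 0.  Genes too
    short to have a gene body are excluded (returned in the third element)
    and logged.

    Returns ``(promoters, bodies, excluded_ids)`` where the first two are
    BED-like DataFrames (chrom, start, end, gene_id, strand).
    """
    rows_prom, rows_body, excluded = [], [], []
    for rec in annotation.data.itertuples(index=False):
        if rec.strand == "+":
            tss, tes = rec.start, rec.end
            prom = (max(0, tss - promoter_halfwidth), tss + promoter_halfwidth)
            body = (tss + body_offset, tes)
        else:
            tss, tes = rec.end, rec.start
            prom = (max(0, tss - promoter_halfwidth), tss + promoter_halfwidth)
            body = (tes, tss - body_offset)
        rows_prom.append((rec.chrom, prom[0], prom[1], rec.gene_id, rec.strand))
        if body[0] >= body[1]:
            excluded.append(rec.gene_id)
        else:
            rows_body.append((rec.chrom, max(0, body[0]), body[1], rec.gene_id, rec.strand))
    if excluded:
        logger.info(
            "derive_regions: %d gene(s) shorter than body offset excluded: %s",
            len(excluded), excluded[:10],
        )
    cols = ["chrom", "start", "end", "gene_id", "strand"]
    return (
        pd.DataFrame(rows_prom, columns=cols),
        pd.DataFrame(rows_body, columns=cols),
        excluded,
    )


# ---------------------------------------------------------------------------
# signal quantification tables
# ---------------------------------------------------------------------------


def read_signal_quant(
    path,
    name_col: str = "name",
    value_col: str = "mean0",
    header: bool = False,
) -> pd.Series:
    """Read one per-gene mean-signal column from a quantification table.

    The default dialect is the headerless six-column output of
    ``bigWigAverageOverBed`` (name, size, covered, sum, mean0, mean); the
    zero-filled mean ``mean0`` is used unless ``value_col`` says otherwise.
    """
    if header:
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] != len(QUANT_COLUMNS):
            raise ValueError(
                f"{path}: expected {len(QUANT_COLUMNS)} columns "
                f"(bigWigAverageOverBed dialect), found {df.shape[1]}"
            )
        df.columns = list(QUANT_COLUMNS)
    for col in (name_col, value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    names = df[name_col].astype(str)
    if names.duplicated().any():
        dupes = names[names.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene id(s) {dupes[:5]}")
    values = pd.to_numeric(df[value_col], errors="coerce")
    if values.isna().any():
        bad = names[values.isna()].tolist()
        raise ValueError(f"{path}: non-numeric value(s) for gene(s) {bad[:5]}")
    return pd.Series(values.to_numpy(dtype=float), index=names.to_numpy(), name=value_col)


def build_feature_matrix(
    columns: dict[tuple[str, str], pd.Series],
    gene_ids=None,
) -> GeneFeatureTable:
    """Assemble per-(assay, context) signal columns into a raw feature table.

    Genes absent from any column are dropped (count logged); column order is
    canonicalised (assay alphabetical, promoter before body).
    """
    if not columns:
        raise ValueError("no signal columns supplied")
    common = None
    for series in columns.values():
        ids = set(series.index)
        common = ids if common is None else (common & ids)
    if gene_ids is not None:
        requested = list(gene_ids)
        common &= set(requested)
        universe = requested
    else:
        universe = list(next(iter(columns.values())).index)
    keep = [g for g in universe if g in common]
    dropped = len(universe) - len(keep)
    if not keep:
        raise ValueError("no gene ids shared by all signal columns")
    if dropped:
        logger.info("build_feature_matrix: dropped %d gene(s) missing from >=1 column", dropped)
    order = canonical_feature_order(columns.keys())
    data = pd.DataFrame(
        {feat: columns[feat].loc[keep].to_numpy() for feat in order}, index=keep
    )
    data.columns = pd.MultiIndex.from_tuples(order, names=["assay", "context"])
    return GeneFeatureTable(data, transform="raw")


def read_degron_table(path, name: str = "degron") -> DegronTable:
    """Read a DE results TSV with header gene_id, log2FoldChange, padj."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "log2FoldChange", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = df[required].rename(columns={"log2FoldChange": "log2fc"}).set_index("gene_id")
    return DegronTable(out, name=name)


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------


@dataclass
class Scaler:
    """log10 + z-score transform fitted on the training partition only."""

    pseudocount: float
    feature_means: pd.Series
    feature_scales: pd.Series
    output_means: pd.Series
    output_scales: pd.Series
    train_ids: list[str] = field(default_factory=list)

    def transform_features(self, table: GeneFeatureTable) -> GeneFeatureTable:
        if table.transform != "raw":
            raise ValueError("scaler expects a raw-scale feature table")
        logged = np.log10(table.data + self.pseudocount)
        std = (logged - self.feature_means) / self.feature_scales
        return GeneFeatureTable(std, transform="standardized")

    def transform_outputs(self, polII: PolIITargets) -> PolIITargets:
        if polII.transform != "raw":
            raise ValueError("scaler expects raw-scale Pol-II targets")
        logged = np.log10(polII.data + self.pseudocount)
        std = (logged - self.output_means) / self.output_scales
        return PolIITargets(std, transform="standardized")


def fit_transform(
    features: GeneFeatureTable,
    polII: PolIITargets,
    train_ids,
    pseudocount: float = 1e-3,
):
    """log10-transform then standardize, with statistics from ``train_ids`` only.

    Returns ``(features_std, polII_std, scaler)``.  A zero-variance feature on
    the training set is an error naming the feature.
    """
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("train_ids is empty")
    if features.transform != "raw" or polII.transform != "raw":
        raise ValueError("fit_transform expects raw-scale inputs")

    logged_X = np.log10(features.data + pseudocount)
    logged_Y = np.log10(polII.data + pseudocount)
    train_X = logged_X.loc[train_ids]
    train_Y = logged_Y.loc[train_ids]

    fm, fs = train_X.mean(axis=0), train_X.std(axis=0, ddof=0)
    om, os_ = train_Y.mean(axis=0), train_Y.std(axis=0, ddof=0)
    tiny_f = fs <= 1e-12 * np.maximum(1.0, fm.abs())
    tiny_o = os_ <= 1e-12 * np.maximum(1.0, om.abs())
    zero = [str(tuple(c)) for c in fs.index[tiny_f]]
    zero += [f"polII:{c}" for c in os_.index[tiny_o]]
    if zero:
        raise ValueError(f"zero-variance feature(s) on training set: {zero}")

    scaler = Scaler(
        pseudocount=pseudocount,
        feature_means=fm,
        feature_scales=fs,
        output_means=om,
        output_scales=os_,
        train_ids=train_ids,
    )
    return (
        scaler.transform_features(features),
        scaler.transform_outputs(polII),
        scaler,
    )


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _apportion(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across strata ``counts``."""
    if counts.sum() == 0:
        return np.zeros_like(counts)
    quota = counts * total / counts.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def make_splits(
    gene_ids,
    degron: DegronTable,
    n_splits: int = 5,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 42,
    alpha: float = 0.05,
) -> list[SplitSpec]:
    """Build stratified, shuffled train/validation/test splits.

    Stratification uses direct-target status (padj < ``alpha``) so each test
    set preserves the global target fraction to within one gene; genes with
    missing padj form their own stratum (retained for training, excluded from
    target/random contrasts downstream).  Split ``i`` shuffles with
    ``seed + i``, so splits differ but the whole list is deterministic.
    """
    gene_ids = list(gene_ids)
    if len(gene_ids) < 10:
        raise ValueError(f"need at least 10 genes to split, got {len(gene_ids)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} do not sum to 1")

    padj = degron.data["padj"].reindex(gene_ids)
    strata = {
        "target": [g for g in gene_ids if padj[g] < alpha],
        "random": [g for g in gene_ids if padj[g] > alpha],
        "unlabelled": [
            g for g in gene_ids if not (padj[g] < alpha) and not (padj[g] > alpha)
        ],
    }

    n = len(gene_ids)
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    counts = np.array([len(v) for v in strata.values()])
    test_alloc = _apportion(counts, n_test)
    val_alloc = _apportion(counts, n_val)

    splits = []
    for i in range(1, n_splits + 1):
        rng = np.random.default_rng(seed + i)
        train: list[str] = []
        val: list[str] = []
        test: list[str] = []
        for (name, members), n_t, n_v in zip(strata.items(), test_alloc, val_alloc):
            perm = list(np.array(members)[rng.permutation(len(members))])
            test += perm[:n_t]
            val += perm[n_t : n_t + n_v]
            train += perm[n_t + n_v :]
        splits.append(SplitSpec(i, sorted(train), sorted(val), sorted(test), seed=seed))
    return splits
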