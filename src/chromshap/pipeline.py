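"""Configuration-driven orchestration of the full analysis.

One :func:`run_pipeline` call executes simulate/ingest -> stratified splits
-> per-family fits -> test-set attribution -> evaluation, writing every
stage output as a file and recording content hashes in a run manifest.
Re-running with an identical configuration reproduces identical hashes:
every stochastic stage is seeded from the run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import attribution as attr_mod
from . import evaluate as eval_mod
from .ingest import (
    CONTEXTS,
    PolIITargets,
    build_feature_matrix,
    make_splits,
    read_degron_table,
    read_signal_quant,
)
from .regression import PolIIModel
from .syndata import SynConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "synthetic"
    syn: SynConfig = field(default_factory=SynConfig)
    # real mode: {"assay:context": path} plus polII entries "polII:context"
    quant_paths: dict = field(default_factory=dict)
    degron_path: str | None = None
    families: tuple[str, ...] = ("linear", "mlp")
    ablate: tuple = ()
    attribution_method: str = "exact"
    n_background: int = 25
    kernel_samples: int = 2048
    alpha: float = 0.05
    subsample_size: int = 50
    n_repeats: int = 50
    n_splits: int = 5
    score_assays: tuple[str, ...] = ()  # default: synthetic driver assays
    pseudocount: float = 1e-3
    seed: int = 42
    outdir: str = "chromshap_run"

    def resolved_score_assays(self) -> tuple[str, ...]:
        if self.score_assays:
            return tuple(self.score_assays)
        if self.mode == "synthetic":
            return tuple(self.syn.driver_assays)
        return ()


def validate_config(config: RunConfig):
    """Materialise defaults and collect *all* configuration errors."""
    errors: list[str] = []
    if config.mode not in ("synthetic", "real"):
        errors.append(f"mode must be 'synthetic' or 'real', got {config.mode!r}")
    if not 0.0 < config.alpha < 1.0:
        errors.append(f"alpha must lie in (0, 1), got {config.alpha}")
    if not config.families:
        errors.append("families must name at least one model family")
    for fam in config.families:
        if fam not in ("linear", "mlp", "gbt"):
            errors.append(f"unknown model family {fam!r}")
    if config.attribution_method not in ("exact", "kernel", "linear"):
        errors.append(f"unknown attribution method {config.attribution_method!r}")
    if config.attribution_method == "linear" and set(config.families) != {"linear"}:
        if "linear" not in config.families:
            errors.append("attribution method 'linear' requires the linear family")
    if config.n_background < 1:
        errors.append(f"n_background must be >= 1, got {config.n_background}")
    if config.subsample_size < 1:
        errors.append(f"subsample_size must be >= 1, got {config.subsample_size}")
    if config.n_repeats < 1:
        errors.append(f"n_repeats must be >= 1, got {config.n_repeats}")
    if config.n_splits < 1:
        errors.append(f"n_splits must be >= 1, got {config.n_splits}")
    if config.mode == "real":
        if not config.quant_paths:
            errors.append("real mode requires quant_paths")
        for key, path in config.quant_paths.items():
            if ":" not in key:
                errors.append(f"quant_paths key {key!r} is not 'assay:context'")
            elif not os.path.exists(path):
                errors.append(f"quant file missing: {path}")
        if not config.degron_path:
            errors.append("real mode requires degron_path")
        elif not os.path.exists(config.degron_path):
            errors.append(f"degron table missing: {config.degron_path}")
        if not config.score_assays:
            errors.append("real mode requires score_assays (the degraded assay)")
    return config, errors


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_real(config: RunConfig):
    feature_cols, polII_cols = {}, {}
    for key, path in config.quant_paths.items():
        assay, ctx = key.split(":", 1)
        col = read_signal_quant(path)
        if assay == "polII":
            polII_cols[ctx] = col
        else:
            feature_cols[(assay, ctx)] = col
    if set(polII_cols) != set(CONTEXTS):
        raise ValueError("real mode needs polII:promoter and polII:body quant files")
    features = build_feature_matrix(feature_cols)
    polII = PolIITargets(pd.DataFrame(polII_cols).loc[features.gene_ids], "raw")
    degron = read_degron_table(config.degron_path)
    return SimpleNamespace(features=features, polII=polII, degron=degron, truth=None)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config, errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    os.makedirs(config.outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def save_frame(name: str, frame: pd.DataFrame, index=False) -> None:
        path = os.path.join(config.outdir, name)
        frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
        paths[name] = path

    # ----- stage: simulate / ingest ------------------------------------
    try:
        if config.mode == "synthetic":
            cohort = generate_cohort(config.syn)
            cohort_paths = write_cohort(cohort, os.path.join(config.outdir, "cohort"))
            paths.update({f"cohort/{k}": v for k, v in cohort_paths.items()})
        else:
            cohort = _load_real(config)
    except Exception as exc:  # noqa: BLE001 - annotate with stage name
        raise RuntimeError(f"stage 'ingest' failed: {exc}") from exc

    if config.ablate:
        from .regression import ablate_features

        cohort = SimpleNamespace(
            features=ablate_features(cohort.features, config.ablate),
            polII=cohort.polII, degron=cohort.degron,
            truth=getattr(cohort, "truth", None),
        )

    labels = eval_mod.stratify_genes(cohort.degron, alpha=config.alpha)
    direct_targets = set(labels.genes("direct_target"))
    splits = make_splits(
        cohort.features.gene_ids, cohort.degron,
        n_splits=config.n_splits, seed=config.seed, alpha=config.alpha,
    )

    # ----- stage: fit + attribute ---------------------------------------
    r2_rows = []
    attrs_by_family: dict[str, list] = {fam: [] for fam in config.families}
    features_std_all = None
    for split in splits:
        try:
            model = PolIIModel.from_cohort(cohort, split, pseudocount=config.pseudocount)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'transform' failed on split {split.split_index}: {exc}") from exc
        if split.split_index == 1:
            features_std_all = model.features
        background = attr_mod.build_background(
            model.features, split.train_ids, excluded_ids=direct_targets,
            k=config.n_background, seed=config.seed + split.split_index,
        )
        for fam in config.families:
            try:
                res = model.fit(family=fam, seed=config.seed + split.split_index)
                r2_rows.append(res.rsquared_table())
                method = config.attribution_method
                if method == "linear" and fam != "linear":
                    method = "exact"
                mat = res.shap_values(
                    method=method, background=background,
                    seed=config.seed + split.split_index,
                    n_samples=config.kernel_samples,
                )
                attrs_by_family[fam].append(mat)
                mat.write(
                    os.path.join(config.outdir, f"shap_{fam}_split{split.split_index}.tsv"),
                    os.path.join(config.outdir, f"shap_{fam}_split{split.split_index}.json"),
                )
                paths[f"shap_{fam}_split{split.split_index}.tsv"] = os.path.join(
                    config.outdir, f"shap_{fam}_split{split.split_index}.tsv"
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"stage 'fit/attribute' failed (family={fam}, "
                    f"split={split.split_index}): {exc}"
                ) from exc

    save_frame("r2_report.tsv", pd.concat(r2_rows, ignore_index=True))

    # ----- stage: evaluate ----------------------------------------------
    score_assays = config.resolved_score_assays()
    score_features = [
        f for f in cohort.features.feature_ids if f[0] in score_assays
    ]
    eval_summary: dict = {}
    for fam, mats in attrs_by_family.items():
        pooled = attr_mod.AttributionMatrix.concat(mats, dedupe=True)
        gi = eval_mod.balanced_group_importance(
            pooled, labels, size=config.subsample_size,
            n_repeats=config.n_repeats, seed=config.seed,
        )
        tab = gi.table.copy()
        tab["separation"] = gi.separation()
        tab.index = [f"{a}:{c}" for a, c in tab.index]
        save_frame(f"group_importance_{fam}.tsv", tab, index=True)

        curves = {}
        if score_features:
            shap_curve = eval_mod.rank_capture(
                eval_mod.shap_scores(pooled, score_features), labels, source="shap"
            )
            sig_curve = eval_mod.rank_capture(
                eval_mod.signal_scores(
                    features_std_all.loc(pooled.gene_ids), score_assays
                ),
                labels, source="signal",
            )
            save_frame(f"capture_{fam}_shap.tsv", shap_curve.curve)
            save_frame(f"capture_{fam}_signal.tsv", sig_curve.curve)
            curves = {
                "capture_top10_shap": shap_curve.fraction_at(0.10),
                "capture_top10_signal": sig_curve.fraction_at(0.10),
            }
        corr = eval_mod.shap_lfc_correlation(
            mats, cohort.degron, features_std=features_std_all
        )
        corr.index = [f"{a}:{c}" for a, c in corr.index]
        save_frame(f"lfc_correlation_{fam}.tsv", corr, index=True)
        eval_summary[fam] = {
            "separation": {
                f"{a}:{c}": float(s) for (a, c), s in gi.separation().items()
            },
            **curves,
        }

    audit = eval_mod.feature_correlation_audit(features_std_all)
    audit_tab = audit.matrix.copy()
    audit_tab.index = [f"{a}:{c}" for a, c in features_std_all.feature_ids]
    audit_tab.columns = audit_tab.index
    save_frame("feature_correlation.tsv", audit_tab, index=True)

    # ----- manifest ------------------------------------------------------
    manifest = {
        "config": _config_dict(config),
        "n_genes": len(cohort.features.gene_ids),
        "n_splits": len(splits),
        "alpha": config.alpha,
        "prevalence": labels.prevalence,
        "evaluation": eval_summary,
        "files": {name: _sha256(path) for name, path in sorted(paths.items())},
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %d output files, manifest at %s", len(paths), manifest_path)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    syn = d.pop("syn", None)
    cfg = RunConfig(**{k: v for k, v in d.items() if k in {
        f.name for f in dataclasses.fields(RunConfig)
    }})
    if syn is not None:
        syn = dict(syn)
        for key in ("assays", "driver_assays"):
            if key in syn:
                syn[key] = tuple(syn[key])
        cfg = dataclasses.replace(cfg, syn=SynConfig(**syn))
    for key in ("families", "score_assays", "ablate"):
        if key in d:
            cfg = dataclasses.replace(cfg, **{key: tuple(d[key])})
    return cfg
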