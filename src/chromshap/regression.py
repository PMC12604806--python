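"""Regressors mapping transformed chromatin features to the two Pol-II outputs.

Three model families are supported — ordinary least squares (with classical
95% coefficient intervals), a multilayer perceptron, and gradient-boosted
trees — each predicting both outputs (promoter, gene body) from one fitted
model.  Hyperparameters are chosen by a seeded random search scored on
validation-set R².

The user-facing entry point is the statsmodels-style pair
:class:`PolIIModel` / :class:`PolIIResults`; the module-level functions do
the work and are what the tests exercise directly.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neural_network import MLPRegressor
from xgboost import XGBRegressor

from .ingest import CONTEXTS, GeneFeatureTable, PolIITargets, SplitSpec, fit_transform

logger = logging.getLogger(__name__)

OUTPUT_NAMES = CONTEXTS  # (promoter, body)


def r_squared(y_true, y_pred) -> np.ndarray:
    """Coefficient of determination per output column.

    1 - SS_res/SS_tot with SS_tot about the mean of ``y_true``; raises on
    zero-variance truth, where R² is undefined.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float).T).T
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float).T).T
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if y_true.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    if (ss_tot == 0).any():
        raise ValueError("zero-variance y_true: R^2 undefined")
    ss_res = ((y_true - y_pred) ** 2).sum(axis=0)
    return 1.0 - ss_res / ss_tot


def _check_finite(name, arr):
    arr = np.asarray(arr, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains NaN or Inf")
    return arr


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MLPParams:
    hidden_layer_sizes: tuple[int, ...] = (64, 32)
    learning_rate_init: float = 1e-3
    alpha: float = 1e-4  # L2 weight decay
    max_epochs: int = 1500
    patience: int = 200
    tol: float = 0.0


@dataclass(frozen=True)
class GBTParams:
    learning_rate: float = 0.1
    max_depth: int = 6
    tree_method: str = "hist"
    n_estimators: int = 300
    early_stopping_rounds: int = 20

    def __post_init__(self) -> None:
        if not 6 <= self.max_depth <= 18:
            raise ValueError(f"max_depth must lie in [6, 18], got {self.max_depth}")
        if self.tree_method not in ("hist", "exact"):
            raise ValueError(f"tree_method must be 'hist' or 'exact', got {self.tree_method!r}")


@dataclass(frozen=True)
class HyperparamSpace:
    """Search space for the seeded random search.

    MLP: candidate hidden-layer shapes, log-uniform learning-rate and
    weight-decay ranges, rectified-linear activation throughout.  GBT:
    learning rate in [1e-3, 1e-1], max tree depth in [6, 18], histogram or
    exact split finding.
    """

    family: str = "mlp"
    hidden_sizes: tuple[tuple[int, ...], ...] = ((64,), (128, 64), (256, 128))
    lr_range: tuple[float, float] = (1e-4, 1e-2)
    alpha_range: tuple[float, float] = (1e-6, 1e-2)
    gbt_lr_range: tuple[float, float] = (1e-3, 1e-1)
    depth_range: tuple[int, int] = (6, 18)
    tree_methods: tuple[str, ...] = ("hist", "exact")
    budget: int = 10
    seed: int = 42

    def __post_init__(self) -> None:
        if self.family not in ("linear", "mlp", "gbt"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.budget < 1:
            raise ValueError(f"budget must be >= 1, got {self.budget}")
        for name, rng_ in (
            ("lr_range", self.lr_range),
            ("alpha_range", self.alpha_range),
            ("gbt_lr_range", self.gbt_lr_range),
            ("depth_range", self.depth_range),
        ):
            if rng_[0] > rng_[1]:
                raise ValueError(f"{name} is not ordered: {rng_}")
        if self.depth_range[0] < 6 or self.depth_range[1] > 18:
            raise ValueError(
                f"depth_range must stay within [6, 18], got {self.depth_range}"
            )

    def sample(self, rng: np.random.Generator):
        if self.family == "linear":
            return None
        if self.family == "mlp":
            lo, hi = np.log(self.lr_range[0]), np.log(self.lr_range[1])
            alo, ahi = np.log(self.alpha_range[0]), np.log(self.alpha_range[1])
            return MLPParams(
                hidden_layer_sizes=tuple(
                    self.hidden_sizes[rng.integers(len(self.hidden_sizes))]
                ),
                learning_rate_init=float(np.exp(rng.uniform(lo, hi))),
                alpha=float(np.exp(rng.uniform(alo, ahi))),
            )
        lo, hi = np.log(self.gbt_lr_range[0]), np.log(self.gbt_lr_range[1])
        return GBTParams(
            learning_rate=float(np.exp(rng.uniform(lo, hi))),
            max_depth=int(rng.integers(self.depth_range[0], self.depth_range[1] + 1)),
            tree_method=str(self.tree_methods[rng.integers(len(self.tree_methods))]),
        )


# ---------------------------------------------------------------------------
# fitted models
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """A trained two-output regressor with a uniform predict contract."""

    family: str
    predictor: object
    feature_names: list | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = _check_finite("X", X)
        out = self._raw_predict(X)
        out = np.asarray(out, dtype=float)
        if out.ndim == 1:
            out = out[:, None]
        return out

    def _raw_predict(self, X):
        return self.predictor.predict(X)


@dataclass
class LinearFit(FittedModel):
    """OLS fit with per-output coefficient vectors and 95% CIs."""

    coef: np.ndarray = None  # (n_outputs, n_features)
    intercept: np.ndarray = None  # (n_outputs,)
    conf_int: np.ndarray = None  # (n_outputs, n_features, 2)
    stderr: np.ndarray = None  # (n_outputs, n_features)

    def _raw_predict(self, X):
        return X @ self.coef.T + self.intercept


class _GBTPair:
    """One XGBoost ensemble per output behind a two-column predict."""

    def __init__(self, boosters):
        self.boosters = boosters

    def predict(self, X):
        return np.column_stack([b.predict(X) for b in self.boosters])


def fit_linear(X, Y, feature_names=None, ci_level: float = 0.95) -> LinearFit:
    """Ordinary least squares per output with classical normal-theory CIs.

    Raises on rank deficiency, naming the collinear columns (identified by
    pivoted QR on the centred design).
    """
    X = _check_finite("X", X)
    Y = _check_finite("Y", np.atleast_2d(np.asarray(Y, dtype=float).T).T)
    n, m = X.shape
    if n <= m:
        raise ValueError(f"need more rows ({n}) than features ({m}) for OLS")
    names = list(feature_names) if feature_names is not None else list(range(m))

    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < m + 1:
        # pivoted QR flags the columns that add no rank
        from scipy.linalg import qr as scipy_qr

        _, _, piv = scipy_qr(design, pivoting=True)
        redundant = sorted(
            (names[j - 1] if j > 0 else "intercept" for j in piv[rank:]), key=str
        )
        raise ValueError(f"rank-deficient design; collinear column(s): {redundant}")

    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ Y  # (m+1, k)
    resid = Y - design @ beta
    dof = n - (m + 1)
    sigma2 = (resid**2).sum(axis=0) / dof  # per output
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # (m+1, k)
    tq = stats.t.ppf(0.5 + ci_level / 2.0, dof)

    coef = beta[1:].T  # (k, m)
    stderr = se[1:].T
    ci = np.stack([coef - tq * stderr, coef + tq * stderr], axis=-1)
    return LinearFit(
        family="linear",
        predictor=None,
        feature_names=names,
        metadata={"n": n, "dof": dof, "ci_level": ci_level},
        coef=coef,
        intercept=beta[0],
        conf_int=ci,
        stderr=stderr,
    )


def fit_mlp(
    X,
    Y,
    params: MLPParams | None = None,
    seed: int = 42,
    X_val=None,
    Y_val=None,
    feature_names=None,
) -> FittedModel:
    """Train a rectified-linear feedforward network with a two-output head.

    Trained by Adam with L2 weight decay; one ``partial_fit`` pass per epoch
    so the validation-R² history is recorded, with early stopping after
    ``patience`` epochs without improvement beyond ``tol``.  The weights of
    the best validation epoch are restored.  Deterministic under ``seed``.
    """
    params = params or MLPParams()
    X = _check_finite("X", X)
    Y = _check_finite("Y", np.atleast_2d(np.asarray(Y, dtype=float).T).T)
    monitor_val = X_val is not None and Y_val is not None
    if monitor_val:
        X_val = _check_finite("X_val", X_val)
        Y_val = _check_finite("Y_val", np.atleast_2d(np.asarray(Y_val, dtype=float).T).T)

    net = MLPRegressor(
        hidden_layer_sizes=params.hidden_layer_sizes,
        activation="relu",
        solver="adam",
        alpha=params.alpha,
        learning_rate_init=params.learning_rate_init,
        random_state=seed,
        max_iter=1,
        warm_start=False,
    )
    history = []
    best_score, best_net, best_epoch, stall = -np.inf, None, 0, 0
    for epoch in range(params.max_epochs):
        net.partial_fit(X, Y)
        if not np.isfinite(net.loss_):
            raise RuntimeError(
                f"MLP training diverged at epoch {epoch}: loss={net.loss_!r}, "
                f"params={params}"
            )
        if monitor_val:
            score = float(np.mean(r_squared(Y_val, net.predict(X_val))))
        else:
            score = -float(net.loss_)
        history.append({"epoch": epoch, "train_loss": float(net.loss_), "score": score})
        if score > best_score + params.tol:
            best_score, best_epoch, stall = score, epoch, 0
            best_net = copy.deepcopy(net)
        else:
            stall += 1
            if stall >= params.patience:
                break
    return FittedModel(
        family="mlp",
        predictor=best_net if best_net is not None else net,
        feature_names=list(feature_names) if feature_names is not None else None,
        metadata={
            "params": params,
            "seed": seed,
            "history": history,
            "best_epoch": best_epoch,
            "best_score": best_score,
        },
    )


def fit_gbt(
    X,
    Y,
    params: GBTParams | None = None,
    seed: int = 42,
    X_val=None,
    Y_val=None,
    feature_names=None,
) -> FittedModel:
    """Gradient-boosted regression trees, one ensemble per output."""
    params = params or GBTParams()
    X = _check_finite("X", X)
    Y = _check_finite("Y", np.atleast_2d(np.asarray(Y, dtype=float).T).T)
    monitor_val = X_val is not None and Y_val is not None
    boosters = []
    histories = []
    for j in range(Y.shape[1]):
        kwargs = dict(
            n_estimators=params.n_estimators,
            learning_rate=params.learning_rate,
            max_depth=params.max_depth,
            tree_method=params.tree_method,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        if monitor_val:
            booster = XGBRegressor(
                **kwargs, early_stopping_rounds=params.early_stopping_rounds
            )
            booster.fit(X, Y[:, j], eval_set=[(X_val, np.asarray(Y_val)[:, j])], verbose=False)
            histories.append(booster.evals_result())
        else:
            booster = XGBRegressor(**kwargs)
            booster.fit(X, Y[:, j])
            histories.append(None)
        boosters.append(booster)
    return FittedModel(
        family="gbt",
        predictor=_GBTPair(boosters),
        feature_names=list(feature_names) if feature_names is not None else None,
        metadata={"params": params, "seed": seed, "history": histories},
    )


_FITTERS = {"linear": fit_linear, "mlp": fit_mlp, "gbt": fit_gbt}


def fit_family(family, X, Y, params=None, seed=42, X_val=None, Y_val=None, feature_names=None):
    if family == "linear":
        return fit_linear(X, Y, feature_names=feature_names)
    if family == "mlp":
        return fit_mlp(X, Y, params, seed, X_val, Y_val, feature_names)
    if family == "gbt":
        return fit_gbt(X, Y, params, seed, X_val, Y_val, feature_names)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class TuneResult:
    best_params: object
    best_model: FittedModel
    best_score: float
    trials: list


def tune(space: HyperparamSpace, X, Y, X_val, Y_val, feature_names=None) -> TuneResult:
    """Seeded random search; selection by validation R² averaged over outputs."""
    rng = np.random.default_rng(space.seed)
    best = None
    trials = []
    for trial in range(space.budget):
        params = space.sample(rng)
        model = fit_family(
            space.family, X, Y, params, seed=space.seed + trial,
            X_val=X_val, Y_val=Y_val, feature_names=feature_names,
        )
        score = float(np.mean(r_squared(Y_val, model.predict(X_val))))
        trials.append({"trial": trial, "params": params, "val_r2": score})
        if best is None or score > best[0]:
            best = (score, params, model)
    return TuneResult(best_params=best[1], best_model=best[2], best_score=best[0], trials=trials)


def ablate_features(table: GeneFeatureTable, drop) -> GeneFeatureTable:
    """Drop named features; a bare assay name drops both of its contexts."""
    feats = table.feature_ids
    to_drop = set()
    for item in drop:
        if isinstance(item, str):
            hits = [f for f in feats if f[0] == item]
            if not hits:
                raise KeyError(f"unknown assay {item!r}")
            to_drop.update(hits)
        else:
            item = tuple(item)
            if item not in feats:
                raise KeyError(f"unknown feature id {item!r}")
            to_drop.add(item)
    keep = [f for f in feats if f not in to_drop]
    if not keep:
        raise ValueError("ablation would remove every feature")
    return GeneFeatureTable(table.data[keep], table.transform)


# ---------------------------------------------------------------------------
# statsmodels-style presentation
# ---------------------------------------------------------------------------


class PolIIModel:
    """Two-output Pol-II occupancy regression on standardized features.

    Parameters
    ----------
    polII : PolIITargets (standardized), the response.
    features : GeneFeatureTable (standardized), the design.
    split : SplitSpec, which genes are train/validation/test.
    scaler : the fitted transform (kept for provenance and baselines).
    """

    def __init__(self, polII: PolIITargets, features: GeneFeatureTable,
                 split: SplitSpec, scaler=None):
        if features.transform != "standardized" or polII.transform != "standardized":
            raise ValueError("PolIIModel expects standardized inputs; see from_cohort")
        if features.gene_ids != polII.gene_ids:
            raise ValueError("feature and Pol-II tables disagree on gene ids")
        missing = set(split.all_ids) - set(features.gene_ids)
        if missing:
            raise ValueError(f"split references {len(missing)} unknown gene(s)")
        self.features = features
        self.polII = polII
        self.split = split
        self.scaler = scaler

    @classmethod
    def from_cohort(cls, cohort, split: SplitSpec, pseudocount: float = 1e-3):
        """Build from a raw-scale cohort, fitting the transform on train genes."""
        X, Y, scaler = fit_transform(
            cohort.features, cohort.polII, split.train_ids, pseudocount
        )
        return cls(Y, X, split, scaler=scaler)

    def partition(self, name: str):
        ids = {"train": self.split.train_ids, "val": self.split.val_ids,
               "test": self.split.test_ids}[name]
        return (
            self.features.data.loc[ids].to_numpy(),
            self.polII.data.loc[ids].to_numpy(),
            ids,
        )

    def fit(self, family: str = "mlp", params=None, space: HyperparamSpace | None = None,
            seed: int = 42) -> "PolIIResults":
        X_tr, Y_tr, _ = self.partition("train")
        X_va, Y_va, _ = self.partition("val")
        names = self.features.feature_ids
        if space is not None:
            result = tune(space, X_tr, Y_tr, X_va, Y_va, feature_names=names)
            fitted, tuning = result.best_model, result
        else:
            fitted = fit_family(
                family, X_tr, Y_tr, params, seed=seed,
                X_val=X_va, Y_val=Y_va, feature_names=names,
            )
            tuning = None
        return PolIIResults(self, fitted, tuning=tuning)


class PolIIResults:
    """Results of a fitted Pol-II occupancy regression.

    Carries per-partition R² for both outputs, the coefficient table with
    95% intervals for the linear family, and Shapley attribution of test
    genes via :meth:`shap_values`.
    """

    def __init__(self, model: PolIIModel, fitted: FittedModel, tuning: TuneResult | None = None):
        self.model = model
        self.fitted = fitted
        self.tuning = tuning

    @property
    def family(self) -> str:
        return self.fitted.family

    def predict(self, X=None, partition: str | None = None) -> np.ndarray:
        if X is None:
            X, _, _ = self.model.partition(partition or "test")
        return self.fitted.predict(np.asarray(X, dtype=float))

    def rsquared(self, partition: str = "test") -> pd.Series:
        X, Y, _ = self.model.partition(partition)
        return pd.Series(r_squared(Y, self.fitted.predict(X)), index=list(OUTPUT_NAMES))

    def rsquared_table(self) -> pd.DataFrame:
        rows = []
        for part in ("train", "val", "test"):
            r2 = self.rsquared(part)
            for out in OUTPUT_NAMES:
                rows.append({
                    "split": self.model.split.split_index, "family": self.family,
                    "partition": part, "output": out, "r2": float(r2[out]),
                })
        return pd.DataFrame(rows)

    @property
    def params(self) -> pd.DataFrame:
        if self.family != "linear":
            raise AttributeError("coefficients are only defined for the linear family")
        idx = pd.MultiIndex.from_tuples(self.fitted.feature_names, names=["assay", "context"])
        return pd.DataFrame(self.fitted.coef.T, index=idx, columns=list(OUTPUT_NAMES))

    def conf_int(self) -> pd.DataFrame:
        if self.family != "linear":
            raise AttributeError("intervals are only defined for the linear family")
        idx = pd.MultiIndex.from_tuples(self.fitted.feature_names, names=["assay", "context"])
        frames = {}
        for k, out in enumerate(OUTPUT_NAMES):
            frames[(out, "lower")] = self.fitted.conf_int[k, :, 0]
            frames[(out, "upper")] = self.fitted.conf_int[k, :, 1]
        return pd.DataFrame(frames, index=idx)

    def shap_values(self, method: str = "exact", background=None, k: int = 25,
                    exclude_ids=(), seed: int = 0, n_samples: int = 2048):
        """Attribute test-partition predictions to features; see attribution module."""
        from .attribution import attribute_cohort, build_background

        if background is None:
            background = build_background(
                self.model.features, self.model.split.train_ids,
                excluded_ids=exclude_ids, k=k, seed=seed,
            )
        test_feats = self.model.features.loc(self.model.split.test_ids)
        return attribute_cohort(
            self.fitted, test_feats, background, method=method,
            train_ids=self.model.split.train_ids, seed=seed, n_samples=n_samples,
        )

    def summary(self) -> str:
        lines = [
            "Pol-II occupancy regression results",
            "===================================",
            f"family: {self.family}    split: {self.model.split.split_index}    "
            f"n_features: {len(self.model.features.feature_ids)}",
            f"n train/val/test: {len(self.model.split.train_ids)}/"
            f"{len(self.model.split.val_ids)}/{len(self.model.split.test_ids)}",
            "",
            "R^2 (rows: partition; columns: output)",
        ]
        r2 = pd.DataFrame({p: self.rsquared(p) for p in ("train", "val", "test")}).T
        lines.append(r2.round(4).to_string())
        if self.family == "linear":
            lines += ["", "coefficients with 95% CI (promoter output)"]
            tab = self.params.copy()
            ci = self.conf_int()
            for out in OUTPUT_NAMES:
                tab[f"{out}_lo"] = ci[(out, "lower")]
                tab[f"{out}_hi"] = ci[(out, "upper")]
            lines.append(tab.round(4).to_string())
        if self.tuning is not None:
            lines += ["", f"hyperparameter search: {len(self.tuning.trials)} trials, "
                          f"best val R^2 = {self.tuning.best_score:.4f}"]
        return "\n".join(lines)
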