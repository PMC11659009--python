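"""Correlation screening, regression models, and the evaluation grid.

The feature table joins the vegetation-index, texture and structural
tables on (plot_id, stage) together with the observed AGB and the plot
metadata (replicate, n_level, variety).  Features are screened by Pearson
correlation with AGB (|r| > 0.6 by default, computed on calibration rows
only to avoid selection leakage), then three regressors are compared:

* DNN — the numpy multilayer perceptron of :mod:`canopyagb.mlp`,
* RF  — random forest, 80 trees, at most 4 features tried per split,
* SVR — RBF-kernel support vector regression (C=10, epsilon=0.1).

Features are z-score standardized for DNN and SVR using calibration
statistics only; the target is standardized the same way for those two
models (and de-standardized at prediction) so that the epsilon tube and
the network's loss scale are meaningful for AGB in kg/ha.

Evaluation follows the replicate-based design: blocks 1 and 2 calibrate,
block 3 validates; a plot-level ten-fold cross-validation is reported
alongside.  Accuracy is scored by R^2 = 1 - SSE/SST,
RMSE = sqrt(SSE / n) and rRMSE = RMSE / mean(y).
"""

from __future__ import annotations

import itertools
import logging

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR as SkSVR

from canopyagb.mlp import MLPRegressor
from canopyagb.spectral import VI_NAMES

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_SETS",
    "ModelConfig",
    "FittedModel",
    "build_feature_table",
    "metrics",
    "screen_features",
    "split_by_replicate",
    "fit",
    "predict",
    "cross_validate",
    "evaluate_grid",
    "rf_importance",
    "EvaluationReport",
]

TF_NAMES = ("RDR", "RVAR", "RENT", "GDR", "GVAR", "GENT", "BDR", "BVAR", "BENT")
SF_NAMES = ("PH", "PR", "PC", "PVM", "CEFR")

_FAMILIES = {"VI": tuple(VI_NAMES), "TF": TF_NAMES, "SF": SF_NAMES}

# the 7 feature-set combinations compared in the evaluation grid
FEATURE_SETS: dict[str, tuple[str, ...]] = {}
for _k in (1, 2, 3):
    for _combo in itertools.combinations(("VI", "TF", "SF"), _k):
        FEATURE_SETS["+".join(_combo)] = tuple(
            n for fam in _combo for n in _FAMILIES[fam])

ALGORITHMS = ("DNN", "RF", "SVR")
META_COLUMNS = ("plot_id", "stage", "replicate", "n_level", "variety")


@dataclass
class ModelConfig:
    """Algorithm choice plus its (configurable) hyperparameters."""

    algorithm: str = "RF"
    seed: int = 0
    dnn_hidden: tuple[int, ...] = (256, 128, 64, 32)
    dnn_dropout: float = 0.2
    dnn_epochs: int = 600
    dnn_batch: int = 256
    dnn_lr: float = 1e-3
    dnn_lr_decay: float = 0.9
    dnn_lr_decay_every: int = 100
    rf_n_trees: int = 80
    rf_m_try: int = 4
    svr_c: float = 10.0
    svr_epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")


def build_feature_table(obs: pd.DataFrame, plots, *feature_tables: pd.DataFrame,
                        ) -> pd.DataFrame:
    """Join feature tables with observations and plot metadata on (plot_id, stage)."""
    meta = pd.DataFrame(
        [{"plot_id": p.plot_id, "replicate": p.replicate,
          "n_level": p.n_level, "variety": p.variety} for p in plots]
    ).drop_duplicates("plot_id")
    out = obs.merge(meta, on="plot_id", how="left")
    for ft in feature_tables:
        out = out.merge(ft, on=["plot_id", "stage"], how="left")
    if out.duplicated(subset=["plot_id", "stage"]).any():
        raise ValueError("duplicate (plot_id, stage) keys in feature table")
    return out


def metrics(y: np.ndarray, y_hat: np.ndarray) -> dict:
    """R^2, RMSE and rRMSE of predictions against observations."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sse = float(((y - y_hat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    rmse = float(np.sqrt(sse / y.size))
    ybar = float(y.mean())
    return {
        "R2": 1.0 - sse / sst if sst > 0 else np.nan,
        "RMSE": rmse,
        "rRMSE": rmse / ybar if ybar != 0 else np.nan,
    }


def screen_features(table: pd.DataFrame, features=None, threshold: float = 0.6,
                    target: str = "agb_kg_ha") -> dict[str, float]:
    """Features whose absolute Pearson r with AGB exceeds the threshold.

    Correlations use pairwise-complete rows; zero-variance features have no
    defined r and are excluded with a warning.  Screening is sign-blind:
    a strong negative correlate is as informative as a positive one.
    """
    if len(table) < 3:
        raise ValueError("screening requires at least 3 rows")
    if features is None:
        features = [c for c in table.columns
                    if c not in META_COLUMNS and c != target
                    and pd.api.types.is_numeric_dtype(table[c])]
    y = table[target].astype(float)
    out: dict[str, float] = {}
    for name in features:
        sub = pd.concat([table[name].astype(float), y], axis=1).dropna()
        if len(sub) < 3:
            continue
        x = sub.iloc[:, 0].to_numpy()
        if np.std(x) == 0 or np.std(sub.iloc[:, 1].to_numpy()) == 0:
            log.warning("screen_features: %s has zero variance, excluded", name)
            continue
        r = float(np.corrcoef(x, sub.iloc[:, 1].to_numpy())[0, 1])
        if abs(r) > threshold:
            out[name] = r
    return out


def split_by_replicate(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate blocks 1-2 -> calibration, block 3 -> validation."""
    if "replicate" not in table.columns or table["replicate"].isna().any():
        raise ValueError("replicate metadata missing")
    cal = table[table["replicate"].isin([1, 2])]
    val = table[table["replicate"] == 3]
    if cal.empty or val.empty:
        raise ValueError("replicate split produced an empty partition")
    return cal, val


@dataclass
class FittedModel:
    config: ModelConfig
    feature_names: tuple[str, ...]
    estimator: object
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    standardized: bool = False

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if self.standardized:
            X = (X - self.x_mean) / self.x_sd
        y = np.asarray(self.estimator.predict(X), dtype=float).ravel()
        if self.standardized:
            y = y * self.y_sd + self.y_mean
        return y


def _design(table: pd.DataFrame, features) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Drop rows with missing screened features; return (kept rows, X, y)."""
    kept = table.dropna(subset=list(features) + ["agb_kg_ha"])
    n_drop = len(table) - len(kept)
    if n_drop:
        log.info("dropping %d rows with missing feature values", n_drop)
    X = kept[list(features)].to_numpy(dtype=float)
    y = kept["agb_kg_ha"].to_numpy(dtype=float)
    return kept, X, y


def fit(config: ModelConfig, X: np.ndarray | pd.DataFrame, y: np.ndarray,
        feature_names=None) -> FittedModel:
    """Fit one regressor; deterministic for a fixed ``config.seed``."""
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if X.shape[0] < 5:
        raise ValueError("need at least 5 training rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values must be dropped before fitting")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1]))
    cfg = config
    if cfg.algorithm == "RF":
        m_try = min(cfg.rf_m_try, X.shape[1])
        if m_try < cfg.rf_m_try:
            log.warning("m_try clipped to %d (only %d features)", m_try, X.shape[1])
        est = RandomForestRegressor(n_estimators=cfg.rf_n_trees,
                                    max_features=m_try,
                                    random_state=cfg.seed).fit(X, y)
        return FittedModel(cfg, names, est)
    # DNN and SVR train on standardized features and target
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean, y_sd = float(y.mean()), float(y.std())
    y_sd = y_sd if y_sd > 0 else 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    if cfg.algorithm == "SVR":
        est = SkSVR(kernel="rbf", C=cfg.svr_c, epsilon=cfg.svr_epsilon).fit(Xs, ys)
    else:
        est = MLPRegressor(hidden=cfg.dnn_hidden, dropout=cfg.dnn_dropout,
                           epochs=cfg.dnn_epochs, batch_size=cfg.dnn_batch,
                           lr=cfg.dnn_lr, lr_decay=cfg.dnn_lr_decay,
                           lr_decay_every=cfg.dnn_lr_decay_every,
                           seed=cfg.seed).fit(Xs, ys)
    return FittedModel(cfg, names, est, x_mean=x_mean, x_sd=x_sd,
                       y_mean=y_mean, y_sd=y_sd, standardized=True)


def predict(model: FittedModel, X) -> np.ndarray:
    return model.predict(X)


def cross_validate(config: ModelConfig, table: pd.DataFrame, features,
                   k: int = 10, seed: int | None = None) -> dict:
    """Plot-level k-fold cross-validation (all stages of a plot share a fold).

    Returns pooled out-of-fold metrics plus the per-fold metric list.
    """
    kept, _, _ = _design(table, features)
    plot_ids = np.asarray(sorted(kept["plot_id"].unique()))
    if len(plot_ids) < k:
        raise ValueError(f"{len(plot_ids)} plots < {k} folds")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    folds = np.array_split(rng.permutation(plot_ids), k)
    oof = pd.Series(index=kept.index, dtype=float)
    per_fold = []
    for i, fold_plots in enumerate(folds):
        test = kept["plot_id"].isin(fold_plots)
        train = kept[~test]
        model = fit(replace(config, seed=config.seed + i), train[list(features)],
                    train["agb_kg_ha"].to_numpy())
        pred = model.predict(kept.loc[test, list(features)])
        oof.loc[kept.index[test]] = pred
        if test.sum() >= 2:
            per_fold.append(metrics(kept.loc[test, "agb_kg_ha"], pred))
    pooled = metrics(kept["agb_kg_ha"], oof)
    return {"pooled": pooled, "per_fold": per_fold, "predictions": oof,
            "n": int(len(kept)), "fold_sizes": [len(f) for f in folds]}


@dataclass
class EvaluationReport:
    """Calibration/validation/CV accuracy per feature set x algorithm x stage."""

    table: pd.DataFrame
    predictions: pd.DataFrame
    selected: dict = field(default_factory=dict)

    def cell(self, feature_set: str, algorithm: str, stage: str = "pooled") -> pd.Series:
        t = self.table
        sel = t[(t.feature_set == feature_set) & (t.algorithm == algorithm)
                & (t.stage == stage)]
        if sel.empty:
            raise KeyError((feature_set, algorithm, stage))
        return sel.iloc[0]


def evaluate_grid(table: pd.DataFrame,
                  feature_sets: dict[str, tuple[str, ...]] | None = None,
                  algorithms=ALGORITHMS, stages=("pooled",),
                  threshold: float = 0.6, seed: int = 0,
                  cv_folds: int | None = 10) -> EvaluationReport:
    """Fit and score every feature-set x algorithm cell, per stage.

    ``stages`` may contain "pooled" (all rows, one model) and/or individual
    stage labels.  Screening (|r| > threshold against AGB) runs on the
    calibration rows of the evaluated subset only; if no feature in a set
    survives, the single highest-|r| feature is kept so every cell remains
    defined (logged).
    """
    feature_sets = FEATURE_SETS if feature_sets is None else feature_sets
    rows, preds, selected = [], [], {}
    for stage in stages:
        sub = table if stage == "pooled" else table[table["stage"] == stage]
        if sub.empty:
            raise ValueError(f"no rows for stage {stage!r}")
        cal, val = split_by_replicate(sub)
        for set_name, family in feature_sets.items():
            feats = [f for f in family if f in sub.columns]
            if not feats:
                raise ValueError(f"feature set {set_name!r} has no columns")
            sel = screen_features(cal, feats, threshold=threshold)
            if not sel:
                all_r = screen_features(cal, feats, threshold=0.0)
                if not all_r:
                    raise ValueError(f"feature set {set_name!r}: no finite correlations")
                best = max(all_r, key=lambda n: abs(all_r[n]))
                log.info("set %s/%s: nothing passes |r|>%.2f, keeping %s",
                         set_name, stage, threshold, best)
                sel = {best: all_r[best]}
            names = [f for f in feats if f in sel]
            selected[(stage, set_name)] = {n: sel[n] for n in names}
            cal_k, Xc, yc = _design(cal, names)
            val_k, Xv, yv = _design(val, names)
            for algo in algorithms:
                cfg = ModelConfig(algorithm=algo, seed=seed)
                model = fit(cfg, cal_k[names], yc)
                yc_hat = model.predict(Xc if not model.standardized else cal_k[names])
                yv_hat = model.predict(val_k[names])
                row = {"stage": stage, "feature_set": set_name, "algorithm": algo,
                       "n_features": len(names),
                       "n_cal": len(cal_k), "n_val": len(val_k)}
                row.update({f"cal_{k_}": v for k_, v in metrics(yc, yc_hat).items()})
                row.update({f"val_{k_}": v for k_, v in metrics(yv, yv_hat).items()})
                if cv_folds:
                    cv = cross_validate(cfg, sub, names, k=cv_folds, seed=seed)
                    row.update({f"cv_{k_}": v for k_, v in cv["pooled"].items()})
                rows.append(row)
                for part, frame, yhat in (("calibration", cal_k, yc_hat),
                                          ("validation", val_k, yv_hat)):
                    p = frame[["plot_id", "stage", "agb_kg_ha"]].copy()
                    p["predicted"] = yhat
                    p["partition"] = part
                    p["feature_set"] = set_name
                    p["algorithm"] = algo
                    p["eval_stage"] = stage
                    preds.append(p)
    return EvaluationReport(table=pd.DataFrame(rows),
                            predictions=pd.concat(preds, ignore_index=True),
                            selected=selected)


def rf_importance(model: FittedModel, feature_names=None) -> pd.DataFrame:
    """Impurity-reduction variable importances, normalized to sum 1."""
    est = model.estimator if isinstance(model, FittedModel) else model
    if not isinstance(est, RandomForestRegressor):
        raise TypeError("rf_importance requires a fitted random forest")
    names = feature_names or (model.feature_names if isinstance(model, FittedModel)
                              else None)
    imp = np.asarray(est.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.DataFrame({"feature": list(names) if names is not None
                         else [f"x{i}" for i in range(imp.size)],
                         "importance": imp}).sort_values(
        "importance", ascending=False, ignore_index=True)
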