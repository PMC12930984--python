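"""Nested stratified group k-fold cross-validation for defacing QA.

The outer loop estimates generalization; the inner loop, run only on outer
training folds, tunes hyperparameters. Every scan of one subject stays in a
single fold (group constraint), and subjects are distributed so per-fold
class proportions track the global proportions as closely as the group
constraint permits.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

__all__ = [
    "CVConfig",
    "FoldResult",
    "CVReport",
    "make_group_stratified_folds",
    "classification_metrics",
    "nested_cv",
    "permutation_importance",
    "build_model",
    "DEFAULT_GRIDS",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "auroc")

#: small per-model hyperparameter grids; tuning exists to exercise the
#: nested protocol, so the grids stay deliberately compact
DEFAULT_GRIDS = {
    "LR": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}],
    "MLP": [{"hidden": 8}, {"hidden": 32}],
    "RF": [{"max_depth": None}, {"max_depth": 4}],
    "XGB": [{"max_depth": 2}, {"max_depth": 4}],
}


@dataclasses.dataclass
class CVConfig:
    outer_folds: int = 5
    inner_folds: int = 3
    models: tuple = ("LR", "MLP", "RF", "XGB")
    grids: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GRIDS)
    )
    permutation_repeats: int = 10
    seed: int = 0
    threshold: float = 0.5
    rf_trees: int = 200
    xgb_trees: int = 100
    correlation_threshold: float = 0.8  # |rho| above which features cluster
    importance_floor: float = 0.005     # minimum mean AUROC drop to keep
    max_selection_iterations: int = 10

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        for m in self.models:
            if m not in self.grids or not self.grids[m]:
                raise ValueError(f"empty hyperparameter grid for {m}")


def build_model(name: str, params: dict, seed: int, cfg: CVConfig):
    """Instantiate one classifier; LR and MLP get feature standardization."""
    if name == "LR":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(C=params["C"], max_iter=2000)),
            ]
        )
    if name == "MLP":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=(params["hidden"],),
                        max_iter=1000,
                        random_state=seed,
                    ),
                ),
            ]
        )
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=cfg.rf_trees,
            max_depth=params["max_depth"],
            random_state=seed,
            n_jobs=1,
        )
    if name == "XGB":
        return XGBClassifier(
            n_estimators=cfg.xgb_trees,
            max_depth=params["max_depth"],
            learning_rate=0.1,
            eval_metric="logloss",
            verbosity=0,
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown model {name!r}")


def make_group_stratified_folds(
    y, groups, k: int, seed: int = 0
) -> np.ndarray:
    """Greedy group-aware stratified fold assignment.

    Subjects (groups) are assigned whole, largest first, each to the fold
    whose class balance deviates least from the global balance after the
    assignment (fold size as tie-break), so no subject ever spans folds.

    Returns an integer fold index per sample.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    if y.shape != groups.shape:
        raise ValueError("y and groups must have equal length")
    uniq = pd.unique(groups)
    if k > len(uniq):
        raise ValueError(
            f"cannot make {k} folds from {len(uniq)} subjects"
        )
    rng = np.random.default_rng(seed)

    classes, y_idx = np.unique(y, return_inverse=True)
    n_classes = len(classes)
    class_totals = np.bincount(y_idx, minlength=n_classes).astype(float)

    sizes, counts = {}, {}
    for g in uniq:
        sel = groups == g
        sizes[g] = int(sel.sum())
        counts[g] = np.bincount(y_idx[sel], minlength=n_classes)

    order = list(uniq)
    rng.shuffle(order)  # random tie order among equal-sized subjects
    order.sort(key=lambda g: -sizes[g])

    fold_counts = np.zeros((k, n_classes))
    fold_n = np.zeros(k)
    assignment = {}
    for g in order:
        best, best_key = None, None
        for f in range(k):
            fold_counts[f] += counts[g]
            # dispersion of per-fold class shares after the assignment
            dev = float(
                np.mean(np.std(fold_counts / class_totals, axis=0))
            )
            fold_counts[f] -= counts[g]
            key = (dev, fold_n[f] + sizes[g], f)
            if best_key is None or key < best_key:
                best, best_key = f, key
        assignment[g] = best
        fold_counts[best] += counts[g]
        fold_n[best] += sizes[g]

    return np.array([assignment[g] for g in groups], dtype=int)


def classification_metrics(
    y_true, scores, threshold: float = 0.5
) -> dict:
    """Accuracy, sensitivity, specificity, precision and AUROC.

    The positive class is 1 = insufficiently defaced (the privacy failure).
    AUROC uses the rank statistic with tie correction; with single-class
    truth it is undefined and reported as NaN.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("truth and scores must have equal length")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = len(y)
    out = {
        "accuracy": (tp + tn) / n if n else np.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
        "precision": tp / (tp + fp) if (tp + fp) else np.nan,
    }
    if len(np.unique(y)) < 2:
        out["auroc"] = np.nan
    else:
        out["auroc"] = float(roc_auc_score(y, s))
    return out


def permutation_importance(
    model, X, y, repeats: int = 10, seed: int = 0
) -> pd.Series:
    """Mean AUROC drop per feature when its column is permuted.

    ``model`` must already be fitted; ``X`` is the (outer test) feature
    frame and ``y`` the matching labels.
    """
    if not hasattr(model, "predict_proba"):
        raise ValueError("model must be a fitted probabilistic classifier")
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    try:
        base = roc_auc_score(y, model.predict_proba(X)[:, 1])
    except Exception as exc:  # unfitted models raise here
        raise ValueError(f"model is not usable for scoring: {exc}") from exc

    drops = {}
    for col in X.columns:
        vals = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            vals.append(base - roc_auc_score(y, model.predict_proba(Xp)[:, 1]))
        drops[col] = float(np.mean(vals))
    return pd.Series(drops, name="importance")


@dataclasses.dataclass
class FoldResult:
    fold: int
    model: str
    params: dict
    metrics: dict
    n_test: int
    test_index: np.ndarray
    importance: pd.Series


@dataclasses.dataclass
class CVReport:
    """Per-outer-fold and aggregated nested-CV results for one model set."""

    folds: list                      # list[FoldResult]
    feature_names: list
    config: CVConfig
    seed: int

    def fold_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            row = {"model": fr.model, "fold": fr.fold, "n_test": fr.n_test}
            row.update(fr.metrics)
            rows.append(row)
        return pd.DataFrame(rows)

    def mean_metrics(self) -> pd.DataFrame:
        """Mean over outer folds (NaN folds excluded per metric)."""
        t = self.fold_table()
        return t.groupby("model")[list(METRIC_NAMES)].mean()

    def sd_metrics(self) -> pd.DataFrame:
        t = self.fold_table()
        return t.groupby("model")[list(METRIC_NAMES)].std(ddof=1)

    def mean_importances(self) -> pd.DataFrame:
        """Permutation importances averaged across outer folds, per model."""
        per_model = {}
        for model in {fr.model for fr in self.folds}:
            cols = [fr.importance for fr in self.folds if fr.model == model]
            per_model[model] = pd.concat(cols, axis=1).mean(axis=1)
        return pd.DataFrame(per_model)


def _inner_select(name, X, y, groups, cfg, seed):
    """Grid search by mean AUROC over inner group-stratified folds."""
    folds = make_group_stratified_folds(y, groups, cfg.inner_folds, seed)
    best_params, best_score = None, -np.inf
    for params in cfg.grids[name]:
        scores = []
        for f in range(cfg.inner_folds):
            tr, te = folds != f, folds == f
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            model = build_model(name, params, seed, cfg)
            model.fit(X[tr], y[tr])
            scores.append(
                roc_auc_score(y[te], model.predict_proba(X[te])[:, 1])
            )
        score = np.mean(scores) if scores else -np.inf
        if score > best_score:
            best_params, best_score = params, score
    return best_params if best_params is not None else cfg.grids[name][0]


def nested_cv(
    table: pd.DataFrame,
    cfg: CVConfig | None = None,
    feature_names: list | None = None,
) -> CVReport:
    """Run the nested stratified group k-fold protocol on a modeling table.

    ``table`` must carry ``label``, ``subject_id`` and numeric feature
    columns. Each sample lands in exactly one outer test fold; inner tuning
    sees only the outer training subset. Outer folds whose test labels are
    single-class get NaN AUROC (excluded from means) with a warning.
    """
    from .features import feature_columns

    cfg = cfg or CVConfig()
    if feature_names is None:
        feature_names = feature_columns(table)
    if not feature_names:
        raise ValueError("no feature columns to model")
    X = table[feature_names].reset_index(drop=True)
    y = table["label"].to_numpy().astype(int)
    groups = table["subject_id"].to_numpy()
    if min(
        pd.Series(groups[y == c]).nunique() for c in np.unique(y)
    ) < 2 or len(np.unique(y)) < 2:
        raise ValueError("need at least 2 subjects per class")

    outer = make_group_stratified_folds(
        y, groups, cfg.outer_folds, cfg.seed
    )
    results = []
    for name in cfg.models:
        for f in range(cfg.outer_folds):
            tr = outer != f
            te = outer == f
            fold_seed = (cfg.seed + 7919 * f + sum(name.encode())) % (2**31)
            Xtr = X[tr].to_numpy()
            params = _inner_select(
                name, Xtr, y[tr], groups[tr], cfg, fold_seed
            )
            model = build_model(name, params, fold_seed, cfg)
            model.fit(Xtr, y[tr])
            scores = model.predict_proba(X[te].to_numpy())[:, 1]
            metrics = classification_metrics(y[te], scores, cfg.threshold)
            if np.isnan(metrics["auroc"]):
                warnings.warn(
                    f"outer fold {f} is single-class; AUROC recorded as "
                    "missing and excluded from the mean"
                )
            if np.isnan(metrics["auroc"]):
                imp = pd.Series(
                    np.nan, index=feature_names, name="importance"
                )
            else:
                imp = permutation_importance(
                    _RenamedFrameModel(model, feature_names),
                    X[te],
                    y[te],
                    repeats=cfg.permutation_repeats,
                    seed=fold_seed,
                )
            results.append(
                FoldResult(
                    fold=f,
                    model=name,
                    params=params,
                    metrics=metrics,
                    n_test=int(te.sum()),
                    test_index=np.nonzero(te)[0],
                    importance=imp,
                )
            )
    return CVReport(
        folds=results, feature_names=list(feature_names),
        config=cfg, seed=cfg.seed,
    )


class _RenamedFrameModel:
    """Adapter: score a numpy-fitted model from a DataFrame, column-safe."""

    def __init__(self, model, feature_names):
        self._model = model
        self._names = list(feature_names)

    def predict_proba(self, X):
        X = pd.DataFrame(X)[self._names]
        return self._model.predict_proba(X.to_numpy())
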