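"""Modeling surface: a `DefacingQA` model object whose `fit()` returns a
`DefacingQAResults` carrying per-fold metrics, permutation importances and a
`summary()` table, plus a deployable prediction bundle.

Typical use::

    qa = DefacingQA.from_feature_table(features, criterion="lenient")
    res = qa.fit()
    print(res.summary())           # mean (sd) metrics per classifier
    bundle = res.final_bundle()    # best model refit on all data
    labels, scores = bundle.predict(new_rows)
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cv import CVConfig, CVReport, METRIC_NAMES, build_model, nested_cv
from .features import feature_columns, modeling_table
from .selection import SelectionResult, iterative_feature_selection

__all__ = ["DefacingQA", "DefacingQAResults", "ModelBundle"]


class DefacingQA:
    """Defacing-success classification model on a per-pair feature table.

    Parameters
    ----------
    table : DataFrame
        Modeling table with ``label`` (1 = insufficiently defaced),
        ``subject_id`` and numeric feature columns (see
        :func:`defaceqc.features.modeling_table`).
    config : CVConfig
        Nested-CV protocol, model set and hyperparameter grids.
    """

    def __init__(self, table: pd.DataFrame, config: CVConfig | None = None,
                 feature_names: list | None = None):
        for col in ("label", "subject_id"):
            if col not in table.columns:
                raise ValueError(f"modeling table lacks {col!r}")
        self.table = table.reset_index(drop=True)
        self.config = config or CVConfig()
        self.feature_names = list(
            feature_names or feature_columns(self.table)
        )
        if not self.feature_names:
            raise ValueError("no numeric feature columns found")

    @classmethod
    def from_feature_table(
        cls,
        features: pd.DataFrame,
        criterion: str = "lenient",
        include_methods: bool = True,
        config: CVConfig | None = None,
    ) -> "DefacingQA":
        """Build from a raw extracted feature table (labels per criterion)."""
        return cls(
            modeling_table(features, criterion, include_methods), config
        )

    @classmethod
    def from_csv(cls, path, criterion: str = "lenient",
                 include_methods: bool = True,
                 config: CVConfig | None = None) -> "DefacingQA":
        return cls.from_feature_table(
            pd.read_csv(path), criterion, include_methods, config
        )

    def fit(self) -> "DefacingQAResults":
        """Run the nested stratified group k-fold evaluation."""
        report = nested_cv(self.table, self.config, self.feature_names)
        return DefacingQAResults(self, report)

    def select_features(self, model: str = "RF") -> SelectionResult:
        """Iterative correlation/importance-driven feature selection."""
        return iterative_feature_selection(
            self.table, self.config, self.feature_names, model=model
        )


@dataclasses.dataclass
class ModelBundle:
    """A trained classifier with its feature schema and config snapshot."""

    model: object
    feature_names: list
    model_name: str
    params: dict
    threshold: float = 0.5
    config: CVConfig | None = None

    def predict(self, features) -> tuple:
        """(labels, scores) for a feature frame or a single row dict."""
        if isinstance(features, dict):
            features = pd.DataFrame([features])
        features = pd.DataFrame(features)
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        scores = self.model.predict_proba(X)[:, 1]
        labels = (scores >= self.threshold).astype(int)
        return labels, scores

    def save(self, path) -> None:
        import joblib

        joblib.dump(
            {
                "model": self.model,
                "feature_names": self.feature_names,
                "model_name": self.model_name,
                "params": self.params,
                "threshold": self.threshold,
                "config": self.config,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ModelBundle":
        import joblib

        return cls(**joblib.load(path))


class DefacingQAResults:
    """Nested-CV results: per-fold metrics, importances, summary table."""

    def __init__(self, model: DefacingQA, report: CVReport):
        self.model = model
        self.report = report

    @property
    def fold_metrics(self) -> pd.DataFrame:
        return self.report.fold_table()

    @property
    def mean_metrics(self) -> pd.DataFrame:
        return self.report.mean_metrics()

    @property
    def importances(self) -> pd.DataFrame:
        return self.report.mean_importances()

    def summary(self) -> pd.DataFrame:
        """Classifier x metric table formatted as ``mean (sd)``."""
        mean = self.report.mean_metrics()
        sd = self.report.sd_metrics()
        out = pd.DataFrame(index=mean.index, columns=list(METRIC_NAMES))
        for m in METRIC_NAMES:
            out[m] = [
                f"{mean.loc[i, m]:.2f} ({sd.loc[i, m]:.2f})"
                for i in mean.index
            ]
        out.index.name = "model"
        return out

    def best_model_name(self, metric: str = "auroc") -> str:
        return str(self.report.mean_metrics()[metric].idxmax())

    def final_bundle(self, model_name: str | None = None) -> ModelBundle:
        """Refit the chosen (default: best-AUROC) model on all data."""
        name = model_name or self.best_model_name()
        cfg = self.model.config
        # most frequently selected inner params across outer folds
        param_list = [
            fr.params for fr in self.report.folds if fr.model == name
        ]
        keys = [tuple(sorted(p.items())) for p in param_list]
        best = dict(max(set(keys), key=keys.count))
        clf = build_model(name, best, cfg.seed, cfg)
        X = self.model.table[self.model.feature_names].to_numpy(dtype=float)
        y = self.model.table["label"].to_numpy().astype(int)
        clf.fit(X, y)
        return ModelBundle(
            model=clf,
            feature_names=list(self.model.feature_names),
            model_name=name,
            params=best,
            threshold=cfg.threshold,
            config=cfg,
        )
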