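"""Correlation-aware iterative feature selection.

Highly inter-correlated features (|Spearman rho| above a threshold, found by
average-linkage hierarchical clustering on distance 1 - |rho|) are pruned to
the member with the highest fold-averaged permutation importance; features
whose importance falls below a floor are dropped too. Models are retrained
on the reduced set and the loop repeats while the mean outer-fold AUROC does
not degrade.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .cv import CVConfig, nested_cv

__all__ = [
    "CorrelationStructure",
    "correlation_structure",
    "iterative_feature_selection",
]


@dataclasses.dataclass
class CorrelationStructure:
    """Spearman rho matrix plus its average-linkage merge tree."""

    rho: pd.DataFrame
    dendrogram: np.ndarray  # scipy linkage matrix on distance 1 - |rho|
    threshold: float = 0.2  # cut distance (= 1 - |rho| cluster threshold)

    def clusters(self, threshold: float | None = None) -> dict:
        """Feature -> cluster id at the given cut distance."""
        t = self.threshold if threshold is None else threshold
        labels = fcluster(self.dendrogram, t=t, criterion="distance")
        return dict(zip(self.rho.columns, labels))


def correlation_structure(
    table: pd.DataFrame,
    feature_names: list | None = None,
    threshold: float = 0.2,
) -> CorrelationStructure:
    """Spearman rank correlations and their hierarchical clustering.

    Ties get average ranks. A constant feature has undefined correlations;
    they are recorded as 0 with a warning so clustering stays defined.
    """
    if feature_names is None:
        feature_names = [
            c for c in table.columns
            if np.issubdtype(table[c].dtype, np.number)
        ]
    X = table[feature_names].to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two features")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(X, axis=0).statistic
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if np.isnan(rho).any():
        warnings.warn(
            "constant feature produced undefined correlations; recorded as 0"
        )
        rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0  # enforce exact symmetry

    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    return CorrelationStructure(
        rho=pd.DataFrame(rho, index=feature_names, columns=feature_names),
        dendrogram=tree,
        threshold=threshold,
    )


@dataclasses.dataclass
class SelectionResult:
    selected: list
    history: list          # one dict per iteration
    final_auroc: float


def _prune(importance: pd.Series, corr: CorrelationStructure,
           floor: float) -> list:
    """Features to drop this iteration: cluster losers + low importance."""
    drop = set()
    clusters = corr.clusters()
    for cid in set(clusters.values()):
        members = [f for f, c in clusters.items() if c == cid]
        if len(members) > 1:
            keep = importance[members].idxmax()
            drop.update(m for m in members if m != keep)
    for f in importance.index:
        if f not in drop and importance[f] < floor:
            drop.add(f)
    # never eliminate everything: the single most important feature stays
    if len(drop) >= len(importance):
        drop.discard(importance.idxmax())
    return sorted(drop)


def iterative_feature_selection(
    table: pd.DataFrame,
    cfg: CVConfig | None = None,
    feature_names: list | None = None,
    model: str = "RF",
) -> SelectionResult:
    """Iteratively remove redundant / uninformative features.

    Each iteration runs the nested CV with ``model`` (a tree ensemble by
    default, which is what the permutation importances are computed from),
    averages permutation importances over outer folds, clusters the
    Spearman correlations, and drops within-cluster losers plus features
    below the importance floor. The loop stops when a drop would lower the
    mean AUROC (the drop is reverted), when nothing is droppable, or at the
    iteration cap. Deterministic given ``cfg.seed``.
    """
    from .features import feature_columns

    cfg = cfg or CVConfig()
    current = list(
        feature_columns(table) if feature_names is None else feature_names
    )
    if not current:
        raise ValueError("no features to select from")
    run_cfg = dataclasses.replace(cfg, models=(model,))

    history = []
    report = nested_cv(table, run_cfg, current)
    auroc = float(report.mean_metrics().loc[model, "auroc"])
    for it in range(cfg.max_selection_iterations):
        importance = report.mean_importances()[model]
        if len(current) < 2:
            break
        corr = correlation_structure(
            table, current, threshold=1.0 - cfg.correlation_threshold
        )
        drop = _prune(importance, corr, cfg.importance_floor)
        if not drop:
            history.append(
                {"iteration": it, "features": list(current),
                 "dropped": [], "auroc": auroc}
            )
            break
        candidate = [f for f in current if f not in drop]
        if not candidate:
            raise ValueError("feature selection eliminated all features")
        cand_report = nested_cv(table, run_cfg, candidate)
        cand_auroc = float(cand_report.mean_metrics().loc[model, "auroc"])
        history.append(
            {"iteration": it, "features": list(current), "dropped": drop,
             "auroc": auroc, "candidate_auroc": cand_auroc}
        )
        if cand_auroc < auroc:  # drop hurt: revert and stop
            break
        current, report, auroc = candidate, cand_report, cand_auroc
    return SelectionResult(
        selected=current, history=history, final_auroc=auroc
    )
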