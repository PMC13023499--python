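"""Emotional-state labels from EDA features: clustering + LOTO-CV SVM.

The selected (highest-MI) EDA features are standardized and grouped into two
clusters by bottom-up agglomerative clustering on squared-Euclidean
dissimilarities (single / complete / average linkage; average by default).
Clustering never sees any FAA column — FAA is used only afterwards to *name*
the clusters: the cluster with the higher mean normalized-ratio FAA becomes
Class 1 (approach / positive affect), the other Class 2 (withdrawal).

An RBF-kernel SVM trained on those cluster labels is evaluated with
leave-one-trial-out cross-validation: for each task, one trial is held out,
the standardizer + cluster labels + SVM are fit on the remaining trials, and
the held-out windows are scored by their *coincidence* with the FAA sign —
the percentage of predicted Class-1 windows whose ratio-FAA is positive, and
of Class-2 windows whose ratio-FAA is non-positive.  Per-fold labeling (the
default) keeps the test fold out of every fitted statistic; a global-labeling
mode (clusters computed once on all trials) exists for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .features import FEATURE_COLUMNS, LABEL_COLUMNS, TARGET_COLUMNS

__all__ = [
    "ClusteringResult",
    "CVReport",
    "standardize",
    "agglomerative_cluster",
    "label_clusters_by_faa",
    "coincidence_rate",
    "loto_cv",
]

_LINKAGES = ("single", "complete", "average")


@dataclass(frozen=True)
class ClusteringResult:
    """Flat two-cluster cut of an agglomerative merge tree."""

    labels: np.ndarray         # cluster index per row (0-based)
    merge_tree: np.ndarray     # rows: (cluster_a, cluster_b, distance, size)
    linkage: str
    n_clusters: int

    def __post_init__(self) -> None:
        if len(np.unique(self.labels)) > self.n_clusters:
            raise ValueError("more clusters than requested after cut")


@dataclass(frozen=True)
class CVReport:
    """Leave-one-trial-out coincidence rates, one row per (task, trial)."""

    per_trial: pd.DataFrame    # task, validation_trial, class1_pct, class2_pct
    task_averages: pd.DataFrame

    @property
    def grand_average(self) -> float:
        """Mean of the per-class coincidence rates over all folds and tasks."""
        vals = self.per_trial[["class1_pct", "class2_pct"]].to_numpy()
        return float(np.nanmean(vals))


def standardize(X, stats_from=None) -> np.ndarray:
    """Column z-scores using the mean/SD of ``stats_from`` (default: X itself).

    In cross-validation ``stats_from`` is the training-fold block, so the test
    fold never influences the statistics.  Constant columns are rejected.
    """
    X = np.asarray(X, dtype=float)
    S = X if stats_from is None else np.asarray(stats_from, dtype=float)
    if S.size == 0:
        raise ValueError("stats_from is empty")
    mean = S.mean(axis=0)
    sd = S.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at indices {bad.tolist()}")
    return (X - mean) / sd


def agglomerative_cluster(X, linkage: str = "average",
                          n_clusters: int = 2) -> ClusteringResult:
    """Bottom-up clustering on pairwise squared-Euclidean dissimilarities.

    Starts from singletons, repeatedly merges the closest pair of clusters
    under the chosen linkage, and cuts the tree at ``n_clusters``.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < n_clusters:
        raise ValueError("need a 2-D matrix with at least n_clusters rows")
    d = pdist(X, metric="sqeuclidean")
    Z = _scipy_linkage(d, method=linkage)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return ClusteringResult(labels=labels, merge_tree=Z, linkage=linkage,
                            n_clusters=n_clusters)


def label_clusters_by_faa(clustering: ClusteringResult, p_faa) -> np.ndarray:
    """Name the two clusters by FAA: higher mean ratio-FAA -> Class 1.

    ``p_faa`` is used for naming only; the clustering itself never consumed
    it.  Returns an array of class labels (1 or 2) per row.  Equal means tie-
    break deterministically to cluster 0 as Class 1.
    """
    p_faa = np.asarray(p_faa, dtype=float).ravel()
    labels = clustering.labels
    if p_faa.size != labels.size:
        raise ValueError("p_faa length must match the clustered rows")
    ids = np.unique(labels)
    if ids.size != 2:
        raise ValueError("exactly two clusters required for class naming")
    means = np.array([p_faa[labels == c].mean() for c in ids])
    if means[0] >= means[1]:
        class1 = ids[0]
    else:
        class1 = ids[1]
    return np.where(labels == class1, 1, 2)


def coincidence_rate(predicted, p_faa) -> tuple[float, float]:
    """Percent agreement of predicted classes with the ratio-FAA sign.

    class1% = share of predicted Class-1 rows with p_faa > 0; class2% = share
    of predicted Class-2 rows with p_faa <= 0 (zero counted as non-positive).
    An empty class reports ``nan`` (missing).
    """
    predicted = np.asarray(predicted).ravel()
    p_faa = np.asarray(p_faa, dtype=float).ravel()
    if predicted.size != p_faa.size:
        raise ValueError("length mismatch")
    out = []
    for cls, agree in ((1, p_faa > 0), (2, p_faa <= 0)):
        sel = predicted == cls
        out.append(float(100.0 * agree[sel].mean()) if np.any(sel)
                   else float("nan"))
    return out[0], out[1]


def _fit_fold(train: pd.DataFrame, features: list[str], linkage: str,
              svm_params: dict, target: str):
    """Standardizer stats + cluster-derived labels + fitted SVM on one fold."""
    Xtr = train[features].to_numpy(dtype=float)
    mean, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    if np.any(sd == 0):
        bad = [features[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant training feature(s): {bad}")
    Ztr = (Xtr - mean) / sd
    clustering = agglomerative_cluster(Ztr, linkage=linkage, n_clusters=2)
    classes = label_clusters_by_faa(clustering, train[target].to_numpy())
    svm = SVC(**svm_params)
    svm.fit(Ztr, classes)
    return mean, sd, svm


def loto_cv(table: pd.DataFrame, features: list[str], *,
            target: str = "P_Asym", linkage: str = "average",
            svm_params: dict | None = None, labeling: str = "per-fold",
            return_models: bool = False) -> CVReport:
    """Leave-one-trial-out cross-validation of the EDA-only classifier.

    For each task and each validation trial, fits standardizer + clustering
    labels + SVM on the other trials (pooled over participants) and scores
    the held-out trial's windows by coincidence with the FAA sign.

    ``features`` must be EDA/HRV feature columns only — passing any FAA or
    label column violates the clustering firewall and is rejected.
    """
    forbidden = set(features) & set(TARGET_COLUMNS + LABEL_COLUMNS)
    if forbidden:
        raise ValueError(
            f"FAA/label columns {sorted(forbidden)} may not be used as "
            f"clustering/SVM features")
    unknown = [f for f in features if f not in table.columns]
    if unknown:
        raise ValueError(f"features not in table: {unknown}")
    if labeling not in ("per-fold", "global"):
        raise ValueError("labeling must be 'per-fold' or 'global'")
    svm_params = {"kernel": "rbf", "C": 1.0, "gamma": "scale",
                  **(svm_params or {})}
    table = table.reset_index(drop=True)

    global_classes = None
    if labeling == "global":
        Z = standardize(table[features].to_numpy(dtype=float))
        clustering = agglomerative_cluster(Z, linkage=linkage, n_clusters=2)
        global_classes = label_clusters_by_faa(clustering,
                                               table[target].to_numpy())

    rows = []
    models = {}
    for task, tdf in table.groupby("task", sort=True):
        trials = np.sort(tdf["trial"].unique())
        if trials.size < 2:
            raise ValueError(f"task {task} needs at least 2 trials for LOTO")
        for v in trials:
            train = tdf[tdf["trial"] != v]
            test = tdf[tdf["trial"] == v]
            if test.empty:
                raise ValueError(f"missing validation trial {v} in task {task}")
            if labeling == "per-fold":
                mean, sd, svm = _fit_fold(train, features, linkage,
                                          svm_params, target)
            else:
                Xtr = train[features].to_numpy(dtype=float)
                mean, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
                svm = SVC(**svm_params)
                svm.fit((Xtr - mean) / sd, global_classes[train.index])
            Zte = (test[features].to_numpy(dtype=float) - mean) / sd
            pred = svm.predict(Zte)
            c1, c2 = coincidence_rate(pred, test[target].to_numpy())
            rows.append({"task": task, "validation_trial": int(v),
                         "class1_pct": c1, "class2_pct": c2})
            if return_models:
                models[(task, int(v))] = (mean, sd, svm)
    per_trial = pd.DataFrame(rows)
    task_averages = (per_trial.groupby("task", sort=True)[
        ["class1_pct", "class2_pct"]].mean().reset_index())
    report = CVReport(per_trial=per_trial, task_averages=task_averages)
    if return_models:
        return report, models
    return report
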