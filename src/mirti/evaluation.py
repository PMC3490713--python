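"""Downstream validation battery.

Three standard checks of whether a miRNA feature set carries clinical
signal:

* hierarchical two-group risk stratification of patients (correlation
  distance, average linkage, tree cut at two clusters);
* Kaplan-Meier style group comparison: log-rank test plus a hazard
  ratio from a single-covariate Cox proportional-hazards fit on the
  group indicator;
* cross-validated linear-SVM classification accuracy (features z-scored
  within training folds, C = 1).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import DegenerateDataError

__all__ = ["SurvivalResult", "cluster_two_groups", "logrank_hr", "svm_cv_accuracy"]


@dataclass(frozen=True)
class SurvivalResult:
    """Two-group survival comparison summary.

    ``hazard_ratio`` is the hazard of the indicator group relative to
    the reference group; ``degenerate`` flags comparisons where a group
    has no observed events (the statistics are then unreliable).
    """

    chi_square: float
    p_value: float
    hazard_ratio: float
    degenerate: bool


def cluster_two_groups(
    features: pd.DataFrame,
    seed: int = 0,
    metric: str = "correlation",
    linkage_method: str = "average",
) -> pd.Series:
    """Agglomerative two-group split of samples (rows) by their profiles.

    Correlation distance (1 - Pearson) with average linkage by default,
    tree cut at two clusters.  Labels are 0/1 with the first sample's
    cluster labeled 0 (deterministic tie-breaking by sample order; the
    ``seed`` argument is accepted for interface uniformity but the
    linkage itself is deterministic).  A constant feature matrix — or
    any constant sample profile under correlation distance — raises
    :class:`DegenerateDataError`.
    """
    del seed  # deterministic; kept for interface uniformity
    if len(features) < 4:
        raise ValueError("need at least 4 samples")
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    X = features.to_numpy(dtype=float)
    if np.ptp(X) == 0:
        raise DegenerateDataError("constant feature matrix")
    if metric == "correlation" and (np.ptp(X, axis=1) == 0).any():
        raise DegenerateDataError("constant sample profile under correlation distance")
    dist = pdist(X, metric=metric)
    if not np.isfinite(dist).all():
        raise DegenerateDataError("non-finite distances between samples")
    tree = hierarchy.linkage(dist, method=linkage_method)
    labels = hierarchy.fcluster(tree, t=2, criterion="maxclust")
    labels = (labels != labels[0]).astype(int)  # first sample's cluster -> 0
    return pd.Series(labels, index=features.index, name="group")


def logrank_hr(
    groups: pd.Series, ann: pd.DataFrame, reference=None
) -> SurvivalResult:
    """Two-group log-rank test and Cox hazard ratio.

    ``groups`` maps sample -> group label (exactly two labels, both
    nonempty); ``ann`` must contain ``time`` and ``event`` for every
    sample.  ``reference`` picks the denominator group of the hazard
    ratio (default: the smaller label in sort order).  Relabeling the
    groups inverts the hazard ratio and leaves the chi-square unchanged.
    """
    groups = pd.Series(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 nonempty groups, got {labels}")
    missing = [s for s in groups.index if s not in ann.index]
    if missing:
        raise ValueError(f"missing survival rows for sample(s): {missing[:3]}")
    if reference is None:
        reference = labels[0]
    if reference not in labels:
        raise ValueError(f"reference {reference!r} is not a group label")
    other = labels[1] if reference == labels[0] else labels[0]

    sub = ann.loc[groups.index]
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int)
    indicator = (groups.to_numpy() == other).astype(int)

    ref_mask = indicator == 0
    res = logrank_test(
        time[ref_mask], time[~ref_mask], event[ref_mask], event[~ref_mask]
    )
    degenerate = event[ref_mask].sum() == 0 or event[~ref_mask].sum() == 0

    cox_df = pd.DataFrame({"time": time, "event": event, "group": indicator})
    try:
        cph = CoxPHFitter()
        cph.fit(cox_df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["group"]))
    except Exception:
        hr = float("nan")
        degenerate = True
    return SurvivalResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        hazard_ratio=hr,
        degenerate=bool(degenerate),
    )


def svm_cv_accuracy(
    features: pd.DataFrame,
    labels: Sequence,
    n_folds: int = 5,
    seed: int = 0,
    c: float = 1.0,
) -> float:
    """Stratified cross-validated linear-SVM accuracy of a feature set.

    Features are z-scored within each training fold; returns the mean
    fold accuracy.  Both classes must have at least ``n_folds`` members.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {n_folds} folds"
        )
    X = features.to_numpy(dtype=float)
    model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))
    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in folds.split(X, y):
        model.fit(X[train], y[train])
        accs.append(float((model.predict(X[test]) == y[test]).mean()))
    return float(np.mean(accs))
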