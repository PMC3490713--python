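"""Transcriptional activity centers.

A gene sitting in a neighborhood of strongly co-expressed, strongly
differentially expressed partners is an "activity center" even when the
gene itself shows no expression change (e.g. regulation at the
post-translational level).  Per gene ``i`` with FPI partners ``d``:

    ActivityScore(i) = [ (1/N) * sum_d CorrFPI(i, d) * R(d) ]
                       * max_d CorrFPI(i, d) * R(d)

where ``N`` is the number of FPI partners, ``CorrFPI`` is the MI of the
edge's expression profiles and ``R`` the partner's DE significance.
Isolated genes score 0 structurally.

Genes whose score exceeds the mean score (over genes with at least one
partner) are principal regulators, split by the gene's own DE p-value:
significant (``p <= p_thresh``) marks a transcriptional center,
non-significant a putative post-translational center.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .influence import CorrFPIMap
from .mi import differential_significance

__all__ = [
    "activity_score",
    "activity_profile",
    "classify_regulators",
    "activity_stability",
]

REGULATOR_CLASSES = ("significant_DE_center", "posttranslational_center", "none")


def activity_score(gene: str, corrfpi: CorrFPIMap, de_r: Mapping[str, float]) -> float:
    """ActivityScore of one gene (0 for FPI-isolated genes).

    ``de_r`` maps gene -> R (DE significance) and must cover every FPI
    partner of ``gene``.
    """
    partners = corrfpi.partners(gene)
    if not partners:
        return 0.0
    products = []
    for d in partners:
        if d not in de_r:
            raise ValueError(f"partner {d!r} of {gene!r} missing from DE results")
        products.append(corrfpi.get(gene, d) * de_r[d])
    products = np.asarray(products, dtype=float)
    return float(products.mean() * products.max())


def activity_profile(corrfpi: CorrFPIMap, de: pd.DataFrame) -> pd.DataFrame:
    """ActivityScore for every gene in the DE table.

    Returns a DataFrame indexed by gene with columns ``R``,
    ``n_neighbors`` and ``activity_score``.
    """
    de_r = de["R"].to_dict()
    rows = {
        gene: (
            de.at[gene, "R"],
            len(corrfpi.partners(gene)),
            activity_score(gene, corrfpi, de_r),
        )
        for gene in de.index
    }
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["R", "n_neighbors", "activity_score"]
    )
    out.index.name = "gene"
    return out


def classify_regulators(
    profile: pd.DataFrame, de: pd.DataFrame, p_thresh: float = 0.05
) -> pd.Series:
    """Partition genes into principal-regulator classes.

    Genes with ActivityScore strictly above the mean score of genes with
    at least one FPI neighbor (structural zeros excluded from the mean)
    are centers; their own DE p-value decides the subclass.  Everything
    else is ``"none"``.  The classes are disjoint and exhaustive.
    """
    if not profile.index.equals(de.index):
        raise ValueError("profile and DE results must cover the same gene set")
    connected = profile["n_neighbors"] > 0
    mean_score = profile.loc[connected, "activity_score"].mean() if connected.any() else 0.0
    high = profile["activity_score"] > mean_score
    significant = de["p"] <= p_thresh
    out = pd.Series("none", index=profile.index, name="regulator_class")
    out[high & significant] = "significant_DE_center"
    out[high & ~significant] = "posttranslational_center"
    return out


def activity_stability(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    corrfpi: CorrFPIMap,
    n_rounds: int = 20,
    seed: int = 0,
    subsample_frac: float = 0.8,
    welch: bool = True,
) -> float:
    """Resampling robustness of the ActivityScore profile.

    Each round draws a stratified ``subsample_frac`` subsample of both
    groups, recomputes the DE significance on it and rebuilds the
    ActivityScore profile (CorrFPI is held fixed — it does not depend on
    the group split).  Returns the mean pairwise squared Pearson
    correlation across the rounds' profiles, in [0, 1]; reproducible
    from ``seed``.
    """
    if n_rounds < 2:
        raise ValueError("n_rounds must be >= 2")
    group_a = list(group_a)
    group_b = list(group_b)
    n_a = int(np.floor(subsample_frac * len(group_a)))
    n_b = int(np.floor(subsample_frac * len(group_b)))
    if n_a < 2 or n_b < 2:
        raise ValueError("groups too small to subsample")
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_rounds):
        sub_a = [group_a[i] for i in rng.choice(len(group_a), size=n_a, replace=False)]
        sub_b = [group_b[i] for i in rng.choice(len(group_b), size=n_b, replace=False)]
        de = differential_significance(expr, sub_a, sub_b, welch=welch)
        profiles.append(
            activity_profile(corrfpi, de)["activity_score"].to_numpy(dtype=float)
        )
    mat = np.vstack(profiles)
    r2s = []
    for i in range(n_rounds):
        for j in range(i + 1, n_rounds):
            xi, xj = mat[i], mat[j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                r2s.append(1.0 if np.allclose(xi, xj) else 0.0)
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            r2s.append(float(r * r))
    return float(np.mean(r2s))
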