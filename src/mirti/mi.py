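"""Statistical kernel: mutual information, Pearson correlation, DE significance.

Mutual information between two expression profiles is estimated by
discretizing each profile into ``n_bins`` bins (equal-frequency by
default, with ties broken by stable rank order), forming the joint
histogram, and summing ``p(d,r) * log[p(d,r) / (p(d) p(r))]`` over
occupied cells.  Equal-frequency binning makes the estimate invariant
under strictly monotone transforms of either profile (for distinct
values) and gives the self-information MI(x, x) an analytic value: the
entropy of the discretized marginal, log(n_bins) when the sample count
divides evenly.

Differential-expression significance is summarized per gene as
``R = -log10(p)`` of a two-sample t-test (Welch by default), so larger R
means more significant.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MIEstimatorConfig",
    "DEFAULT_MI_CONFIG",
    "discretize",
    "mutual_information",
    "entropy",
    "pearson",
    "differential_significance",
]

_MIN_MI_SAMPLES = 8


@dataclass(frozen=True)
class MIEstimatorConfig:
    """Density-estimation policy for the MI kernel.

    Parameters
    ----------
    n_bins:
        Number of discretization bins (>= 2).  8 is a robust default for
        cohorts of ~100-150 samples.
    binning:
        ``"equal_frequency"`` (rank-based, default) or ``"equal_width"``.
    log_base:
        ``"natural"`` (nats, default) or ``"2"`` (bits).
    """

    n_bins: int = 8
    binning: str = "equal_frequency"
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.binning not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown binning {self.binning!r}")
        if self.log_base not in ("natural", "2"):
            raise ValueError(f"unknown log_base {self.log_base!r}")

    @property
    def log_scale(self) -> float:
        return 1.0 if self.log_base == "natural" else np.log(2.0)


DEFAULT_MI_CONFIG = MIEstimatorConfig()


def discretize(x: Sequence[float], cfg: MIEstimatorConfig = DEFAULT_MI_CONFIG) -> np.ndarray:
    """Map a profile to integer bin codes in ``[0, n_bins)`` per ``cfg``."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D profile")
    if not np.isfinite(arr).all():
        raise ValueError("profile contains non-finite values")
    n = arr.size
    if cfg.binning == "equal_frequency":
        # ordinal ranks give stable tie-breaking and near-equal bin sizes
        ranks = stats.rankdata(arr, method="ordinal").astype(np.int64) - 1
        return (ranks * cfg.n_bins) // n
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(n, dtype=np.int64)
    edges = np.linspace(lo, hi, cfg.n_bins + 1)[1:-1]
    return np.digitize(arr, edges)


def mi_from_codes(cx: np.ndarray, cy: np.ndarray, n_bins: int, log_scale: float = 1.0) -> float:
    """MI (in nats / log_scale) of two already-discretized profiles."""
    n = cx.size
    joint = np.bincount(cx * n_bins + cy, minlength=n_bins * n_bins).astype(float)
    joint /= n
    pj = joint.reshape(n_bins, n_bins)
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    mask = pj > 0
    outer = px[:, None] * py[None, :]
    mi = float(np.sum(pj[mask] * np.log(pj[mask] / outer[mask])))
    # clip tiny negative round-off; true MI is nonnegative
    return max(mi, 0.0) / log_scale


def mutual_information(
    x: Sequence[float],
    y: Sequence[float],
    cfg: MIEstimatorConfig = DEFAULT_MI_CONFIG,
) -> float:
    """Mutual information between two expression profiles.

    Symmetric and nonnegative.  Profiles with zero variance carry no
    information and yield 0.  Raises on length mismatch or fewer than 8
    observations.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < _MIN_MI_SAMPLES:
        raise ValueError(f"need at least {_MIN_MI_SAMPLES} observations, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return 0.0
    return mi_from_codes(discretize(xa, cfg), discretize(ya, cfg), cfg.n_bins, cfg.log_scale)


def entropy(x: Sequence[float], cfg: MIEstimatorConfig = DEFAULT_MI_CONFIG) -> float:
    """Entropy of the discretized marginal of ``x`` (same units as MI)."""
    codes = discretize(np.asarray(x, dtype=float), cfg)
    p = np.bincount(codes, minlength=cfg.n_bins).astype(float) / codes.size
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) / cfg.log_scale


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two profiles.

    Raises on length mismatch, fewer than 3 observations, or zero
    variance in either argument (callers that use the sign as a filter
    treat zero variance as "no correlation evidence" before calling).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance profile")
    xa = xa - xa.mean()
    ya = ya - ya.mean()
    denom = np.sqrt((xa * xa).sum() * (ya * ya).sum())
    return float(np.clip((xa * ya).sum() / denom, -1.0, 1.0))


def differential_significance(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    welch: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t-test significance between two sample groups.

    Returns a DataFrame indexed by gene with columns ``t``, ``p`` and
    ``R = -log10(p)``.  Genes with zero variance in both groups (no
    evidence either way) get ``p = 1, R = 0``.  Welch's unequal-variance
    test is the default; set ``welch=False`` for the pooled-variance
    Student test.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    samples = set(expr.columns)
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        missing = [s for s in grp if s not in samples]
        if missing:
            raise ValueError(f"{name} contains unknown sample(s): {missing[:3]}")
        if len(grp) < 2:
            raise ValueError(f"{name} must contain at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")

    a = expr.loc[:, group_a].to_numpy(dtype=float)
    b = expr.loc[:, group_b].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    flat = np.isnan(t) | np.isnan(p)  # zero variance in both groups
    t[flat] = 0.0
    p[flat] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame({"t": t, "p": p, "R": -np.log10(p)}, index=expr.index)
    return out
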