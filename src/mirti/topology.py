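"""Protein network topology vs miRNA regulation.

Tests the global observation that highly connected proteins are targeted
by more miRNAs while tightly clustered proteins (complex members) need
fewer: per protein, degree and local clustering coefficient in the FPI
network are related to the number of targeting miRNAs (the protein's
in-degree in the Seq relation).

The summary statistic is the signed per-protein Pearson correlation
(Spearman available via ``method="spearman"``) between each topology
measure and the targeting count; its null distribution under
degree-preserving randomization is tight, which a trend-line correlation
over binned means is not.  The report still carries bin-level means
(exact-degree bins, clustering in 10 equal-width bins on [0, 1], bins
with at least ``min_bin_count`` proteins) for trend-line inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import TargetNetwork

__all__ = ["TopologyReport", "clustering_coefficient", "topology_mirna_correlation"]


@dataclass(frozen=True)
class TopologyReport:
    """Per-protein topology table plus the two summary correlations.

    ``degree_r`` / ``clustering_r`` are signed correlations between the
    topology measure and the number of targeting miRNAs; a degenerate
    flag marks zero-variance inputs (reported as r=0, p=1).
    ``degree_trend`` / ``clustering_trend`` hold the binned means used
    for trend-line plots.
    """

    per_protein: pd.DataFrame
    degree_r: float
    degree_p: float
    degree_degenerate: bool
    clustering_r: float
    clustering_p: float
    clustering_degenerate: bool
    degree_trend: pd.DataFrame = field(repr=False, default=None)
    clustering_trend: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"degree vs #miRNAs: r={self.degree_r:+.3f} (p={self.degree_p:.3g})"
            f"{' [degenerate]' if self.degree_degenerate else ''}; "
            f"clustering vs #miRNAs: r={self.clustering_r:+.3f} "
            f"(p={self.clustering_p:.3g})"
            f"{' [degenerate]' if self.clustering_degenerate else ''}"
        )


def clustering_coefficient(fpi: nx.Graph, node: str) -> float:
    """Local clustering coefficient ``2*triangles / (k*(k-1))``; 0 for k<2."""
    if node not in fpi:
        raise ValueError(f"unknown node {node!r}")
    return float(nx.clustering(fpi, node))


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float, bool]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0, True
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p), False


def _trend(x: np.ndarray, y: np.ndarray, bin_ids: np.ndarray, min_bin_count: int) -> pd.DataFrame:
    df = pd.DataFrame({"x": x, "y": y, "bin": bin_ids})
    grouped = df.groupby("bin").agg(
        x=("x", "mean"), mean_n_mirnas=("y", "mean"), n_proteins=("y", "size")
    )
    return grouped[grouped["n_proteins"] >= min_bin_count].reset_index(drop=True)


def topology_mirna_correlation(
    fpi: nx.Graph,
    seq: TargetNetwork,
    method: str = "pearson",
    min_bin_count: int = 5,
    min_shared: int = 20,
    betweenness: bool = False,
) -> TopologyReport:
    """Correlate FPI degree and clustering with the number of targeting miRNAs.

    Requires at least ``min_shared`` proteins present in both the FPI
    node set and the Seq gene set.  All FPI proteins enter the analysis
    (targeting count 0 when absent from Seq).  Betweenness centrality is
    optionally added to the per-protein table as a descriptive column
    (it enters no summary statistic).  The report is invariant to node
    ordering.
    """
    nodes = sorted(fpi.nodes())
    shared = set(nodes) & set(seq.genes)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} proteins shared between FPI and Seq "
            f"(need >= {min_shared})"
        )
    degree = np.array([fpi.degree(n) for n in nodes], dtype=float)
    clustering = nx.clustering(fpi)
    cc = np.array([clustering[n] for n in nodes], dtype=float)
    n_mirnas = np.array([len(seq.mirnas_targeting(n)) for n in nodes], dtype=float)

    per_protein = pd.DataFrame(
        {
            "degree": degree.astype(int),
            "clustering": cc,
            "n_targeting_mirnas": n_mirnas.astype(int),
        },
        index=pd.Index(nodes, name="protein"),
    )
    if betweenness:
        bet = nx.betweenness_centrality(fpi)
        per_protein["betweenness"] = [bet[n] for n in nodes]

    deg_r, deg_p, deg_flag = _correlate(degree, n_mirnas, method)
    cc_r, cc_p, cc_flag = _correlate(cc, n_mirnas, method)
    cc_bins = np.minimum((cc * 10).astype(int), 9)  # 10 equal-width bins on [0, 1]
    return TopologyReport(
        per_protein=per_protein,
        degree_r=deg_r,
        degree_p=deg_p,
        degree_degenerate=deg_flag,
        clustering_r=cc_r,
        clustering_p=cc_p,
        clustering_degenerate=cc_flag,
        degree_trend=_trend(degree, n_mirnas, degree.astype(int), min_bin_count),
        clustering_trend=_trend(cc, n_mirnas, cc_bins, min_bin_count),
    )
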