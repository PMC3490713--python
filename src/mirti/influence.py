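"""Construction of the miRNA-target influence (miRTI) network.

The influence of a miRNA ``miR`` on a sequence-predicted target ``t`` is
the product of three evidence channels computed on matched miRNA/mRNA
expression profiles and a functional protein interaction (FPI) network:

* ``corrmir(miR, t)`` — MI(miR, t) if ``Seq(miR, t) = 1`` and the
  Pearson correlation of the pair is negative (repression evidence),
  else 0;
* ``w(miR, t) = sum_k MI(miR, k) * MI(k, t)`` over the FPI partners
  ``k`` of ``t`` — the indirect influence of the miRNA on the target
  through its partners;
* ``max_corrfpi(t) = max_k MI(t, k)`` — the target's strongest partner
  co-expression, representing the direct influence of the miRNA on the
  target's partners.

``mirti = corrmir * w * max_corrfpi``; the score is zero whenever any
channel is zero (no sequence support, nonnegative correlation, or an
FPI-isolated target).

High-influence miRNA-target modules are the connected components of the
graph over retained entries (``mirti`` strictly above the upper quartile
of the positive scores) plus the FPI edges among retained targets.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError
from .io import TargetNetwork
from .mi import DEFAULT_MI_CONFIG, MIEstimatorConfig, discretize, mi_from_codes

log = logging.getLogger(__name__)

__all__ = [
    "CorrFPIMap",
    "MiRTargetModule",
    "compute_corrfpi",
    "compute_corrmir",
    "compute_w",
    "build_mirti",
    "extract_modules",
    "randomize_for_null",
    "write_influence",
    "read_influence",
    "write_modules",
]

INFLUENCE_COLUMNS = ("miRNA", "target", "corrmir", "w", "max_corrfpi", "mirti")


class CorrFPIMap:
    """MI values on FPI edges; zero is implied for non-edges.

    The map is symmetric and defined exactly on the FPI edge set; it also
    records each gene's FPI partner list so downstream consumers (the W
    channel, ActivityScore) can iterate neighborhoods without carrying
    the graph around.
    """

    __slots__ = ("_mi", "_partners")

    def __init__(self, values: dict[tuple[str, str], float], partners: dict[str, tuple[str, ...]]):
        self._mi = values
        self._partners = partners

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self._mi.get(self._key(a, b), default)

    def partners(self, gene: str) -> tuple[str, ...]:
        """FPI partners of ``gene`` (empty tuple if absent or isolated)."""
        return self._partners.get(gene, ())

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), v in self._mi.items():
            yield a, b, v

    def __len__(self) -> int:
        return len(self._mi)


class _CodeCache:
    """Lazily discretized profiles of an expression matrix."""

    def __init__(self, expr: pd.DataFrame, cfg: MIEstimatorConfig):
        self._expr = expr
        self._cfg = cfg
        self._codes: dict[str, np.ndarray | None] = {}

    def __contains__(self, row_id: str) -> bool:
        return row_id in self._expr.index

    def codes(self, row_id: str) -> np.ndarray | None:
        """Bin codes for a row; ``None`` for zero-variance profiles."""
        try:
            return self._codes[row_id]
        except KeyError:
            x = self._expr.loc[row_id].to_numpy(dtype=float)
            out = None if np.ptp(x) == 0 else discretize(x, self._cfg)
            self._codes[row_id] = out
            return out

    def values(self, row_id: str) -> np.ndarray:
        return self._expr.loc[row_id].to_numpy(dtype=float)


def _cached_mi(
    ca: np.ndarray | None, cb: np.ndarray | None, cfg: MIEstimatorConfig
) -> float:
    if ca is None or cb is None:
        return 0.0
    return mi_from_codes(ca, cb, cfg.n_bins, cfg.log_scale)


def _check_aligned(mirna: pd.DataFrame, mrna: pd.DataFrame) -> None:
    if list(mirna.columns) != list(mrna.columns):
        raise ValueError("miRNA and mRNA matrices are not sample-aligned")


# ---------------------------------------------------------------------------
# evidence channels
# ---------------------------------------------------------------------------


def compute_corrfpi(
    expr: pd.DataFrame,
    fpi: nx.Graph,
    cfg: MIEstimatorConfig = DEFAULT_MI_CONFIG,
) -> CorrFPIMap:
    """MI between the expression profiles of every FPI edge's endpoints.

    Edges with an endpoint missing from ``expr`` (or with a constant
    profile) carry 0.
    """
    cache = _CodeCache(expr, cfg)
    values: dict[tuple[str, str], float] = {}
    for a, b in fpi.edges():
        key = CorrFPIMap._key(a, b)
        if a in cache and b in cache:
            values[key] = _cached_mi(cache.codes(a), cache.codes(b), cfg)
        else:
            values[key] = 0.0
    partners = {node: tuple(sorted(fpi.neighbors(node))) for node in fpi.nodes()}
    return CorrFPIMap(values, partners)


def _corrmir_one(
    mir_cache: _CodeCache,
    gene_cache: _CodeCache,
    mir: str,
    gene: str,
    cfg: MIEstimatorConfig,
) -> float:
    if mir not in mir_cache or gene not in gene_cache:
        return 0.0
    x = mir_cache.values(mir)
    y = gene_cache.values(gene)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # zero-variance profiles carry no correlation evidence
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    if not (r < 0):
        return 0.0
    return _cached_mi(mir_cache.codes(mir), gene_cache.codes(gene), cfg)


def compute_corrmir(
    mirna: pd.DataFrame,
    mrna: pd.DataFrame,
    seq: TargetNetwork,
    cfg: MIEstimatorConfig = DEFAULT_MI_CONFIG,
) -> dict[tuple[str, str], float]:
    """Negative-correlation-filtered MI channel for every Seq pair.

    ``corrmir(miR, t) = MI(miR, t)`` if ``Seq(miR, t) = 1`` and the
    Pearson correlation of the pair is negative; 0 otherwise (including
    pairs whose profiles are missing or constant).
    """
    _check_aligned(mirna, mrna)
    mir_cache = _CodeCache(mirna, cfg)
    gene_cache = _CodeCache(mrna, cfg)
    return {
        (m, t): _corrmir_one(mir_cache, gene_cache, m, t, cfg)
        for m, t in sorted(seq.pairs)
    }


def compute_w(
    mirna: pd.DataFrame,
    mrna: pd.DataFrame,
    fpi: nx.Graph,
    pair: tuple[str, str],
    cfg: MIEstimatorConfig = DEFAULT_MI_CONFIG,
) -> float:
    """Indirect influence ``W(miR, t) = sum_k MI(miR, k) * MI(k, t)``.

    ``k`` runs over the FPI partners of ``t`` (the target itself is not
    its own partner); an FPI-isolated or absent target yields 0.
    """
    _check_aligned(mirna, mrna)
    mir, target = pair
    if target not in fpi:
        return 0.0
    mir_cache = _CodeCache(mirna, cfg)
    gene_cache = _CodeCache(mrna, cfg)
    mc = mir_cache.codes(mir) if mir in mir_cache else None
    total = 0.0
    for k in fpi.neighbors(target):
        if k not in gene_cache or target not in gene_cache:
            continue
        mi_mk = _cached_mi(mc, gene_cache.codes(k), cfg)
        mi_kt = _cached_mi(gene_cache.codes(k), gene_cache.codes(target), cfg)
        total += mi_mk * mi_kt
    return total


# ---------------------------------------------------------------------------
# miRTI network
# ---------------------------------------------------------------------------


def build_mirti(
    mirna: pd.DataFrame,
    mrna: pd.DataFrame,
    fpi: nx.Graph,
    seq: TargetNetwork,
    cfg: MIEstimatorConfig = DEFAULT_MI_CONFIG,
) -> pd.DataFrame:
    """Score every Seq pair: ``mirti = corrmir * w * max_corrfpi``.

    Returns a DataFrame with columns ``miRNA, target, corrmir, w,
    max_corrfpi, mirti`` sorted by (miRNA, target).  All MI values are
    computed once through a shared per-profile discretization cache, so
    recomputation is bit-identical and deterministic given ``cfg``.
    """
    _check_aligned(mirna, mrna)
    corrfpi = compute_corrfpi(mrna, fpi, cfg)
    mir_cache = _CodeCache(mirna, cfg)
    gene_cache = _CodeCache(mrna, cfg)
    mi_mk_memo: dict[tuple[str, str], float] = {}

    def mi_mir_gene(m: str, k: str) -> float:
        key = (m, k)
        try:
            return mi_mk_memo[key]
        except KeyError:
            if m in mir_cache and k in gene_cache:
                v = _cached_mi(mir_cache.codes(m), gene_cache.codes(k), cfg)
            else:
                v = 0.0
            mi_mk_memo[key] = v
            return v

    rows = []
    for m, t in sorted(seq.pairs):
        corrmir = _corrmir_one(mir_cache, gene_cache, m, t, cfg)
        partners = corrfpi.partners(t)
        w = 0.0
        max_fpi = 0.0
        for k in partners:
            mi_kt = corrfpi.get(k, t)
            w += mi_mir_gene(m, k) * mi_kt
            if mi_kt > max_fpi:
                max_fpi = mi_kt
        rows.append((m, t, corrmir, w, max_fpi, corrmir * w * max_fpi))
    net = pd.DataFrame(rows, columns=list(INFLUENCE_COLUMNS))
    log.info(
        "miRTI network: %d Seq pairs, %d with corrmir>0, %d with mirti>0",
        len(net),
        int((net["corrmir"] > 0).sum()),
        int((net["mirti"] > 0).sum()),
    )
    return net


@dataclass(frozen=True)
class MiRTargetModule:
    """A connected high-influence miRNA-target module."""

    mirnas: frozenset[str]
    targets: frozenset[str]
    mir_edges: frozenset[tuple[str, str]]
    fpi_edges: frozenset[tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.mirnas) + len(self.targets)


def retention_threshold(net: pd.DataFrame) -> float:
    """Upper quartile (75th percentile, linear interpolation) of the
    strictly positive mirti scores; zeros are structural and excluded."""
    positive = net.loc[net["mirti"] > 0, "mirti"].to_numpy()
    if positive.size == 0:
        raise DegenerateDataError("no positive influence scores")
    return float(np.percentile(positive, 75))


def extract_modules(net: pd.DataFrame, fpi: nx.Graph) -> list[MiRTargetModule]:
    """Extract top-quartile miRNA-target modules.

    Entries with ``mirti`` strictly above the upper quartile of positive
    scores are retained; modules are the connected components of the
    bipartite graph over retained miRNA->target edges plus the FPI edges
    among retained targets.  Modules are returned largest first (ties by
    lexicographic node order).
    """
    if net.empty:
        raise DegenerateDataError("no positive influence scores")
    threshold = retention_threshold(net)
    kept = net[net["mirti"] > threshold]
    graph = nx.Graph()
    for m, t in zip(kept["miRNA"], kept["target"]):
        graph.add_edge(("miR", m), ("gene", t))
    targets = {t for t in kept["target"]}
    for t in targets:
        if t in fpi:
            for k in fpi.neighbors(t):
                if k in targets:
                    graph.add_edge(("gene", t), ("gene", k))
    modules = []
    for component in nx.connected_components(graph):
        mirnas = frozenset(n for kind, n in component if kind == "miR")
        genes = frozenset(n for kind, n in component if kind == "gene")
        mir_edges = frozenset(
            (m, t)
            for m, t in zip(kept["miRNA"], kept["target"])
            if m in mirnas and t in genes
        )
        fpi_edges = frozenset(
            tuple(sorted((a, b)))
            for (ka, a), (kb, b) in graph.edges()
            if ka == "gene" and kb == "gene" and a in genes and b in genes
        )
        modules.append(MiRTargetModule(mirnas, genes, mir_edges, fpi_edges))
    modules.sort(key=lambda mod: (-mod.size, sorted(mod.mirnas), sorted(mod.targets)))
    return modules


# ---------------------------------------------------------------------------
# degree-preserving nulls
# ---------------------------------------------------------------------------


def _swap_bipartite_margins(
    pairs: list[tuple[str, str]], rng: np.random.Generator, n_attempts: int
) -> frozenset[tuple[str, str]]:
    """Checkerboard swaps preserving miRNA out-degree and gene in-degree."""
    pair_set = set(pairs)
    pairs = list(pairs)
    n = len(pairs)
    for _ in range(n_attempts):
        i, j = rng.integers(0, n, size=2)
        (m1, t1), (m2, t2) = pairs[i], pairs[j]
        if m1 == m2 or t1 == t2:
            continue
        if (m1, t2) in pair_set or (m2, t1) in pair_set:
            continue
        pair_set.discard((m1, t1))
        pair_set.discard((m2, t2))
        pair_set.add((m1, t2))
        pair_set.add((m2, t1))
        pairs[i] = (m1, t2)
        pairs[j] = (m2, t1)
    return frozenset(pair_set)


def randomize_for_null(
    fpi: nx.Graph,
    seq: TargetNetwork,
    seed: int,
    mode: str = "margins",
) -> tuple[nx.Graph, TargetNetwork]:
    """Degree-preserving randomization of the FPI and Seq networks.

    The FPI graph is rewired by double-edge swaps (10x|E| successful
    swaps), preserving every protein's degree.  The Seq relation is
    randomized per ``mode``:

    * ``"margins"`` — checkerboard swaps preserving both each miRNA's
      out-degree and each gene's in-degree (10x|pairs| swap attempts).
      Appropriate for module-level nulls, where the expression coupling
      must be broken while all degrees are kept.
    * ``"mirna_degree"`` — each miRNA keeps its target count but target
      genes are redrawn uniformly from the FPI node set.  This breaks
      the gene-side degree/targeting coupling and is the null for the
      topology analysis (a margins-preserving null leaves every gene's
      degree and targeting count, hence their correlation, unchanged).

    Reproducible from ``seed``.
    """
    if fpi.number_of_edges() < 2 or fpi.number_of_nodes() < 4:
        raise DegenerateDataError("FPI network too small to rewire")
    if len(seq) < 2:
        raise DegenerateDataError("Seq relation too small to rewire")
    if mode not in ("margins", "mirna_degree"):
        raise ValueError(f"unknown randomization mode {mode!r}")

    rng = np.random.default_rng(seed)
    rewired = fpi.copy()
    n_edges = rewired.number_of_edges()
    nx.double_edge_swap(
        rewired,
        nswap=10 * n_edges,
        max_tries=1000 * n_edges,
        seed=int(rng.integers(2**31)),
    )

    pairs = sorted(seq.pairs)
    if mode == "margins":
        new_pairs = _swap_bipartite_margins(pairs, rng, 10 * len(pairs))
    else:
        universe = sorted(fpi.nodes()) if fpi.number_of_nodes() else sorted(seq.genes)
        new_pairs = set()
        for mirna in sorted(seq.mirnas):
            k = len(seq.targets_of(mirna))
            chosen = rng.choice(len(universe), size=min(k, len(universe)), replace=False)
            new_pairs.update((mirna, universe[i]) for i in chosen)
        new_pairs = frozenset(new_pairs)
    return rewired, TargetNetwork(new_pairs)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_influence(net: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    """Serialize as ``miRNA<TAB>target<TAB>corrmir<TAB>w<TAB>max_corrfpi<TAB>mirti``."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        net.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_influence(path) -> pd.DataFrame:
    net = pd.read_csv(path, sep="\t", comment="#", dtype={"miRNA": str, "target": str})
    if list(net.columns) != list(INFLUENCE_COLUMNS):
        raise ValueError(
            f"influence table must have columns {list(INFLUENCE_COLUMNS)}, "
            f"got {list(net.columns)}"
        )
    return net


def write_modules(modules: list[MiRTargetModule], path, comments: Iterable[str] = ()) -> None:
    """Module membership TSV: ``module<TAB>kind<TAB>a<TAB>b`` rows, where
    ``kind`` is node (b empty), mir_edge, or fpi_edge."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("module\tkind\ta\tb\n")
        for idx, mod in enumerate(modules):
            for m in sorted(mod.mirnas):
                fh.write(f"{idx}\tmirna\t{m}\t\n")
            for t in sorted(mod.targets):
                fh.write(f"{idx}\ttarget\t{t}\t\n")
            for m, t in sorted(mod.mir_edges):
                fh.write(f"{idx}\tmir_edge\t{m}\t{t}\n")
            for a, b in sorted(mod.fpi_edges):
                fh.write(f"{idx}\tfpi_edge\t{a}\t{b}\n")
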