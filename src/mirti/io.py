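"""Readers, writers and domain containers for the tool's tabular formats.

Conventions
-----------
* Expression matrices are :class:`pandas.DataFrame` objects with row
  identifiers (gene symbols or miRNA names) as the index and sample names
  as columns.  Values are continuous, log-scale expression.
* Functional protein interaction (FPI) networks are undirected
  :class:`networkx.Graph` objects on gene identifiers.
* Sequence-predicted miRNA-target relations are :class:`TargetNetwork`
  objects (a deduplicated set of ``(miRNA, gene)`` pairs).
* Sample annotations are DataFrames indexed by sample with columns
  ``class`` (normal / primary / metastatic), ``time`` (months) and
  ``event`` (0/1).

Identifier matching is exact, case-sensitive string equality throughout;
no symbol aliasing is attempted.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CLASS_LABELS = ("normal", "primary", "metastatic")

__all__ = [
    "CLASS_LABELS",
    "TargetNetwork",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_targets",
    "write_targets",
    "read_annotations",
    "write_annotations",
    "align_samples",
]


class TargetNetwork:
    """Binary sequence-based miRNA->gene relation (``Seq(miR, t) = 1``).

    Membership in :attr:`pairs` is equivalent to ``Seq = 1``; absent pairs
    are ``Seq = 0``.  The relation is deduplicated and bipartite.
    """

    __slots__ = ("pairs", "_targets_of", "_mirnas_of")

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: frozenset[tuple[str, str]] = frozenset(
            (str(m), str(g)) for m, g in pairs
        )
        targets: dict[str, set[str]] = {}
        mirnas: dict[str, set[str]] = {}
        for m, g in self.pairs:
            targets.setdefault(m, set()).add(g)
            mirnas.setdefault(g, set()).add(m)
        self._targets_of = {m: frozenset(v) for m, v in targets.items()}
        self._mirnas_of = {g: frozenset(v) for g, v in mirnas.items()}

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(self._targets_of)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._mirnas_of)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self._targets_of.get(mirna, frozenset())

    def mirnas_targeting(self, gene: str) -> frozenset[str]:
        return self._mirnas_of.get(gene, frozenset())

    def union(self, other: "TargetNetwork") -> "TargetNetwork":
        return TargetNetwork(self.pairs | other.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetNetwork) and self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash(self.pairs)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TargetNetwork({len(self.pairs)} pairs, "
            f"{len(self._targets_of)} miRNAs, {len(self._mirnas_of)} genes)"
        )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression(
    path,
    impute: str = "row_mean",
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Read a genes/miRNAs x samples expression TSV.

    The file has a header row of sample names and row identifiers in the
    first column.  Missing cells are imputed with the row mean; rows with
    more than ``max_missing_frac`` missing values are dropped with a
    logged warning.  Duplicate row or sample identifiers and non-numeric
    cells raise :class:`ValueError` naming the offender.
    """
    # pandas mangles duplicate header names, so check them on the raw line
    with open(path) as fh:
        header = ""
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                header = line.rstrip("\n")
                break
    sample_names = header.split("\t")[1:]
    seen: set[str] = set()
    for name in sample_names:
        if name in seen:
            raise ValueError(f"duplicate sample identifier: {name!r}")
        seen.add(name)

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    raw.index = raw.index.astype(str)
    dup_rows = raw.index[raw.index.duplicated()]
    if len(dup_rows):
        raise ValueError(f"duplicate row identifier: {dup_rows[0]!r}")

    values = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = values.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}"
        )
    if np.isinf(values.to_numpy(dtype=float, na_value=np.nan)).any():
        raise ValueError("expression values must be finite")

    missing_frac = values.isna().mean(axis=1)
    drop = missing_frac > max_missing_frac
    if drop.any():
        log.warning(
            "dropping %d rows with >%d%% missing values: %s",
            int(drop.sum()),
            int(round(100 * max_missing_frac)),
            ", ".join(map(repr, values.index[drop][:5])),
        )
        values = values.loc[~drop]
    if impute == "row_mean":
        row_means = values.mean(axis=1)
        values = values.apply(lambda col: col.fillna(row_means))
    elif impute != "none":
        raise ValueError(f"unknown imputation policy {impute!r}")
    if values.isna().to_numpy().any():
        raise ValueError("matrix still contains missing values after imputation")
    return values.astype(float)


def write_expression(expr: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    """Write an expression matrix as TSV (header ``id<TAB>sample...``)."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        expr.to_csv(fh, sep="\t", index_label="id", lineterminator="\n")


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------


def _two_columns(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            yield fields[0].strip(), fields[1].strip()


def read_network(path) -> nx.Graph:
    """Read an undirected interaction network from a two-column TSV.

    Duplicate edges (in either orientation) are merged; self-loops are
    dropped with a logged count.
    """
    graph = nx.Graph()
    self_loops = 0
    for a, b in _two_columns(path):
        if a == b:
            self_loops += 1
            continue
        graph.add_edge(a, b)
    if self_loops:
        log.info("dropped %d self-loop(s) while reading %s", self_loops, path)
    return graph


def write_network(graph: nx.Graph, path, comments: Iterable[str] = ()) -> None:
    """Write the network as a canonical (sorted) two-column TSV."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# miRNA-target relation
# ---------------------------------------------------------------------------


def read_targets(path) -> TargetNetwork:
    """Read a two-column (miRNA, gene) TSV into a deduplicated relation."""
    return TargetNetwork(_two_columns(path))


def write_targets(seq: TargetNetwork, path, comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        for m, g in sorted(seq.pairs):
            fh.write(f"{m}\t{g}\n")


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------


def read_annotations(path) -> pd.DataFrame:
    """Read a ``sample<TAB>class<TAB>time<TAB>event`` annotation TSV."""
    ann = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str})
    expected = ["sample", "class", "time", "event"]
    if list(ann.columns) != expected:
        raise ValueError(f"annotation header must be {expected}, got {list(ann.columns)}")
    ann = ann.set_index("sample")
    if ann.index.duplicated().any():
        dup = ann.index[ann.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    bad_class = set(ann["class"]) - set(CLASS_LABELS)
    if bad_class:
        raise ValueError(f"unknown class label(s): {sorted(bad_class)}")
    ann["time"] = pd.to_numeric(ann["time"])
    ann["event"] = pd.to_numeric(ann["event"]).astype(int)
    if (ann["time"] < 0).any():
        raise ValueError("survival times must be >= 0")
    if not ann["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    return ann


def write_annotations(ann: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        ann.to_csv(fh, sep="\t", index_label="sample", lineterminator="\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_samples(
    mrna: pd.DataFrame,
    mirna: pd.DataFrame,
    ann: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Restrict the two expression matrices and annotations to shared samples.

    The intersection keeps the mRNA matrix's sample order so that both
    matrices end up identically ordered.  An empty intersection raises
    :class:`ValueError`.  The operation is idempotent.
    """
    mirna_samples = set(mirna.columns)
    ann_samples = set(ann.index)
    shared = [s for s in mrna.columns if s in mirna_samples and s in ann_samples]
    if not shared:
        raise ValueError("no samples shared between mRNA, miRNA and annotations")
    return mrna.loc[:, shared], mirna.loc[:, shared], ann.loc[shared]
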