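"""Synthetic matched miRNA/mRNA cohorts with planted regulatory structure.

The generator emulates the statistical structure the pipeline assumes,
at desk scale:

* a functional protein network built from dense intra-module subgraphs
  (edge probability 0.6 over ``n_modules`` disjoint modules) on top of a
  sparse scale-free preferential-attachment background;
* module co-expression: genes in a module share a latent factor, so FPI
  neighbors are co-expressed;
* planted repression: each driver miRNA targets one module's genes with
  ``target = latent - repression_effect * miR + noise``, and drivers are
  differentially expressed between the normal and cancer classes (plus a
  sign-alternating shift tied to the planted risk group, so risk leaves
  a pattern — not just an offset — across drivers);
* decoy Seq pairs drawn with probability proportional to ``degree**kappa``
  but with no expression linkage, creating the positive degree/targeting
  coupling without functional signal;
* exponential survival with the planted group hazard ratio and uniform
  administrative censoring (~50% events at defaults).

Everything is reproducible bit-for-bit from ``cfg.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    TargetNetwork,
    write_annotations,
    write_expression,
    write_network,
    write_targets,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedData",
    "simulate",
    "simulate_survival",
    "write_fixture",
    "FIXTURE_FILES",
]

FIXTURE_FILES = (
    "mrna.tsv",
    "mirna.tsv",
    "fpi.tsv",
    "seq.tsv",
    "samples.tsv",
    "truth.tsv",
    "config.json",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Expression is on a log-like continuous scale with Gaussian noise.
    ``repression_effect`` is the slope (expression units per unit miRNA
    expression) of the planted repression; ``kappa`` the exponent of the
    degree-coupled decoy targeting; ``decoys_per_mirna`` mirrors
    sequence-prediction density scaled to the gene universe.
    """

    n_genes: int = 600
    n_mirnas: int = 50
    n_normal: int = 30
    n_primary: int = 60
    n_metastatic: int = 10
    n_modules: int = 12
    module_size: int = 15
    n_driver_mirnas: int = 5
    repression_effect: float = 1.0
    noise_sd: float = 0.5
    kappa: float = 1.0
    decoys_per_mirna: int = 12
    class_effect: float = 1.2
    risk_effect: float = 1.2
    module_edge_prob: float = 0.6
    background_attachment: int = 2
    baseline_hazard: float = 0.02
    hazard_ratio: float = 2.8
    censor_horizon: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes,
            self.n_mirnas,
            self.n_normal,
            self.n_primary,
            self.n_metastatic,
            self.n_modules,
            self.module_size,
            self.n_driver_mirnas,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module_size * n_modules exceeds n_genes")
        if self.n_driver_mirnas > min(self.n_mirnas, self.n_modules):
            raise ValueError("more driver miRNAs than miRNAs or modules")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_normal + self.n_primary + self.n_metastatic


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated cohort."""

    drivers: tuple[str, ...]
    planted_pairs: frozenset[tuple[str, str]]
    decoy_pairs: frozenset[tuple[str, str]]
    modules: dict[str, int]
    risk_group: pd.Series


@dataclass(frozen=True)
class SimulatedData:
    mrna: pd.DataFrame
    mirna: pd.DataFrame
    fpi: nx.Graph
    seq: TargetNetwork
    annotations: pd.DataFrame
    truth: GroundTruth


def _build_fpi(cfg: SimulationConfig, genes: list[str], rng: np.random.Generator) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    background = nx.barabasi_albert_graph(
        cfg.n_genes, cfg.background_attachment, seed=int(rng.integers(2**31))
    )
    graph.add_edges_from((genes[a], genes[b]) for a, b in background.edges())
    for m in range(cfg.n_modules):
        block = genes[m * cfg.module_size : (m + 1) * cfg.module_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                if rng.random() < cfg.module_edge_prob:
                    graph.add_edge(block[i], block[j])
    return graph


def simulate(cfg: SimulationConfig = SimulationConfig()) -> SimulatedData:
    """Generate a matched miRNA/mRNA cohort with planted structure."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"miR-{i:03d}" for i in range(cfg.n_mirnas)]
    samples = (
        [f"N{i:03d}" for i in range(cfg.n_normal)]
        + [f"P{i:03d}" for i in range(cfg.n_primary)]
        + [f"M{i:03d}" for i in range(cfg.n_metastatic)]
    )
    classes = (
        ["normal"] * cfg.n_normal
        + ["primary"] * cfg.n_primary
        + ["metastatic"] * cfg.n_metastatic
    )
    is_cancer = np.array([c != "normal" for c in classes], dtype=float)

    # planted risk group: cancer samples split ~50/50, normals low risk
    high = (rng.random(cfg.n_samples) < 0.5) & (is_cancer > 0)
    risk = pd.Series(
        np.where(high, "high", "low"), index=pd.Index(samples, name="sample"),
        name="risk_group",
    )

    fpi = _build_fpi(cfg, genes, rng)

    # miRNA expression: drivers are DE between classes and carry a
    # sign-alternating risk program with opposite polarity in the two
    # risk groups (so each group is a coherent expression pattern, as in
    # real high/low-risk tumor profiles); the rest is standard normal noise
    mirna_values = rng.normal(0.0, 1.0, size=(cfg.n_mirnas, cfg.n_samples))
    drivers = tuple(mirnas[: cfg.n_driver_mirnas])
    risk_ind = np.where(high, 1.0, -1.0) * is_cancer  # normals carry no program
    for j in range(cfg.n_driver_mirnas):
        sign = 1.0 if j % 2 == 0 else -1.0
        mirna_values[j] += cfg.class_effect * is_cancer + sign * cfg.risk_effect * risk_ind
    mirna = pd.DataFrame(mirna_values, index=mirnas, columns=samples)

    # mRNA expression: module latent factors + planted repression
    latents = rng.normal(0.0, 1.0, size=(cfg.n_modules, cfg.n_samples))
    mrna_values = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    modules: dict[str, int] = {}
    planted: set[tuple[str, str]] = set()
    for m in range(cfg.n_modules):
        block = range(m * cfg.module_size, (m + 1) * cfg.module_size)
        for gi in block:
            modules[genes[gi]] = m
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
            profile = latents[m] + noise
            if m < cfg.n_driver_mirnas:
                profile = profile - cfg.repression_effect * mirna_values[m]
                planted.add((mirnas[m], genes[gi]))
            mrna_values[gi] = profile
    mrna = pd.DataFrame(mrna_values, index=genes, columns=samples)

    # decoy Seq pairs: degree-coupled, no expression linkage
    degree = np.array([fpi.degree(g) for g in genes], dtype=float)
    weights = np.power(np.maximum(degree, 1.0), cfg.kappa)
    decoys: set[tuple[str, str]] = set()
    planted_targets = {m: {t for mm, t in planted if mm == m} for m in mirnas}
    for mirna_name in mirnas:
        excluded = planted_targets[mirna_name]
        mask = np.array([g not in excluded for g in genes])
        w = weights * mask
        w = w / w.sum()
        n_decoys = min(cfg.decoys_per_mirna, int(mask.sum()))
        chosen = rng.choice(cfg.n_genes, size=n_decoys, replace=False, p=w)
        decoys.update((mirna_name, genes[i]) for i in chosen)
    seq = TargetNetwork(planted | decoys)

    # survival: exponential with the planted group hazard ratio,
    # uniform administrative censoring
    rate = cfg.baseline_hazard * np.where(high, cfg.hazard_ratio, 1.0)
    true_time = rng.exponential(1.0 / rate)
    censor = rng.uniform(0.0, cfg.censor_horizon, size=cfg.n_samples)
    time = np.minimum(true_time, censor)
    event = (true_time <= censor).astype(int)
    annotations = pd.DataFrame(
        {"class": classes, "time": time, "event": event},
        index=pd.Index(samples, name="sample"),
    )

    truth = GroundTruth(
        drivers=drivers,
        planted_pairs=frozenset(planted),
        decoy_pairs=frozenset(decoys),
        modules=modules,
        risk_group=risk,
    )
    return SimulatedData(mrna, mirna, fpi, seq, annotations, truth)


def simulate_survival(
    n_samples: int = 140,
    hazard_ratio: float = 2.8,
    baseline_hazard: float = 0.02,
    censor_horizon: float = 60.0,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Standalone two-group exponential survival cohort.

    Returns the planted high/low risk labels and an annotation table
    with ``time``/``event`` (uniform administrative censoring, ~50%
    events at the defaults).  Used to calibrate hazard-ratio recovery
    independently of the expression generator.
    """
    rng = np.random.default_rng(seed)
    samples = pd.Index([f"S{i:03d}" for i in range(n_samples)], name="sample")
    high = rng.random(n_samples) < 0.5
    rate = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    true_time = rng.exponential(1.0 / rate)
    censor = rng.uniform(0.0, censor_horizon, size=n_samples)
    ann = pd.DataFrame(
        {
            "class": "primary",
            "time": np.minimum(true_time, censor),
            "event": (true_time <= censor).astype(int),
        },
        index=samples,
    )
    groups = pd.Series(np.where(high, "high", "low"), index=samples, name="group")
    return groups, ann


def write_fixture(sim: SimulatedData, directory, cfg: SimulationConfig | None = None) -> list[Path]:
    """Write the cohort to ``directory`` in the tool's external formats.

    Exactly the files in :data:`FIXTURE_FILES` are produced: the four
    pipeline inputs, sample annotations, the ground truth and the
    generator configuration.  Re-running with the same seed reproduces
    identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(sim.mrna, directory / "mrna.tsv")
    write_expression(sim.mirna, directory / "mirna.tsv")
    write_network(sim.fpi, directory / "fpi.tsv")
    write_targets(sim.seq, directory / "seq.tsv")
    write_annotations(sim.annotations, directory / "samples.tsv")

    truth = sim.truth
    with open(directory / "truth.tsv", "w") as fh:
        fh.write("kind\ta\tb\n")
        for m, t in sorted(truth.planted_pairs):
            fh.write(f"pair_planted\t{m}\t{t}\n")
        for m, t in sorted(truth.decoy_pairs):
            fh.write(f"pair_decoy\t{m}\t{t}\n")
        for d in truth.drivers:
            fh.write(f"driver\t{d}\t\n")
        for g in sorted(truth.modules):
            fh.write(f"module\t{g}\t{truth.modules[g]}\n")
        for s, r in truth.risk_group.items():
            fh.write(f"risk\t{s}\t{r}\n")

    payload = dataclasses.asdict(cfg) if cfg is not None else {}
    with open(directory / "config.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [directory / name for name in FIXTURE_FILES]
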