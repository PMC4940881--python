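"""Synthetic-data generators with planted ground truth for every pipeline input.

Four generators emulate the study's data modalities:

* :func:`simulate_factorial_expression` — a 2x2 factorial expression matrix
  (strain x copper, r replicates per cell) with per-gene log2-additive
  strain/copper/interaction effects and Gaussian replicate noise; each gene
  carries a planted response-group label the classifier should recover.
* :func:`simulate_interaction_network` — a connected random genetic-interaction
  network with a focal gene and an annotation term planted at elevated rate in
  one chosen BFS shell.
* :func:`simulate_regulons` — TF -> target maps with one regulator whose
  targets are over-represented in a query gene set at a chosen fraction.
* :func:`simulate_cq_table` — qPCR Cq tables whose ΔΔCq analysis recovers
  chosen fold changes exactly at zero jitter (the generator is the analytic
  inverse of 2^-ΔΔCq: a fold change FC shifts the deletant's Cq by -log2 FC).

All generators are deterministic given their seed; one global seed spawns
per-generator child streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    COPPER_LEVELS,
    DESIGN_CELLS,
    INTERACTION_TYPES,
    STRAINS,
    ExpressionMatrix,
)
from .errors import ConfigurationError
from .network import ShellDecomposition, bfs_shells, build_network

#: Planted classes and the sign pattern (a, b, c) of their log2 effects:
#: a = strain (deletant) effect, b = copper (high) effect, c = interaction.
#: None means a seed-dependent random sign.
CLASS_SIGNS: dict[str, tuple[int | None, int | None, int | None]] = {
    "NULL": (0, 0, 0),
    "G1": (None, 0, 0),
    "G2": (0, None, 0),
    "G3.1": (-1, +1, 0),
    "G3.2": (-1, -1, 0),
    "G3.3": (+1, +1, 0),
    "G3.4": (+1, -1, 0),
    "G4": (0, 0, None),
}

DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "NULL": 0.72,
    "G1": 0.05,
    "G2": 0.10,
    "G3.1": 0.02,
    "G3.2": 0.01,
    "G3.3": 0.01,
    "G3.4": 0.01,
    "G4": 0.08,
}


def child_seed(seed: int, tag: str) -> int:
    """Deterministic per-component child seed below 2**31."""
    return (int(seed) ^ zlib.crc32(tag.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# factorial expression
# ---------------------------------------------------------------------------


@dataclass
class FactorialSimSpec:
    """Conditions of the simulated 2x2 factorial transcriptome experiment."""

    n_genes: int = 1000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.25
    baseline_log2: float = 10.0
    replicates_per_cell: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        unknown = set(self.class_proportions) - set(CLASS_SIGNS)
        if unknown:
            raise ConfigurationError(f"unknown planted class(es): {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9 or min(self.class_proportions.values(), default=0) < 0:
            raise ConfigurationError(f"class proportions must be >= 0 and sum to 1 (got {total})")
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be >= 0")
        if self.effect_size_log2 <= 0:
            raise ConfigurationError("effect_size_log2 must be > 0")
        if self.replicates_per_cell < 2:
            raise ConfigurationError("replicates_per_cell must be >= 2 for ANOVA")


def simulate_factorial_expression(
    spec: FactorialSimSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a linear-scale expression matrix plus its planted truth table.

    Model per gene: log2 x = baseline + a*I[deletant] + b*I[high copper]
    + c*I[deletant]*I[high copper] + N(0, noise_sd); the emitted matrix is
    2**(log2 x). The truth table holds (planted_class, a, b, c) per gene.
    """
    spec.validate()
    rng = np.random.default_rng(child_seed(spec.seed, "factorial"))
    classes = sorted(spec.class_proportions)
    probs = np.array([spec.class_proportions[c] for c in classes], dtype=float)
    labels = rng.choice(classes, size=spec.n_genes, p=probs / probs.sum())

    e = spec.effect_size_log2
    effects = np.zeros((spec.n_genes, 3))
    for i, label in enumerate(labels):
        pattern = CLASS_SIGNS[label]
        effects[i] = [
            (rng.choice([-1, 1]) if s is None else s) * e if s != 0 else 0.0
            for s in pattern
        ]
    a, b, c = effects.T

    genes = [f"SIM{i:05d}" for i in range(spec.n_genes)]
    r = spec.replicates_per_cell
    columns, meta_rows = [], []
    blocks = []
    for strain, cu in DESIGN_CELLS:
        i_del = 1.0 if strain == "DEL" else 0.0
        i_hi = 1.0 if cu == "HIGH" else 0.0
        mean_log2 = spec.baseline_log2 + a * i_del + b * i_hi + c * i_del * i_hi
        noise = rng.normal(0.0, spec.noise_sd_log2, size=(spec.n_genes, r))
        blocks.append(mean_log2[:, None] + noise)
        for rep in range(1, r + 1):
            columns.append(f"{strain}_{cu}_{rep}")
            meta_rows.append({"strain": strain, "copper": cu, "replicate": rep})

    values = pd.DataFrame(
        2.0 ** np.concatenate(blocks, axis=1), index=genes, columns=columns
    )
    samples = pd.DataFrame(meta_rows, index=columns)
    truth = pd.DataFrame(
        {"planted_class": labels, "strain_effect": a, "copper_effect": b, "interaction_effect": c},
        index=genes,
    )
    return ExpressionMatrix(values, samples), truth


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------


@dataclass
class NetworkSimSpec:
    """Conditions of the simulated genetic-interaction network."""

    n_nodes: int = 500
    edge_density: float = 0.01
    focal_gene: str = "FOCAL"
    enriched_shell: int = 3
    annotation_rate_in_shell: float = 0.8
    annotation_rate_background: float = 0.1
    term: str = "planted process"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.annotation_rate_in_shell <= 1.0):
            raise ConfigurationError("annotation_rate_in_shell must be in [0, 1]")
        if not (0.0 <= self.annotation_rate_background <= 1.0):
            raise ConfigurationError("annotation_rate_background must be in [0, 1]")
        if self.enriched_shell < 1:
            raise ConfigurationError("enriched_shell must be >= 1")
        if self.n_nodes < self.enriched_shell + 1:
            raise ConfigurationError(
                f"n_nodes={self.n_nodes} cannot host a shell at distance {self.enriched_shell}"
            )


def simulate_interaction_network(
    spec: NetworkSimSpec,
    graph_override: nx.Graph | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]], ShellDecomposition]:
    """Simulate a connected typed interaction network with a planted shell term.

    The graph is Erdős–Rényi at ``edge_density``, repaired to connectivity
    with the minimum number of bridging edges (one per extra component).
    Nodes in the focal gene's shell at ``enriched_shell`` receive the
    annotation term with probability ``annotation_rate_in_shell``; all other
    non-focal nodes with ``annotation_rate_background``. ``graph_override``
    substitutes an explicit graph (its nodes are used as-is) for the random
    topology, e.g. a path graph in a worked example.
    """
    spec.validate()
    rng = np.random.default_rng(child_seed(spec.seed, "network"))

    if graph_override is not None:
        g = graph_override.copy()
        if spec.focal_gene not in g:
            raise ConfigurationError(f"focal gene {spec.focal_gene!r} absent from override graph")
    else:
        names = [spec.focal_gene] + [f"NODE{i:04d}" for i in range(1, spec.n_nodes)]
        g = nx.gnp_random_graph(spec.n_nodes, spec.edge_density, seed=int(rng.integers(2**31 - 1)))
        g = nx.relabel_nodes(g, dict(enumerate(names)))
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: c[0])
        for prev, nxt in zip(comps, comps[1:]):  # minimal bridging to connect
            g.add_edge(prev[int(rng.integers(len(prev)))], nxt[int(rng.integers(len(nxt)))])

    genetic_types = [t for t in INTERACTION_TYPES if t != "other"]
    records = [
        {
            "gene_a": a,
            "gene_b": b,
            "interaction_type": genetic_types[int(rng.integers(len(genetic_types)))],
            "system_type": "genetic",
        }
        for a, b in sorted(g.edges())
    ]
    edges = pd.DataFrame(records, columns=["gene_a", "gene_b", "interaction_type", "system_type"])

    shells = bfs_shells(build_network(edges) if records else g, spec.focal_gene)
    enriched = shells.shell(spec.enriched_shell)
    annotation: dict[str, set[str]] = {}
    for node in sorted(g.nodes):
        if node == spec.focal_gene:
            continue
        rate = (
            spec.annotation_rate_in_shell
            if node in enriched
            else spec.annotation_rate_background
        )
        if rng.random() < rate:
            annotation[node] = {spec.term}
    return edges, annotation, shells


# ---------------------------------------------------------------------------
# regulons
# ---------------------------------------------------------------------------


def simulate_regulons(
    n_tfs: int,
    n_genes: int,
    planted_tf: str = "TF000",
    planted_overlap: float = 0.5,
    seed: int = 0,
    regulon_size: int = 30,
    query_size: int = 50,
) -> tuple[dict[str, set[str]], set[str]]:
    """Simulate TF regulons plus a query set enriched for one TF's targets.

    Every TF regulates ``regulon_size`` genes drawn uniformly from the
    ``n_genes`` universe. The query contains ``round(planted_overlap *
    query_size)`` genes from the planted TF's regulon, the remainder drawn
    uniformly from the rest of the universe — at overlap 0 the query is a
    pure null draw.
    """
    if not (0.0 <= planted_overlap <= 1.0):
        raise ConfigurationError("planted_overlap must be in [0, 1]")
    tf_names = [f"TF{i:03d}" for i in range(n_tfs)]
    if planted_tf not in tf_names:
        raise ConfigurationError(f"planted TF {planted_tf!r} not among the {n_tfs} simulated TFs")
    if regulon_size > n_genes or query_size > n_genes:
        raise ConfigurationError("regulon_size and query_size must not exceed n_genes")

    rng = np.random.default_rng(child_seed(seed, "regulons"))
    genes = np.array([f"SIM{i:05d}" for i in range(n_genes)])
    regulons = {
        tf: set(rng.choice(genes, size=regulon_size, replace=False)) for tf in tf_names
    }

    n_planted = min(round(planted_overlap * query_size), regulon_size)
    planted_targets = sorted(regulons[planted_tf])
    query = set(rng.choice(planted_targets, size=n_planted, replace=False))
    rest = np.array(sorted(set(genes) - query))
    query |= set(rng.choice(rest, size=query_size - n_planted, replace=False))
    return regulons, query


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------


@dataclass
class CqSimSpec:
    """Conditions of the simulated qPCR experiment.

    ``target_fold_changes`` maps each target gene to the intended expression
    ratio deletant/reference per copper level, e.g.
    ``{"SIC1": {"DEFICIENT": 1/1.84, "HIGH": 1.0}}`` (a ratio below 1 is
    down-regulation in the deletant).
    """

    target_fold_changes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    housekeeping_genes: tuple[str, ...] = ("ARF1", "TDH3", "FBA1")
    cq_jitter_sd: float = 0.0
    base_cq: float = 20.0
    replicates: int = 2
    technical_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        for gene, per_cu in self.target_fold_changes.items():
            for cu, fc in per_cu.items():
                if cu not in COPPER_LEVELS:
                    raise ConfigurationError(f"{gene}: unknown copper level {cu!r}")
                if fc <= 0:
                    raise ConfigurationError(f"{gene}: fold change must be > 0 (got {fc})")
        if self.cq_jitter_sd < 0:
            raise ConfigurationError("cq_jitter_sd must be >= 0")
        if not self.housekeeping_genes:
            raise ConfigurationError("at least one housekeeping gene is required")
        if self.replicates < 1 or self.technical_replicates < 1:
            raise ConfigurationError("replicate counts must be >= 1")


def simulate_cq_table(spec: CqSimSpec) -> pd.DataFrame:
    """Simulate a Cq table whose ΔΔCq analysis recovers the intended ratios.

    Housekeeping genes sit at ``base_cq`` (plus a small fixed per-gene
    offset) in every condition; a target's reference-strain Cq is offset
    likewise, and its deletant Cq is shifted by -log2(FC) so that
    2^-ΔΔCq = FC exactly at zero jitter. Gaussian jitter of sd
    ``cq_jitter_sd`` is added to every measurement; emitted Cq values are
    clipped to the instrument range [0, 45].
    """
    spec.validate()
    rng = np.random.default_rng(child_seed(spec.seed, "qpcr"))
    genes = list(spec.housekeeping_genes) + sorted(spec.target_fold_changes)
    offsets = {g: 0.5 * i for i, g in enumerate(genes)}  # spread genes on the Cq axis

    rows = []
    for strain in STRAINS:
        for cu in COPPER_LEVELS:
            for rep in range(1, spec.replicates + 1):
                sample = f"{strain}_{cu}_{rep}"
                for gene in genes:
                    cq0 = spec.base_cq + offsets[gene]
                    if gene in spec.target_fold_changes and strain == "DEL":
                        fc = spec.target_fold_changes[gene].get(cu, 1.0)
                        cq0 -= np.log2(fc)
                    for tech in range(1, spec.technical_replicates + 1):
                        cq = cq0 + rng.normal(0.0, spec.cq_jitter_sd) if spec.cq_jitter_sd else cq0
                        rows.append(
                            {
                                "sample": sample,
                                "strain": strain,
                                "copper": cu,
                                "gene": gene.upper(),
                                "replicate": tech,
                                "cq": float(np.clip(cq, 0.0, 45.0)),
                            }
                        )
    return pd.DataFrame(rows, columns=["sample", "strain", "copper", "gene", "replicate", "cq"])
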