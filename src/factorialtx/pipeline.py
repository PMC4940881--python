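"""End-to-end pipeline orchestration.

Sequences the analysis stages over either simulated or file-based inputs:

    normalize -> ANOVA/fold-change -> classification -> SOM on the
    interaction group -> annotation enrichment per group -> genetic-network
    shells, paths and shell enrichment on the deletion-responsive genes
    (G1 u G3 u G4) -> TF-regulon enrichment -> optional qPCR quantification.

Every stage writes a TSV (with the thresholds used in a ``#`` header line);
a JSON manifest records the config echo, seed, package version and input
checksums, and a machine-readable summary collects group counts, shell sizes
and enrichment tables. Runs are byte-deterministic given config + seed; a
stage failure removes the partial bundle and re-raises with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, enrichment_table
from .errors import ConfigurationError, DataError, FactorialTxError
from .factorial import (
    classify_genes,
    compute_fold_changes,
    normalize_to_baseline,
    two_way_anova,
)
from .enrichment import enrich_annotation, enrich_tfs
from .io_formats import (
    read_biogrid_tab,
    read_cq_table,
    read_expression_table,
    read_gene_term_map,
    read_tf_target_table,
    write_cq_table,
    write_expression_table,
    write_gene_term_map,
    write_interaction_edges,
    write_tf_target_table,
)
from .network import (
    all_shortest_paths,
    bfs_shells,
    build_network,
    connected_component,
    induce_subnetwork,
    shell_enrichment,
    shell_table,
    write_sif,
)
from .qpcr import delta_delta_ct, qpcr_report
from .simulate import (
    CqSimSpec,
    FactorialSimSpec,
    NetworkSimSpec,
    child_seed,
    simulate_cq_table,
    simulate_factorial_expression,
    simulate_interaction_network,
    simulate_regulons,
)
from .som import som_cluster

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One reproducible pipeline run: inputs (files or simulation), thresholds."""

    # file inputs (each optional; simulation fills the gaps)
    expression_path: str | None = None
    metadata_path: str | None = None
    edges_path: str | None = None
    annotation_path: str | None = None
    tf_table_path: str | None = None
    cq_path: str | None = None

    # simulation specs used for inputs not supplied as files
    simulate_expression: bool = True
    factorial: dict = field(default_factory=dict)
    network_sim: dict = field(default_factory=dict)
    regulon_sim: dict = field(
        default_factory=lambda: {"n_tfs": 40, "n_genes": 1000, "planted_overlap": 0.0}
    )
    cq_sim: dict | None = None

    # thresholds (factorial gates, enrichment alphas)
    alpha: float = 0.05
    fc_threshold: float = 1.5
    g3_gate: str = "either"
    go_alpha: float = 0.05
    tf_alpha: float = 1e-4

    # SOM settings
    som_grid: tuple[int, int] = (2, 3)
    som_epochs: int = 500
    som_learning_rate: float = 0.5
    som_radius: float = 1.5

    # network stage
    focal_gene: str = "FOCAL"
    shell_term: str = "planted process"

    # qPCR stage
    qpcr_targets: list[str] = field(default_factory=list)
    qpcr_housekeeping: list[str] = field(default_factory=lambda: ["ARF1", "TDH3", "FBA1"])

    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name, value in (("alpha", self.alpha), ("go_alpha", self.go_alpha), ("tf_alpha", self.tf_alpha)):
            if not (0.0 < value < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1); got {value}")
        if self.fc_threshold < 1.0:
            raise ConfigurationError("fc_threshold must be >= 1")
        if not self.simulate_expression and self.expression_path is None:
            raise ConfigurationError("either an expression file or a simulation spec is required")
        for label, p in (
            ("expression", self.expression_path),
            ("metadata", self.metadata_path),
            ("edges", self.edges_path),
            ("annotation", self.annotation_path),
            ("tf_table", self.tf_table_path),
            ("cq", self.cq_path),
        ):
            if p is not None and not os.path.exists(p):
                raise DataError(f"{label} input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "som_grid" in raw:
            raw["som_grid"] = tuple(raw["som_grid"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["som_grid"] = list(self.som_grid)
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Bundle:
    """Tracks written outputs so a failed stage can clean up after itself."""

    def __init__(self, out_dir: Path, header: str):
        self.out_dir = out_dir
        self.header = header
        self.files: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.out_dir / name
        self.files.append(p)
        return p

    def write_tsv(self, frame: pd.DataFrame, name: str, index_label: str | None = None) -> None:
        p = self.path(name)
        with open(p, "w", newline="\n") as fh:
            fh.write(self.header)
            frame.to_csv(fh, sep="\t", index=index_label is not None,
                         index_label=index_label, lineterminator="\n")

    def write_json(self, obj: Any, name: str) -> None:
        p = self.path(name)
        with open(p, "w", newline="\n") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def discard(self) -> None:
        for p in self.files:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; return the machine-readable summary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# factorialtx {__version__} | alpha={config.alpha} "
        f"fc_threshold={config.fc_threshold} go_alpha={config.go_alpha} "
        f"tf_alpha={config.tf_alpha} seed={config.seed}\n"
    )
    bundle = _Bundle(out_dir, header)
    stage = "setup"
    summary: dict[str, Any] = {"seed": config.seed}
    try:
        # -- expression ------------------------------------------------------
        stage = "expression"
        truth = None
        if config.expression_path is not None:
            matrix, report = read_expression_table(config.expression_path, config.metadata_path)
            if report.clipped:
                log.info("sanitized %d expression value(s)", report.clipped)
        else:
            spec = FactorialSimSpec(**{"seed": config.seed, **config.factorial})
            matrix, truth = simulate_factorial_expression(spec)
            write_expression_table(
                matrix, bundle.path("expression.tsv"), bundle.path("expression_metadata.tsv")
            )
            bundle.write_tsv(truth, "truth.tsv", index_label="gene")

        stage = "normalize"
        matrix = normalize_to_baseline(matrix)

        # -- factorial DE ----------------------------------------------------
        stage = "anova"
        anova = two_way_anova(matrix)
        stage = "fold_change"
        fc = compute_fold_changes(matrix)
        stage = "classify"
        classification = classify_genes(
            anova, fc, alpha=config.alpha, fc_threshold=config.fc_threshold, g3_gate=config.g3_gate
        )
        genes_table = pd.concat([anova, fc, classification.table], axis=1)
        summary["group_counts"] = classification.counts()

        # -- SOM on interaction-effect genes ---------------------------------
        stage = "som"
        g4 = classification.genes_in("G4")
        if len(g4) >= config.som_grid[0] * config.som_grid[1]:
            profiles = matrix.subset_genes(g4).cell_means(log2=True)
            som = som_cluster(
                profiles,
                grid=config.som_grid,
                epochs=config.som_epochs,
                learning_rate=config.som_learning_rate,
                radius=config.som_radius,
                seed=child_seed(config.seed, "som"),
            )
            genes_table["cluster"] = som.labels.reindex(genes_table.index)
            bundle.write_tsv(som.centroids, "som_centroids.tsv", index_label="cluster")
            summary["som_cluster_sizes"] = som.labels.value_counts().sort_index().to_dict()
        else:
            genes_table["cluster"] = pd.Series(dtype="float64")
            summary["som_cluster_sizes"] = {}
        bundle.write_tsv(genes_table, "genes.tsv", index_label="gene")

        # -- annotation enrichment per group ---------------------------------
        stage = "annotation_enrichment"
        annotation = (
            read_gene_term_map(config.annotation_path) if config.annotation_path else None
        )
        universe = set(matrix.gene_ids)
        go_tables = []
        if annotation:
            for group in ("G1", "G2", "G3.1", "G3.2", "G3.3", "G3.4", "G4"):
                members = classification.genes_in(group)
                if not members:
                    continue
                results = enrich_annotation(
                    members, annotation, universe, correction="none", alpha=config.go_alpha
                )
                t = enrichment_table(results)
                t.insert(0, "group", group)
                go_tables.append(t)
        go_all = (
            pd.concat(go_tables, ignore_index=True)
            if go_tables
            else pd.DataFrame(columns=["group", "term", "k", "n", "K", "N", "p", "p_adj", "significant"])
        )
        bundle.write_tsv(go_all, "go_enrichment.tsv")
        summary["go_significant"] = int(go_all["significant"].sum()) if len(go_all) else 0

        # -- genetic-interaction network -------------------------------------
        stage = "network"
        responsive = classification.genes_in("G1", "G3.1", "G3.2", "G3.3", "G3.4", "G4")
        if config.edges_path is not None:
            edges = read_biogrid_tab(config.edges_path, genetic_only=True)
            net_annotation = annotation or {}
            shell_term = config.shell_term
            network = build_network(edges)
            network = induce_subnetwork(network, set(responsive) | {config.focal_gene})
        else:
            net_spec = NetworkSimSpec(**{"seed": config.seed, "focal_gene": config.focal_gene,
                                         **config.network_sim})
            edges, net_annotation, _ = simulate_interaction_network(net_spec)
            shell_term = net_spec.term
            write_interaction_edges(edges, bundle.path("network_edges.tsv"))
            write_gene_term_map(net_annotation, bundle.path("network_annotation.tsv"))
            network = build_network(edges)

        if config.focal_gene in network:
            component = connected_component(network, config.focal_gene)
            write_sif(component, bundle.path("network.sif"))
            shells = bfs_shells(component, config.focal_gene)
            bundle.write_tsv(shell_table(shells), "network_shells.tsv")
            summary["shell_sizes"] = {d: len(s) for d, s in sorted(shells.shells.items())}
            summary["eccentricity"] = shells.eccentricity

            if shells.eccentricity > 0:
                farthest = min(shells.shell(shells.eccentricity))
                paths = all_shortest_paths(component, config.focal_gene, farthest)
                path_frame = pd.DataFrame(
                    {"path": [" -> ".join(p) for p in paths.paths]}
                )
                path_frame.insert(0, "length", paths.length)
                bundle.write_tsv(path_frame, "network_paths.tsv")
                summary["paths_to_farthest"] = {
                    "target": farthest, "length": paths.length,
                    "count": len(paths.paths), "truncated": paths.truncated,
                }

            background = set(component.nodes) - {config.focal_gene}
            shell_rows = []
            for d in sorted(shells.shells):
                res = shell_enrichment(
                    shells.shell(d), background, net_annotation, shell_term, alpha=config.go_alpha
                )
                shell_rows.append(
                    {"distance": d, "term": res.term, "k": res.k, "n": res.n,
                     "K": res.K, "N": res.N, "p": res.p, "significant": res.significant}
                )
            shell_enrich = pd.DataFrame(shell_rows)
            bundle.write_tsv(shell_enrich, "shell_enrichment.tsv")
            summary["shell_enrichment"] = {
                int(r["distance"]): float(r["p"]) for _, r in shell_enrich.iterrows()
            }
        else:
            summary["shell_sizes"] = {}
            log.warning("focal gene %s not in the network; shell stage skipped", config.focal_gene)

        # -- TF-regulon enrichment -------------------------------------------
        stage = "tf_enrichment"
        if config.tf_table_path is not None:
            regulons = read_tf_target_table(config.tf_table_path, documented_only=True)
        else:
            regulons, _ = simulate_regulons(
                seed=child_seed(config.seed, "tf"), **config.regulon_sim
            )
            write_tf_target_table(regulons, bundle.path("tf_targets.tsv"))
        regulated = set().union(*regulons.values()) if regulons else set()
        query = set(responsive) & regulated
        if query:
            tf_results = enrich_tfs(query, regulons, universe=universe, alpha=config.tf_alpha)
            tf_table = enrichment_table(tf_results)
        else:
            tf_table = pd.DataFrame(columns=["term", "k", "n", "K", "N", "p", "p_adj", "significant"])
        bundle.write_tsv(tf_table, "tf_enrichment.tsv")
        summary["tf_significant"] = int(tf_table["significant"].sum()) if len(tf_table) else 0

        # -- qPCR -------------------------------------------------------------
        stage = "qpcr"
        cq = None
        if config.cq_path is not None:
            cq = read_cq_table(config.cq_path)
        elif config.cq_sim is not None:
            cq_spec = CqSimSpec(**{"seed": config.seed, **config.cq_sim})
            cq = simulate_cq_table(cq_spec)
            write_cq_table(cq, bundle.path("cq.csv"))
        if cq is not None:
            targets = config.qpcr_targets or sorted(
                set(cq["gene"]) - {h.upper() for h in config.qpcr_housekeeping}
            )
            results = []
            for gene in targets:
                for cu in ("DEFICIENT", "HIGH"):
                    results.append(
                        delta_delta_ct(
                            cq, gene, config.qpcr_housekeeping,
                            (("DEL", cu), ("REF", cu)),
                        )
                    )
            report = qpcr_report(results)
            bundle.write_tsv(report, "qpcr.tsv")
            summary["qpcr"] = {
                f"{r.gene}@{r.condition_a[1]}": r.fold_change for r in results
            }

        # -- manifest ----------------------------------------------------------
        stage = "manifest"
        checksums = {
            label: _sha256(p)
            for label, p in (
                ("expression", config.expression_path),
                ("metadata", config.metadata_path),
                ("edges", config.edges_path),
                ("annotation", config.annotation_path),
                ("tf_table", config.tf_table_path),
                ("cq", config.cq_path),
            )
            if p is not None
        }
        if truth is not None:
            planted = truth["planted_class"]
            observed = classification.table["group"]
            non_null = planted != "NULL"
            summary["planted_recovery"] = float(
                (observed[non_null] == planted[non_null]).mean()
            ) if non_null.any() else None
        bundle.write_json(summary, "summary.json")
        bundle.write_json(
            {"config": config.echo(), "version": __version__, "seed": config.seed,
             "input_checksums": checksums},
            "manifest.json",
        )
        return summary
    except FactorialTxError as exc:
        bundle.discard()
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    except Exception as exc:  # unexpected: still clean up partial outputs
        bundle.discard()
        raise FactorialTxError(f"stage {stage!r} failed: {exc}") from exc
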