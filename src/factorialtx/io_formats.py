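"""Readers and writers for every external format the pipeline touches.

Formats
-------
* expression TSV (gene-id first column, one column per sample) with factorial
  metadata either as a sidecar TSV or encoded in sample names ``STRAIN_COPPER_REP``
* BioGRID TAB 2.0 / 3.0 genetic-interaction tables (header-based dialect
  detection, column order independent)
* two-column gene -> annotation-term TSV
* Yeastract-style TF -> target table with a documented-evidence flag
* qPCR Cq CSV with columns (sample, strain, copper, gene, replicate, cq)

All gene identifiers are normalized to uppercase on input so that matching
across sources is exact. Readers tolerate CRLF line endings and trailing
whitespace; writers are bit-stable given fixed inputs.
"""

from __future__ import annotations

import csv
import io
import os
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    COPPER_LEVELS,
    EXPRESSION_EPSILON,
    INTERACTION_TYPES,
    STRAINS,
    ExpressionMatrix,
    SanitizationReport,
    normalize_gene_id,
)
from .errors import DataError

# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


def _parse_sample_name(sample: str) -> dict:
    parts = sample.strip().split("_")
    if len(parts) != 3 or parts[0] not in STRAINS or parts[1] not in COPPER_LEVELS:
        raise DataError(
            f"sample {sample!r} has no metadata: expected sidecar metadata or "
            "a STRAIN_COPPER_REP sample name (e.g. DEL_HIGH_1)"
        )
    try:
        rep = int(parts[2])
    except ValueError as exc:
        raise DataError(f"sample {sample!r}: replicate field is not an integer") from exc
    return {"strain": parts[0], "copper": parts[1], "replicate": rep}


def read_expression_table(
    path: str | os.PathLike,
    metadata_path: str | os.PathLike | None = None,
) -> tuple[ExpressionMatrix, SanitizationReport]:
    """Read a linear-scale expression TSV plus factorial sample metadata.

    Values <= ``EXPRESSION_EPSILON`` (including negatives, possible in
    model-based array summaries) are clipped to the epsilon and counted in the
    returned :class:`SanitizationReport`.
    """
    try:
        table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except ValueError as exc:
        raise DataError(f"cannot parse expression table {path}: {exc}") from exc
    table.index = [normalize_gene_id(g) for g in table.index]
    table.columns = [str(c).strip() for c in table.columns]
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique()
        raise DataError(f"duplicate gene ids in {path}: {list(dupes)[:5]}")

    for col in table.columns:
        if not np.issubdtype(table[col].dtype, np.number):
            bad = table[col][pd.to_numeric(table[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise DataError(f"non-numeric expression value at gene {row}, sample {col}")
    if table.isna().to_numpy().any():
        rows, cols = np.nonzero(table.isna().to_numpy())
        raise DataError(
            f"missing expression value at gene {table.index[rows[0]]}, "
            f"sample {table.columns[cols[0]]}"
        )

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", comment="#")
        required = {"sample", "strain", "copper", "replicate"}
        if not required.issubset(meta.columns):
            raise DataError(
                f"metadata {metadata_path} lacks columns {sorted(required - set(meta.columns))}"
            )
        meta["sample"] = meta["sample"].astype(str).str.strip()
        meta = meta.set_index("sample")
        missing = [s for s in table.columns if s not in meta.index]
        if missing:
            raise DataError(f"no metadata for sample(s): {missing}")
        meta = meta.loc[list(table.columns), ["strain", "copper", "replicate"]]
        meta["strain"] = meta["strain"].str.strip().str.upper()
        meta["copper"] = meta["copper"].str.strip().str.upper()
        meta.index.name = None
    else:
        meta = pd.DataFrame(
            [_parse_sample_name(s) for s in table.columns], index=list(table.columns)
        )

    report = SanitizationReport()
    arr = table.to_numpy(dtype=float)
    low = arr < EXPRESSION_EPSILON
    report.clipped = int(low.sum())
    if report.clipped:
        report.details.append(
            f"{report.clipped} value(s) < {EXPRESSION_EPSILON} clipped to {EXPRESSION_EPSILON}"
        )
        arr = np.where(low, EXPRESSION_EPSILON, arr)
    clean = pd.DataFrame(arr, index=table.index, columns=table.columns)
    return ExpressionMatrix(clean, meta), report


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    metadata_path: str | os.PathLike | None = None,
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")
    if metadata_path is not None:
        meta = matrix.samples.copy()
        meta.index.name = "sample"
        meta.to_csv(metadata_path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# BioGRID genetic-interaction tables
# ---------------------------------------------------------------------------

#: Experimental-system strings mapped onto the controlled edge-type vocabulary.
_SYSTEM_MAP = {
    "negative genetic": "negative genetic",
    "positive genetic": "positive genetic",
    "synthetic lethality": "synthetic lethal",
    "synthetic lethal": "synthetic lethal",
    "synthetic growth defect": "synthetic growth defect",
    "dosage lethality": "dosage lethality",
    "synthetic rescue": "synthetic rescue",
}

_BIOGRID_COLUMN_ALIASES = {
    "symbol_a": ["official symbol interactor a"],
    "symbol_b": ["official symbol interactor b"],
    "systematic_a": ["systematic name interactor a"],
    "systematic_b": ["systematic name interactor b"],
    "system": ["experimental system"],
    "system_type": ["experimental system type"],
    "organism_a": ["organism interactor a", "organism id interactor a", "organism name interactor a"],
    "organism_b": ["organism interactor b", "organism id interactor b", "organism name interactor b"],
}


def map_experimental_system(system: str) -> str:
    """Fold a BioGRID experimental-system string onto the edge-type vocabulary."""
    return _SYSTEM_MAP.get(str(system).strip().lower(), "other")


def read_biogrid_tab(
    path: str | os.PathLike,
    organism_filter: str | int | None = None,
    genetic_only: bool = True,
) -> pd.DataFrame:
    """Read a BioGRID TAB 2.0/3.0 file into an interaction edge list.

    Returns a DataFrame with columns ``gene_a, gene_b, interaction_type,
    system_type``. Systematic names are preferred over official symbols when
    present ("-" counts as absent). Rows failing the organism or genetic-only
    filter are dropped; unknown experimental systems map to ``"other"``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {str(c).strip().lstrip("#").strip().lower(): c for c in table.columns}

    def find(key: str, required: bool = True) -> str | None:
        for alias in _BIOGRID_COLUMN_ALIASES[key]:
            if alias in lower:
                return lower[alias]
        if required:
            raise DataError(
                f"{path}: missing BioGRID column for {key!r}; expected one of "
                f"{_BIOGRID_COLUMN_ALIASES[key]} (TAB 2.0/3.0 dialects)"
            )
        return None

    sym_a, sym_b = find("symbol_a"), find("symbol_b")
    sys_a, sys_b = find("systematic_a", required=False), find("systematic_b", required=False)
    system_col = find("system")
    type_col = find("system_type")
    org_a, org_b = find("organism_a", required=False), find("organism_b", required=False)

    def gene(row: pd.Series, systematic: str | None, symbol: str) -> str:
        if systematic is not None:
            name = str(row[systematic]).strip()
            if name and name != "-":
                return normalize_gene_id(name)
        return normalize_gene_id(row[symbol])

    records = []
    for _, row in table.iterrows():
        if genetic_only and str(row[type_col]).strip().lower() != "genetic":
            continue
        if organism_filter is not None and org_a is not None and org_b is not None:
            wanted = str(organism_filter).strip().lower()
            if (
                str(row[org_a]).strip().lower() != wanted
                or str(row[org_b]).strip().lower() != wanted
            ):
                continue
        a, b = gene(row, sys_a, sym_a), gene(row, sys_b, sym_b)
        if not a or not b:
            raise DataError(f"{path}: empty gene symbol in row {_}")
        records.append(
            {
                "gene_a": a,
                "gene_b": b,
                "interaction_type": map_experimental_system(row[system_col]),
                "system_type": str(row[type_col]).strip().lower(),
            }
        )
    return pd.DataFrame(
        records, columns=["gene_a", "gene_b", "interaction_type", "system_type"]
    )


def write_interaction_edges(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an edge list back out in a minimal BioGRID TAB 2.0 dialect."""
    out = pd.DataFrame(
        {
            "Official Symbol Interactor A": edges["gene_a"],
            "Official Symbol Interactor B": edges["gene_b"],
            "Experimental System": edges["interaction_type"].str.title(),
            "Experimental System Type": edges["system_type"],
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# annotation map, regulon map, Cq table
# ---------------------------------------------------------------------------


def read_gene_term_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column (gene, term) TSV into gene -> set-of-terms.

    Genes with no (non-empty) term never appear in the map.
    """
    mapping: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").rstrip(" ")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:  # a trailing tab (empty term set) is acceptable
                raise DataError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            gene, term = normalize_gene_id(parts[0]), parts[1].strip()
            if not gene:
                raise DataError(f"{path}:{lineno}: empty gene id")
            if term:
                mapping.setdefault(gene, set()).add(term)
    return mapping


def write_gene_term_map(mapping: Mapping[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for gene in sorted(mapping):
            for term in sorted(mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_tf_target_table(
    path: str | os.PathLike, documented_only: bool = True
) -> dict[str, set[str]]:
    """Read a Yeastract-style TF -> target TSV into TF -> set-of-targets.

    Columns: tf, target, evidence. With ``documented_only`` only pairs whose
    evidence field is "documented" (case-insensitive) are retained.
    """
    regulons: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").rstrip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("tf"):
                continue
            parts = [p.strip() for p in (line.split("\t") if "\t" in line else line.split(";"))]
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected 'tf<TAB>target<TAB>evidence'")
            tf, target, evidence = normalize_gene_id(parts[0]), normalize_gene_id(parts[1]), parts[2]
            if not tf or not target:
                raise DataError(f"{path}:{lineno}: empty TF or target id")
            if documented_only and evidence.strip().lower() != "documented":
                continue
            regulons.setdefault(tf, set()).add(target)
    return regulons


def write_tf_target_table(
    regulons: Mapping[str, set[str]], path: str | os.PathLike, evidence: str = "documented"
) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("tf\ttarget\tevidence\n")
        for tf in sorted(regulons):
            for target in sorted(regulons[tf]):
                fh.write(f"{tf}\t{target}\t{evidence}\n")


CQ_COLUMNS = ["sample", "strain", "copper", "gene", "replicate", "cq"]


def read_cq_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a qPCR Cq CSV; every Cq must lie in [0, 45] cycles."""
    table = pd.read_csv(path)
    table.columns = [str(c).strip().lower() for c in table.columns]
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing Cq column(s) {missing}")
    table = table[CQ_COLUMNS].copy()
    table["gene"] = table["gene"].map(normalize_gene_id)
    table["strain"] = table["strain"].astype(str).str.strip().str.upper()
    table["copper"] = table["copper"].astype(str).str.strip().str.upper()
    table["cq"] = pd.to_numeric(table["cq"], errors="coerce")
    bad = table.index[table["cq"].isna() | (table["cq"] < 0) | (table["cq"] > 45)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise DataError(f"{path}: Cq outside [0, 45] or non-numeric at line {bad[0] + 2}")
    return table


def write_cq_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table[CQ_COLUMNS].to_csv(path, index=False, lineterminator="\n")
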