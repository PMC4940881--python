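"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`: a linear-scale gene x sample
expression table together with the factorial sample metadata (strain:
reference vs deletant; copper: deficient vs high; replicate index). All
downstream statistics (two-way ANOVA, fold changes, classification, SOM
profiles) are derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

#: Factor levels of the 2x2 design, in canonical order.
STRAINS = ("REF", "DEL")
COPPER_LEVELS = ("DEFICIENT", "HIGH")

#: Canonical design-cell order used for profiles and centroids.
DESIGN_CELLS = (
    ("REF", "DEFICIENT"),
    ("REF", "HIGH"),
    ("DEL", "DEFICIENT"),
    ("DEL", "HIGH"),
)

#: Controlled vocabulary for genetic-interaction edge types.
INTERACTION_TYPES = (
    "negative genetic",
    "positive genetic",
    "synthetic lethal",
    "synthetic growth defect",
    "dosage lethality",
    "synthetic rescue",
    "other",
)

#: Minimum linear expression value; smaller/non-positive values are clipped.
EXPRESSION_EPSILON = 1.0


@dataclass
class ExpressionMatrix:
    """Linear-scale expression values with factorial sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); index = uppercase gene ids,
        columns = sample ids, entries strictly positive linear intensities.
    samples
        DataFrame indexed by sample id with columns ``strain`` (REF/DEL),
        ``copper`` (DEFICIENT/HIGH) and ``replicate`` (int).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise DataError(f"duplicate gene ids: {list(dupes)[:5]}")
        if list(self.values.columns) != list(self.samples.index):
            missing = set(self.values.columns) ^ set(self.samples.index)
            raise DataError(
                f"sample metadata does not match matrix columns; mismatched: {sorted(missing)}"
            )
        bad_strain = set(self.samples["strain"]) - set(STRAINS)
        bad_copper = set(self.samples["copper"]) - set(COPPER_LEVELS)
        if bad_strain or bad_copper:
            raise DataError(
                f"unknown factor levels: strain={sorted(bad_strain)} copper={sorted(bad_copper)}"
            )
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise DataError("expression values must be numeric")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def cell_samples(self) -> dict[tuple[str, str], list[str]]:
        """Map (strain, copper) -> list of sample ids, in canonical cell order."""
        out: dict[tuple[str, str], list[str]] = {cell: [] for cell in DESIGN_CELLS}
        for sid, row in self.samples.iterrows():
            out[(row["strain"], row["copper"])].append(sid)
        return out

    def require_balanced(self, min_replicates: int = 2) -> int:
        """Check the 2x2 design is balanced; return the per-cell replicate count."""
        counts = {cell: len(s) for cell, s in self.cell_samples().items()}
        n = set(counts.values())
        if len(n) != 1 or min(n) < min_replicates:
            raise DataError(f"unbalanced or under-replicated 2x2 design: {counts}")
        return n.pop()

    def cell_means(self, log2: bool = False) -> pd.DataFrame:
        """Per-gene mean of each design cell (genes x 4, canonical cell order).

        With ``log2=True`` means are taken on the log2 scale (for ANOVA and
        SOM profiles); otherwise on the linear scale (for fold changes).
        """
        data = np.log2(self.values) if log2 else self.values
        cols = {}
        for (strain, cu), sids in self.cell_samples().items():
            cols[f"{strain}_{cu}"] = data[sids].mean(axis=1)
        return pd.DataFrame(cols, index=self.values.index)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.samples)


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric over-representation test.

    k of n sampled genes carry the term; K of N population genes carry it.
    ``p`` is the exact upper-tail probability P(X >= k); ``p_adj`` the
    multiplicity-corrected value.
    """

    term: str
    k: int
    n: int
    K: int
    N: int
    p: float
    p_adj: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise DataError(f"inconsistent counts for {self.term}: k={self.k} n={self.n} K={self.K}")
        if self.p_adj + 1e-15 < self.p:
            raise DataError(f"corrected p below raw p for {self.term}")


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (term, k/n, K/N, p, p_adj, significant)."""
    rows = [
        {
            "term": r.term,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "p": r.p,
            "p_adj": r.p_adj,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p", "p_adj", "significant"]
    )


@dataclass
class SanitizationReport:
    """Counts of values adjusted while reading an expression table."""

    clipped: int = 0
    details: list[str] = field(default_factory=list)


def normalize_gene_id(gene: str) -> str:
    """Uppercase and strip a gene identifier (yeast ORF/symbol convention)."""
    return str(gene).strip().upper()
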