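"""RT-qPCR relative quantification: housekeeping stability ranking and the
2^-ΔΔCq method.

Normalization follows the comparative-Ct convention: the target gene's Cq is
referenced to the geometric mean of the Cq values of a small housekeeping
panel, within each condition; the fold change between two conditions A and B
is 2^-(ΔCq_A - ΔCq_B), with condition A as numerator. Technical replicates
are averaged arithmetically on the Cq scale before any Δ computation, and
biological samples within a condition are pooled mean-of-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import DataError

#: A qPCR condition is a (strain, copper) pair, e.g. ("DEL", "DEFICIENT").
Condition = tuple[str, str]


@dataclass(frozen=True)
class QpcrFoldChange:
    """2^-ΔΔCq fold change of one target gene for one condition contrast."""

    gene: str
    condition_a: Condition
    condition_b: Condition
    delta_cq_a: float
    delta_cq_b: float
    delta_delta_cq: float
    fold_change: float          # 2^-ΔΔCq, condition A as numerator

    @property
    def magnitude(self) -> float:
        """Fold change folded to >= 1 (the scale papers print)."""
        return max(self.fold_change, 1.0 / self.fold_change)

    @property
    def direction(self) -> str:
        if self.fold_change > 1:
            return "up"
        if self.fold_change < 1:
            return "down"
        return "none"


def rank_housekeeping_stability(
    matrix: ExpressionMatrix, candidates
) -> pd.DataFrame:
    """Rank candidate housekeeping genes by expression stability.

    Stability score is the coefficient of variation (sd/mean) of linear
    expression across all arrays; lower is stabler. Returns a DataFrame
    sorted ascending by score, ties broken lexicographically by gene id.
    """
    candidates = [c.upper() for c in candidates]
    missing = [c for c in candidates if c not in matrix.values.index]
    if missing:
        raise DataError(f"housekeeping candidate(s) absent from matrix: {missing}")
    values = matrix.values.loc[candidates]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    cv = (sd / mean).rename("cv")
    out = cv.reset_index().rename(columns={"index": "gene"})
    out = out.sort_values(["cv", "gene"], kind="stable").reset_index(drop=True)
    out.index = pd.RangeIndex(1, len(out) + 1, name="rank")
    return out


def _condition_cq(cq: pd.DataFrame, gene: str, condition: Condition) -> float:
    """Mean Cq of a gene in one condition (technical reps first, then samples)."""
    strain, copper = condition
    rows = cq[(cq["gene"] == gene) & (cq["strain"] == strain) & (cq["copper"] == copper)]
    if rows.empty:
        raise DataError(f"no Cq measurement for gene {gene} in condition {condition}")
    per_sample = rows.groupby("sample")["cq"].mean()
    return float(per_sample.mean())


def delta_delta_ct(
    cq: pd.DataFrame,
    target_gene: str,
    housekeeping,
    contrast: tuple[Condition, Condition],
) -> QpcrFoldChange:
    """2^-ΔΔCq fold change of ``target_gene`` between two conditions.

    ``contrast`` is (A, B); the returned fold change has A as numerator.
    ΔCq(cond) = Cq_target(cond) - geometric_mean(Cq of housekeeping genes in
    cond); ΔΔCq = ΔCq(A) - ΔCq(B); FC = 2^-ΔΔCq.
    """
    target_gene = target_gene.upper()
    housekeeping = [h.upper() for h in housekeeping]
    if not housekeeping:
        raise DataError("at least one housekeeping gene is required")
    cond_a, cond_b = contrast

    def delta(cond: Condition) -> float:
        target_cq = _condition_cq(cq, target_gene, cond)
        hk = np.array([_condition_cq(cq, h, cond) for h in housekeeping])
        if (hk <= 0).any():
            bad = housekeeping[int(np.argmax(hk <= 0))]
            raise DataError(f"non-positive Cq for housekeeping gene {bad} in {cond}")
        geo = float(np.exp(np.mean(np.log(hk))))
        return target_cq - geo

    d_a, d_b = delta(cond_a), delta(cond_b)
    ddcq = d_a - d_b
    return QpcrFoldChange(
        gene=target_gene,
        condition_a=cond_a,
        condition_b=cond_b,
        delta_cq_a=d_a,
        delta_cq_b=d_b,
        delta_delta_cq=ddcq,
        fold_change=float(2.0 ** (-ddcq)),
    )


def qpcr_report(results) -> pd.DataFrame:
    """Tabulate ΔΔCq results (gene, contrast, ΔCq's, ΔΔCq, FC, direction)."""
    rows = [
        {
            "gene": r.gene,
            "condition_a": "_".join(r.condition_a),
            "condition_b": "_".join(r.condition_b),
            "delta_cq_a": r.delta_cq_a,
            "delta_cq_b": r.delta_cq_b,
            "delta_delta_cq": r.delta_delta_cq,
            "fold_change": r.fold_change,
            "magnitude": r.magnitude,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
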