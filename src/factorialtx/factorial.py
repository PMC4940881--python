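"""Factorial differential expression: baseline normalization, per-gene two-way
ANOVA, fold-change contrasts and response-group classification.

The experiment is a balanced 2x2 factorial: strain (reference vs deletant)
crossed with copper level (deficient vs high), r >= 2 replicate arrays per
cell. Genes are partitioned into response groups:

* G1 — significant strain main effect only, with a qualifying deletion fold
  change;
* G2 — significant copper main effect only, with a qualifying copper fold
  change;
* G3 — both main effects significant without interaction (additive), split
  into directional subgroups G3.1 (deletion down / copper up), G3.2
  (down/down), G3.3 (up/up), G3.4 (up/down);
* G4 — significant strain x copper interaction with any qualifying fold
  change;
* NS — everything else.

ANOVA is computed on log2 intensities (variance stabilization); fold changes
are ratios of linear-scale cell means, reported as magnitude >= 1 plus
direction, matching how array fold changes are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DESIGN_CELLS, ExpressionMatrix
from .errors import DataError

GROUPS = ("G1", "G2", "G3.1", "G3.2", "G3.3", "G3.4", "G4", "NS")

#: Zero-variance guard for sums of squares on the log2 scale.
_SS_TOL = 1e-12


# ---------------------------------------------------------------------------
# baseline normalization
# ---------------------------------------------------------------------------


def normalize_to_baseline(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-scale every array to a baseline array of median overall intensity.

    The baseline is the sample whose overall median intensity is the median
    across samples (the lower of the two middle samples when the count is
    even); every other sample is rescaled multiplicatively so its median
    matches the baseline's.
    """
    if matrix.values.shape[1] < 2:
        raise DataError("baseline normalization needs at least 2 samples")
    medians = matrix.values.median(axis=0)
    if (medians <= 0).any():
        bad = medians.index[medians <= 0][0]
        raise DataError(f"sample {bad} has non-positive median intensity")
    order = medians.sort_values(kind="stable").index
    baseline = order[(len(order) - 1) // 2]  # lower middle on even counts
    factors = medians[baseline] / medians
    scaled = matrix.values * factors
    return ExpressionMatrix(scaled, matrix.samples.copy())


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------


def _cell_array(matrix: ExpressionMatrix) -> tuple[np.ndarray, int]:
    """Log2 data as (genes, 2 strains, 2 copper, r) in canonical level order."""
    r = matrix.require_balanced()
    cells = matrix.cell_samples()
    data = np.empty((matrix.n_genes, 2, 2, r))
    log2 = np.log2(matrix.values.to_numpy(dtype=float))
    col_pos = {s: i for i, s in enumerate(matrix.values.columns)}
    for ci, (strain, cu) in enumerate(DESIGN_CELLS):
        idx = [col_pos[s] for s in cells[(strain, cu)]]
        data[:, ci // 2, ci % 2, :] = log2[:, idx]
    return data, r


def two_way_anova(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene fixed-effects 2x2 ANOVA on log2 expression.

    Returns a DataFrame indexed by gene with F and p for the strain and
    copper main effects and their interaction, the error degrees of freedom,
    and a ``degenerate`` flag for genes with zero within-cell variance
    (their p-values are 0 for effects with positive sum of squares and 1
    otherwise, since the F statistic is unbounded).
    """
    data, r = _cell_array(matrix)
    cell_means = data.mean(axis=3)                      # (G, 2, 2)
    strain_means = cell_means.mean(axis=2)              # (G, 2)
    copper_means = cell_means.mean(axis=1)              # (G, 2)
    grand = cell_means.mean(axis=(1, 2))                # (G,)

    ss_strain = 2 * r * ((strain_means - grand[:, None]) ** 2).sum(axis=1)
    ss_copper = 2 * r * ((copper_means - grand[:, None]) ** 2).sum(axis=1)
    interaction = (
        cell_means
        - strain_means[:, :, None]
        - copper_means[:, None, :]
        + grand[:, None, None]
    )
    ss_inter = r * (interaction ** 2).sum(axis=(1, 2))
    ss_error = ((data - cell_means[..., None]) ** 2).sum(axis=(1, 2, 3))

    df_error = 4 * (r - 1)
    ms_error = ss_error / df_error
    degenerate = ss_error <= _SS_TOL

    safe_ms = np.where(degenerate, 1.0, ms_error)
    out = {}
    for name, ss in (("strain", ss_strain), ("copper", ss_copper), ("interaction", ss_inter)):
        F = ss / safe_ms
        p = stats.f.sf(F, 1, df_error)
        # zero residual variance: F is unbounded, so an effect with positive
        # sum of squares is maximally significant and a flat gene is not
        F = np.where(degenerate, np.where(ss > _SS_TOL, np.inf, 0.0), F)
        p = np.where(degenerate, np.where(ss > _SS_TOL, 0.0, 1.0), p)
        out[f"F_{name}"] = F
        out[f"p_{name}"] = p
    result = pd.DataFrame(out, index=matrix.values.index)
    result["df_effect"] = 1
    result["df_error"] = df_error
    result["degenerate"] = degenerate
    return result


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

#: Contrast names: deletant vs reference at each copper level, then
#: high vs deficient copper within each strain.
FC_CONTRASTS = ("del_deficient", "del_high", "cu_ref", "cu_del")


def _fc(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ratio = num / den
    magnitude = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio > 1, "up", np.where(ratio < 1, "down", "none"))
    return magnitude, direction


def compute_fold_changes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Four factorial contrasts as (magnitude >= 1, direction) per gene.

    Contrasts are ratios of linear-scale cell means pooled over replicates:
    deletant/reference at each copper level (numerator = deletant) and
    high/deficient copper within each strain (numerator = high copper).
    """
    means = matrix.cell_means(log2=False)
    if (means.to_numpy() <= 0).any():
        raise DataError("non-positive cell mean; sanitize expression values first")
    ref_def, ref_hi = means["REF_DEFICIENT"], means["REF_HIGH"]
    del_def, del_hi = means["DEL_DEFICIENT"], means["DEL_HIGH"]
    table = {}
    for name, (num, den) in {
        "del_deficient": (del_def, ref_def),
        "del_high": (del_hi, ref_hi),
        "cu_ref": (ref_hi, ref_def),
        "cu_del": (del_hi, del_def),
    }.items():
        mag, direction = _fc(num.to_numpy(), den.to_numpy())
        table[f"fc_{name}"] = mag
        table[f"dir_{name}"] = direction
    return pd.DataFrame(table, index=means.index)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _factor_direction(fc: pd.Series, contrasts: list[str]) -> tuple[str, bool]:
    """Consensus direction over a factor's two contrasts.

    When the two contrasts disagree, the direction is taken from the sign of
    the mean of the two log-ratios and the gene is flagged inconsistent.
    """
    signs = []
    logs = []
    for c in contrasts:
        mag, d = fc[f"fc_{c}"], fc[f"dir_{c}"]
        signed = np.log2(mag) * (1 if d == "up" else -1 if d == "down" else 0)
        logs.append(signed)
        if d != "none":
            signs.append(d)
    if len(set(signs)) == 1:
        return signs[0], False
    mean_log = float(np.mean(logs))
    return ("up" if mean_log > 0 else "down"), True


_G3_SUBGROUP = {
    ("down", "up"): "G3.1",
    ("down", "down"): "G3.2",
    ("up", "up"): "G3.3",
    ("up", "down"): "G3.4",
}


@dataclass
class GeneClassification:
    """Per-gene response-group labels with the rule that fired."""

    table: pd.DataFrame  # columns: group, rationale, direction_inconsistent

    def genes_in(self, *groups: str) -> list[str]:
        mask = self.table["group"].isin(groups)
        return list(self.table.index[mask])

    def counts(self) -> dict[str, int]:
        return {g: int((self.table["group"] == g).sum()) for g in GROUPS}


def classify_genes(
    anova: pd.DataFrame,
    fold_changes: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    g3_gate: str = "either",
) -> GeneClassification:
    """Partition genes into response groups G1, G2, G3.1–G3.4, G4 and NS.

    Precedence: interaction (G4) first, then additive (G3), then single main
    effects (G1/G2). A group's fold-change gate requires at least one
    qualifying contrast of the relevant factor(s) at ``fc_threshold``
    (``g3_gate="both"`` demands both copper levels / both strains for G3).
    """
    if set(anova.index) != set(fold_changes.index):
        raise DataError("ANOVA and fold-change tables cover different gene sets")
    if g3_gate not in ("either", "both"):
        raise DataError(f"unknown g3_gate {g3_gate!r}")
    fold_changes = fold_changes.loc[anova.index]

    del_contrasts = ["del_deficient", "del_high"]
    cu_contrasts = ["cu_ref", "cu_del"]
    rows = []
    for gene in anova.index:
        a = anova.loc[gene]
        fc = fold_changes.loc[gene]
        sig_strain = a["p_strain"] < alpha
        sig_copper = a["p_copper"] < alpha
        sig_inter = a["p_interaction"] < alpha
        del_pass = [fc[f"fc_{c}"] >= fc_threshold for c in del_contrasts]
        cu_pass = [fc[f"fc_{c}"] >= fc_threshold for c in cu_contrasts]
        gate = all if g3_gate == "both" else any

        group, rationale, inconsistent = "NS", "no gate fired", False
        if sig_inter and (any(del_pass) or any(cu_pass)):
            group, rationale = "G4", f"interaction p={a['p_interaction']:.3g} with qualifying contrast"
        elif sig_strain and sig_copper and not sig_inter and gate(del_pass) and gate(cu_pass):
            ddir, dinc = _factor_direction(fc, del_contrasts)
            cdir, cinc = _factor_direction(fc, cu_contrasts)
            group = _G3_SUBGROUP[(ddir, cdir)]
            rationale = f"additive: deletion {ddir}, copper {cdir}"
            inconsistent = dinc or cinc
        elif sig_strain and not sig_copper and not sig_inter and any(del_pass):
            group, rationale = "G1", f"strain-only p={a['p_strain']:.3g}"
        elif sig_copper and not sig_strain and not sig_inter and any(cu_pass):
            group, rationale = "G2", f"copper-only p={a['p_copper']:.3g}"
        rows.append(
            {"group": group, "rationale": rationale, "direction_inconsistent": inconsistent}
        )
    return GeneClassification(pd.DataFrame(rows, index=anova.index))
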