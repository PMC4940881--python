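"""Factorial DE: normalization, ANOVA vs oracles, fold changes, classification."""

import numpy as np
import pandas as pd
import pytest

import factorialtx as ft
from factorialtx.errors import DataError
from factorialtx.factorial import classify_genes, compute_fold_changes, normalize_to_baseline, two_way_anova

from conftest import make_matrix


# ---------------------------------------------------------------------------
# baseline normalization
# ---------------------------------------------------------------------------


class TestNormalizeToBaseline:
    def test_all_sample_medians_equal_after_op(self):
        rng = np.random.default_rng(42)
        m = make_matrix(
            {cell: rng.uniform(10, 1000, size=(50, 2)) for cell in
             [("REF", "DEFICIENT"), ("REF", "HIGH"), ("DEL", "DEFICIENT"), ("DEL", "HIGH")]}
        )
        out = normalize_to_baseline(m)
        medians = out.values.median(axis=0)
        assert np.allclose(medians, medians.iloc[0])

    def test_baseline_is_median_ranked_sample(self):
        # gene rows chosen so sample medians are 10, 20, 30, ... per column
        m = make_matrix(
            {
                ("REF", "DEFICIENT"): [[10, 20], [10, 20], [10, 20]],
                ("REF", "HIGH"): [[30, 40], [30, 40], [30, 40]],
                ("DEL", "DEFICIENT"): [[50, 60], [50, 60], [50, 60]],
                ("DEL", "HIGH"): [[70, 80], [70, 80], [70, 80]],
            }
        )
        out = normalize_to_baseline(m)
        # 8 samples, medians 10..80: lower-middle is the 4th (median 40)
        assert np.allclose(out.values.median(axis=0), 40.0)

    def test_identity_when_medians_already_equal(self):
        m = make_matrix(
            {cell: [[5.0, 5.0], [100.0, 100.0]] for cell in
             [("REF", "DEFICIENT"), ("REF", "HIGH"), ("DEL", "DEFICIENT"), ("DEL", "HIGH")]}
        )
        out = normalize_to_baseline(m)
        pd.testing.assert_frame_equal(out.values, m.values)


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------


def anova_oracle_statsmodels(matrix: ft.ExpressionMatrix, gene: str) -> dict:
    """Independent per-gene oracle: OLS + type-II anova_lm on log2 values."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = matrix.samples.copy()
    df["y"] = np.log2(matrix.values.loc[gene, df.index].to_numpy())
    fit = smf.ols("y ~ C(strain) * C(copper)", data=df).fit()
    table = anova_lm(fit, typ=2)
    return {
        "F_strain": table.loc["C(strain)", "F"],
        "p_strain": table.loc["C(strain)", "PR(>F)"],
        "F_copper": table.loc["C(copper)", "F"],
        "p_copper": table.loc["C(copper)", "PR(>F)"],
        "F_interaction": table.loc["C(strain):C(copper)", "F"],
        "p_interaction": table.loc["C(strain):C(copper)", "PR(>F)"],
    }


class TestTwoWayAnova:
    def test_hand_derived_fixture(self):
        # log2 cells: REF={10,12} at both copper levels, DEL={6,8} at both
        # SS_strain=32, SS_error=8, df=(1,4) -> F_strain=16
        m = make_matrix(
            {
                ("REF", "DEFICIENT"): [[2**10, 2**12]],
                ("REF", "HIGH"): [[2**10, 2**12]],
                ("DEL", "DEFICIENT"): [[2**6, 2**8]],
                ("DEL", "HIGH"): [[2**6, 2**8]],
            }
        )
        res = two_way_anova(m)
        assert res["F_strain"].iloc[0] == pytest.approx(16.0, abs=1e-9)
        assert res["F_copper"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["F_interaction"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["df_error"].iloc[0] == 4

    def test_matches_statsmodels_on_random_genes(self):
        spec = ft.FactorialSimSpec(n_genes=12, seed=9)
        m, _ = ft.simulate_factorial_expression(spec)
        res = two_way_anova(m)
        for gene in m.gene_ids[:6]:
            oracle = anova_oracle_statsmodels(m, gene)
            for key, value in oracle.items():
                assert res.loc[gene, key] == pytest.approx(value, rel=1e-9), (gene, key)

    def test_all_values_equal_is_degenerate_with_p_one(self):
        m = make_matrix({cell: [[64.0, 64.0]] for cell in
                         [("REF", "DEFICIENT"), ("REF", "HIGH"), ("DEL", "DEFICIENT"), ("DEL", "HIGH")]})
        res = two_way_anova(m)
        assert bool(res["degenerate"].iloc[0])
        assert res["p_strain"].iloc[0] == 1.0
        assert res["p_interaction"].iloc[0] == 1.0

    def test_zero_noise_effect_gene_is_maximally_significant(self):
        m = make_matrix(
            {
                ("REF", "DEFICIENT"): [[100.0, 100.0]],
                ("REF", "HIGH"): [[100.0, 100.0]],
                ("DEL", "DEFICIENT"): [[50.0, 50.0]],
                ("DEL", "HIGH"): [[50.0, 50.0]],
            }
        )
        res = two_way_anova(m)
        assert bool(res["degenerate"].iloc[0])
        assert res["p_strain"].iloc[0] == 0.0
        assert res["p_copper"].iloc[0] == 1.0

    def test_unbalanced_design_rejected(self, two_gene_matrix):
        dropped = two_gene_matrix.values.drop(columns=["DEL_HIGH_2"])
        meta = two_gene_matrix.samples.drop(index=["DEL_HIGH_2"])
        with pytest.raises(DataError):
            two_way_anova(ft.ExpressionMatrix(dropped, meta))


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------


class TestFoldChanges:
    def test_two_fold_down_in_deletant(self):
        m = make_matrix(
            {
                ("REF", "DEFICIENT"): [[100.0, 100.0]],
                ("REF", "HIGH"): [[100.0, 100.0]],
                ("DEL", "DEFICIENT"): [[50.0, 50.0]],
                ("DEL", "HIGH"): [[100.0, 100.0]],
            }
        )
        fc = compute_fold_changes(m)
        assert fc["fc_del_deficient"].iloc[0] == pytest.approx(2.0)
        assert fc["dir_del_deficient"].iloc[0] == "down"
        assert fc["fc_del_high"].iloc[0] == pytest.approx(1.0)
        assert fc["dir_del_high"].iloc[0] == "none"

    def test_zero_noise_copper_gene_doubles_in_both_strains(self):
        spec = ft.FactorialSimSpec(
            n_genes=30, noise_sd_log2=0.0, effect_size_log2=1.0, seed=2,
            class_proportions={"NULL": 0.0, "G1": 0.0, "G2": 1.0, "G3.1": 0.0,
                               "G3.2": 0.0, "G3.3": 0.0, "G3.4": 0.0, "G4": 0.0},
        )
        m, truth = ft.simulate_factorial_expression(spec)
        fc = compute_fold_changes(m)
        up = truth["copper_effect"] > 0
        assert np.allclose(fc["fc_cu_ref"], 2.0)
        assert np.allclose(fc["fc_cu_del"], 2.0)
        assert (fc.loc[up, "dir_cu_ref"] == "up").all()
        assert (fc.loc[~up, "dir_cu_ref"] == "down").all()

    def test_magnitude_at_least_one_and_direction_consistency(self):
        spec = ft.FactorialSimSpec(n_genes=200, seed=4)
        m, _ = ft.simulate_factorial_expression(spec)
        fc = compute_fold_changes(m)
        for c in ("del_deficient", "del_high", "cu_ref", "cu_del"):
            assert (fc[f"fc_{c}"] >= 1.0).all()
            none_rows = fc[f"dir_{c}"] == "none"
            assert (fc.loc[none_rows, f"fc_{c}"] == 1.0).all()


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _anova_row(p_strain, p_copper, p_inter):
    return pd.DataFrame(
        {
            "F_strain": [1.0], "p_strain": [p_strain],
            "F_copper": [1.0], "p_copper": [p_copper],
            "F_interaction": [1.0], "p_interaction": [p_inter],
            "df_effect": [1], "df_error": [4], "degenerate": [False],
        },
        index=["G0"],
    )


def _fc_row(del_def=(1.0, "none"), del_high=(1.0, "none"),
            cu_ref=(1.0, "none"), cu_del=(1.0, "none")):
    vals = {"del_deficient": del_def, "del_high": del_high, "cu_ref": cu_ref, "cu_del": cu_del}
    data = {}
    for name, (mag, d) in vals.items():
        data[f"fc_{name}"] = [mag]
        data[f"dir_{name}"] = [d]
    return pd.DataFrame(data, index=["G0"])


@pytest.mark.parametrize(
    "pvals,fc,expected",
    [
        # strain-only significance with a qualifying deletion contrast
        ((0.01, 0.5, 0.6), _fc_row(del_def=(1.8, "down")), "G1"),
        # copper-only
        ((0.5, 0.01, 0.6), _fc_row(cu_del=(2.1, "up")), "G2"),
        # additive down/up -> G3.1
        ((0.01, 0.02, 0.7),
         _fc_row(del_def=(1.6, "down"), del_high=(1.7, "down"),
                 cu_ref=(1.8, "up"), cu_del=(1.9, "up")), "G3.1"),
        # additive up/down -> G3.4
        ((0.01, 0.02, 0.7),
         _fc_row(del_def=(1.6, "up"), del_high=(1.7, "up"),
                 cu_ref=(1.8, "down"), cu_del=(1.9, "down")), "G3.4"),
        # interaction wins over everything
        ((0.01, 0.02, 0.03), _fc_row(del_def=(1.6, "down")), "G4"),
        # significant but below the fold-change gate
        ((0.01, 0.5, 0.6), _fc_row(del_def=(1.2, "down")), "NS"),
        # interaction significant but nothing differential
        ((0.5, 0.5, 0.01), _fc_row(), "NS"),
    ],
)
def test_classification_rules(pvals, fc, expected):
    result = classify_genes(_anova_row(*pvals), fc)
    assert result.table["group"].iloc[0] == expected


def test_g3_direction_inconsistency_flagged():
    fc = _fc_row(del_def=(2.0, "down"), del_high=(1.6, "up"),
                 cu_ref=(1.8, "up"), cu_del=(1.9, "up"))
    result = classify_genes(_anova_row(0.01, 0.02, 0.7), fc)
    assert result.table["group"].iloc[0] == "G3.1"  # mean log-ratio is down
    assert bool(result.table["direction_inconsistent"].iloc[0])


def test_g3_both_gate_is_stricter():
    fc = _fc_row(del_def=(1.6, "down"), del_high=(1.1, "down"),
                 cu_ref=(1.8, "up"), cu_del=(1.9, "up"))
    either = classify_genes(_anova_row(0.01, 0.02, 0.7), fc)
    both = classify_genes(_anova_row(0.01, 0.02, 0.7), fc, g3_gate="both")
    assert either.table["group"].iloc[0] == "G3.1"
    assert both.table["group"].iloc[0] == "NS"


def test_groups_disjoint_and_exhaustive():
    spec = ft.FactorialSimSpec(n_genes=500, seed=8)
    m, _ = ft.simulate_factorial_expression(spec)
    result = classify_genes(two_way_anova(m), compute_fold_changes(m))
    counts = result.counts()
    assert sum(counts.values()) == 500
    g3 = [g for g in result.table["group"] if g.startswith("G3")]
    assert len(g3) == sum(counts[f"G3.{i}"] for i in (1, 2, 3, 4))


def test_zero_noise_round_trip_recovers_all_planted_classes():
    spec = ft.FactorialSimSpec(
        n_genes=400, noise_sd_log2=0.0, seed=13,
        class_proportions={"NULL": 0.3, "G1": 0.1, "G2": 0.1, "G3.1": 0.1,
                           "G3.2": 0.1, "G3.3": 0.1, "G3.4": 0.1, "G4": 0.1},
    )
    m, truth = ft.simulate_factorial_expression(spec)
    m = normalize_to_baseline(m)
    result = classify_genes(two_way_anova(m), compute_fold_changes(m))
    non_null = truth["planted_class"] != "NULL"
    assert (result.table.loc[non_null, "group"] == truth.loc[non_null, "planted_class"]).all()


def test_noisy_recovery_matches_theoretical_power():
    """Empirical G1/G4 recovery agrees with exact noncentral-F power analysis.

    At effect 1.0 log2 and sd 0.25 (r=2), the strain main-effect test has
    noncentrality 32 and the interaction test 8; recovery of a planted class
    additionally requires retaining the null on the other two (0.95 each) and
    passing the fold-change gate (~1 here).
    """
    from scipy.stats import f as fdist, ncf

    spec = ft.FactorialSimSpec(
        n_genes=8000, seed=21,
        class_proportions={"NULL": 0.0, "G1": 0.5, "G2": 0.0, "G3.1": 0.0,
                           "G3.2": 0.0, "G3.3": 0.0, "G3.4": 0.0, "G4": 0.5},
    )
    m, truth = ft.simulate_factorial_expression(spec)
    result = classify_genes(two_way_anova(m), compute_fold_changes(m))
    crit = fdist.isf(0.05, 1, 4)
    sigma2 = 0.25 ** 2
    expect_g1 = ncf.sf(crit, 1, 4, 2 / sigma2) * 0.95 * 0.95
    expect_g4 = ncf.sf(crit, 1, 4, 0.5 / sigma2)
    for cls, expected in (("G1", expect_g1), ("G4", expect_g4)):
        mask = truth["planted_class"] == cls
        observed = (result.table.loc[mask, "group"] == cls).mean()
        assert observed == pytest.approx(expected, abs=0.03), cls
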