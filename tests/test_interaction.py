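"""Two-way ANOVA decomposition, Bonferroni screen, and error control."""

import numpy as np
import pandas as pd
import pytest

import mechanoseq as ms

from .oracles import anova_2x2_brute

TOY_CELLS = {
    ("soft", "KDEL"): [1.0, 2.0, 3.0],
    ("soft", "SUN1L"): [2.0, 3.0, 4.0],
    ("stiff", "KDEL"): [3.0, 4.0, 5.0],
    ("stiff", "SUN1L"): [10.0, 11.0, 12.0],
}


class TestTwoWayAnovaGene:
    def test_additive_noise_free_interaction_zero(self):
        cells = {
            ("soft", "KDEL"): [1.0, 1.5],
            ("soft", "SUN1L"): [2.0, 2.5],
            ("stiff", "KDEL"): [3.0, 3.5],
            ("stiff", "SUN1L"): [4.0, 4.5],  # cell means perfectly additive
        }
        res = ms.two_way_anova_gene(cells)
        assert res["F_interaction"] == pytest.approx(0.0, abs=1e-12)

    def test_toy_matches_brute_force(self):
        res = ms.two_way_anova_gene(TOY_CELLS)
        expected = anova_2x2_brute(TOY_CELLS)
        for key in ("F_rigidity", "F_genotype", "F_interaction",
                    "p_rigidity", "p_genotype", "p_interaction"):
            assert res[key] == pytest.approx(expected[key], rel=1e-10)

    def test_toy_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rows = [(rig, gen, v) for (rig, gen), vs in TOY_CELLS.items() for v in vs]
        df = pd.DataFrame(rows, columns=["rig", "gen", "y"])
        fit = ols("y ~ C(rig) * C(gen)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        res = ms.two_way_anova_gene(TOY_CELLS)
        assert res["F_rigidity"] == pytest.approx(table.loc["C(rig)", "F"], rel=1e-9)
        assert res["F_genotype"] == pytest.approx(table.loc["C(gen)", "F"], rel=1e-9)
        assert res["F_interaction"] == pytest.approx(
            table.loc["C(rig):C(gen)", "F"], rel=1e-9)

    def test_constant_values_flagged(self):
        cells = {k: [7.0, 7.0, 7.0] for k in TOY_CELLS}
        res = ms.two_way_anova_gene(cells)
        assert res["zero_residual"]
        assert np.isnan(res["p_interaction"])

    def test_unbalanced_rejected(self):
        cells = dict(TOY_CELLS)
        cells[("soft", "KDEL")] = [1.0, 2.0]
        with pytest.raises(ms.ConfigurationError, match="unbalanced"):
            ms.two_way_anova_gene(cells)

    def test_sum_of_squares_decomposition(self, rng):
        for _ in range(20):
            cells = {k: rng.normal(rng.normal(0, 2), 1, size=3) for k in TOY_CELLS}
            expected = anova_2x2_brute(cells)
            assert expected["ss_parts"] == pytest.approx(expected["ss_total"],
                                                         rel=1e-9)

    def test_shift_and_label_swap_invariance(self, rng):
        cells = {k: rng.normal(0, 1, size=3) for k in TOY_CELLS}
        res = ms.two_way_anova_gene(cells)
        shifted = {k: v + 100.0 for k, v in cells.items()}
        res_shift = ms.two_way_anova_gene(shifted)
        assert res_shift["F_interaction"] == pytest.approx(res["F_interaction"],
                                                           rel=1e-9)
        swapped = {
            ("soft", "KDEL"): cells[("stiff", "SUN1L")],
            ("soft", "SUN1L"): cells[("stiff", "KDEL")],
            ("stiff", "KDEL"): cells[("soft", "SUN1L")],
            ("stiff", "SUN1L"): cells[("soft", "KDEL")],
        }
        res_swap = ms.two_way_anova_gene(swapped)
        assert res_swap["F_interaction"] == pytest.approx(res["F_interaction"],
                                                          rel=1e-9)


class TestInteractionScreen:
    def test_bonferroni_arithmetic(self, small_simulation):
        counts, design, _ = small_simulation
        factors = ms.tmm_factors(counts)
        norm = ms.log2_cpm(counts, factors)
        _, table = ms.interaction_screen(norm, design, counts, factors)
        fam = table[table["in_family"]]
        g = len(fam)
        np.testing.assert_allclose(
            fam["p_interaction_bonferroni"],
            np.minimum(1.0, fam["p_interaction"] * g),
        )
        # a raw p of 1e-4 in a family of 1,000 corrects to 0.1: not significant
        corrected = min(1.0, 1e-4 * 1000)
        assert corrected == pytest.approx(0.1)
        assert corrected > 0.05

    def test_missing_cell_rejected(self, small_simulation):
        counts, design, _ = small_simulation
        kdel_only = ms.DesignTable(
            design.table[design.table["genotype"] == "KDEL"])
        factors = ms.tmm_factors(counts)
        norm = ms.log2_cpm(counts, factors)
        with pytest.raises(ms.ConfigurationError, match="cell"):
            ms.interaction_screen(norm, kdel_only, counts, factors)

    def test_planted_strong_interaction_detected(self):
        """A gene with a -3 log2 interaction at low dispersion and high
        abundance must be flagged by the Bonferroni screen."""
        cfg = ms.SimulationConfig(
            n_genes=500,
            class_proportions={"null": 0.998, "reversed": 0.002},
            effect_floor=1.5, effect_window=0.0001,
            dispersion_range=(0.05, 0.05), planted_b0_range=(8.0, 8.0),
            seed=31,
        )
        counts, design, truth = ms.simulate_counts(cfg)
        truth = truth.set_index("gene_id")
        planted = truth.index[truth["true_class"] == "reversed"]
        assert len(planted) == 1
        factors = ms.tmm_factors(counts)
        norm = ms.log2_cpm(counts, factors)
        hits, _ = ms.interaction_screen(norm, design, counts, factors)
        assert set(planted) <= set(hits)

    def test_global_null_mostly_empty(self):
        """FWER spot-check: across 20 null simulations, at most a couple have
        any Bonferroni-significant interaction (full 200-run calibration lives
        in the acceptance suite)."""
        with_hits = 0
        for seed in range(20):
            counts, design, _ = ms.simulate_counts(ms.null_scenario(700 + seed))
            factors = ms.tmm_factors(counts)
            norm = ms.log2_cpm(counts, factors)
            hits, _ = ms.interaction_screen(norm, design, counts, factors)
            with_hits += bool(hits)
        assert with_hits <= 4


class TestRigidityDependentNoninteracting:
    def test_definitional_cases(self):
        """beta_rig=2 alone is included; a gene also shifted by genotype is
        excluded; null genes are excluded."""
        cfg = ms.SimulationConfig(
            n_genes=400,
            class_proportions={"null": 0.99, "rigidity_only": 0.01},
            effect_floor=2.0, effect_window=0.0001,
            dispersion_range=(0.02, 0.02), planted_b0_range=(8.0, 8.0),
            seed=37,
        )
        counts, design, truth = ms.simulate_counts(cfg)
        truth = truth.set_index("gene_id")
        norm = ms.log2_cpm(counts, ms.tmm_factors(counts))
        got = set(ms.rigidity_dependent_noninteracting(norm, design))
        planted = set(truth.index[truth["true_class"] == "rigidity_only"])
        assert planted <= got
        # every pick is genuinely rigidity-responsive in truth
        nulls = set(truth.index[truth["true_class"] == "null"])
        assert len(got & nulls) / max(len(got), 1) < 0.2

    def test_genotype_responsive_gene_excluded(self):
        """A gene whose rigidity response flips with genotype (reversed class)
        responds to SUN1L on at least one substrate, so it is excluded."""
        cfg = ms.class_recovery_scenario(seed=41, n_per_class=30, n_null=110)
        counts, design, truth = ms.simulate_counts(cfg)
        truth = truth.set_index("gene_id")
        norm = ms.log2_cpm(counts, ms.tmm_factors(counts))
        got = set(ms.rigidity_dependent_noninteracting(norm, design))
        reversed_genes = set(truth.index[truth["true_class"] == "reversed"])
        assert not (got & reversed_genes)
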