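"""Fold changes, Welch z, BH adjustment, low-count filter, Spearman QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mechanoseq as ms
from mechanoseq.diffexpr import signed_fc_from_fold

from .oracles import bh_brute, spearman_brute, welch_z_brute


def _norm_matrix(rows, samples):
    df = pd.DataFrame(rows, columns=samples)
    df.index = [f"g{i+1}" for i in range(len(df))]
    df.index.name = "gene_id"
    return df


class TestFoldChange:
    @pytest.mark.parametrize(
        "delta,fc,signed",
        [(0.0, 1.0, 1.0), (1.0, 2.0, 2.0), (-2.0, 0.25, -4.0)],
    )
    def test_signed_convention(self, delta, fc, signed):
        norm = _norm_matrix([[5.0 + delta, 5.0 + delta, 5.0, 5.0]],
                            ["a1", "a2", "b1", "b2"])
        out = ms.group_fold_change(norm, ["a1", "a2"], ["b1", "b2"])
        assert out["fold_change"].iloc[0] == pytest.approx(fc)
        assert out["signed_fc"].iloc[0] == pytest.approx(signed)

    def test_swapping_groups_negates_signed_fc(self):
        rng = np.random.default_rng(0)
        norm = _norm_matrix(rng.normal(5, 1, size=(10, 6)),
                            [f"s{i}" for i in range(6)])
        a, b = [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]
        fwd = ms.group_fold_change(norm, a, b)["signed_fc"]
        rev = ms.group_fold_change(norm, b, a)["signed_fc"]
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), rtol=1e-12)

    def test_overlapping_groups_rejected(self):
        norm = _norm_matrix([[1.0, 2.0, 3.0]], ["s1", "s2", "s3"])
        with pytest.raises(ms.ConfigurationError, match="overlap"):
            ms.group_fold_change(norm, ["s1", "s2"], ["s2", "s3"])

    @given(st.floats(min_value=-20, max_value=20))
    def test_signed_fc_is_odd_in_log_difference(self, delta):
        s_fwd = signed_fc_from_fold(2.0 ** delta)
        s_rev = signed_fc_from_fold(2.0 ** (-delta))
        assert s_fwd == pytest.approx(-s_rev) or (s_fwd == 1.0 and s_rev == 1.0)


class TestZTest:
    def test_identical_groups_give_null(self):
        norm = _norm_matrix([[2.0, 3.0, 2.0, 3.0]], ["a1", "a2", "b1", "b2"])
        out = ms.z_test(norm, ["a1", "a2"], ["b1", "b2"])
        assert out["z"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        norm = _norm_matrix(rng.normal(5, 1, size=(8, 6)),
                            [f"s{i}" for i in range(6)])
        a, b = [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]
        fwd = ms.z_test(norm, a, b)
        rev = ms.z_test(norm, b, a)
        np.testing.assert_allclose(fwd["z"], -rev["z"], rtol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-12)

    def test_hand_computed_welch_z(self):
        norm = _norm_matrix([[2.0, 3.0, 4.0, 5.0, 6.0, 7.0]],
                            ["a1", "a2", "a3", "b1", "b2", "b3"])
        out = ms.z_test(norm, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        z_expected, p_expected = welch_z_brute([2, 3, 4], [5, 6, 7])
        assert z_expected == pytest.approx(-3.674, abs=1e-3)
        assert out["z"].iloc[0] == pytest.approx(z_expected, rel=1e-12)
        assert out["p"].iloc[0] == pytest.approx(p_expected, rel=1e-12)

    def test_zero_variance_unequal_means_flagged(self):
        norm = _norm_matrix([[1.0, 1.0, 2.0, 2.0]], ["a1", "a2", "b1", "b2"])
        out = ms.z_test(norm, ["a1", "a2"], ["b1", "b2"])
        assert out["degenerate"].iloc[0]
        assert 0 < out["p"].iloc[0] < 1e-300


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ms.bh_adjust([0.03]), [0.03])

    def test_all_equal_p(self):
        np.testing.assert_allclose(ms.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_spec_example(self):
        np.testing.assert_allclose(ms.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   bh_brute([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(ms.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_brute_force_equivalence_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(ms.bh_adjust(p), bh_brute(p),
                                       rtol=1e-12, atol=1e-15)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=100)
        q = ms.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ms.bh_adjust([0.5, 1.5])


class TestLowCountFilter:
    def test_threshold_is_strict_less_than(self):
        df = pd.DataFrame({"s1": [4, 5, 6], "s2": [5, 5, 5]},
                          index=["gA", "gB", "gC"])
        out = ms.low_count_filter(ms.CountMatrix(df), min_total=10)
        assert out.gene_ids == ["gB", "gC"]  # totals 9, 10, 11

    def test_zero_threshold_is_identity(self, toy_counts):
        out = ms.low_count_filter(toy_counts, min_total=0)
        pd.testing.assert_frame_equal(out.counts, toy_counts.counts)

    def test_all_filtered_returns_empty(self, toy_counts):
        out = ms.low_count_filter(toy_counts, min_total=10**9)
        assert len(out) == 0


class TestSampleSpearman:
    def test_self_correlation_and_symmetry(self, small_simulation):
        counts, _, _ = small_simulation
        norm = ms.log2_cpm(counts, ms.tmm_factors(counts))
        rho = ms.sample_spearman(norm)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho.to_numpy(), rho.to_numpy().T)

    def test_reversed_ranks(self):
        norm = _norm_matrix([[1.0, 4.0], [2.0, 3.0], [3.0, 2.0], [4.0, 1.0]],
                            ["s1", "s2"])
        rho = ms.sample_spearman(norm)
        assert rho.loc["s1", "s2"] == pytest.approx(-1.0)

    def test_midrank_ties_match_brute_force(self):
        x, y = [1.0, 2.0, 2.0, 3.0], [1.0, 2.0, 3.0, 3.0]
        norm = _norm_matrix(np.column_stack([x, y]), ["s1", "s2"])
        rho = ms.sample_spearman(norm)
        assert rho.loc["s1", "s2"] == pytest.approx(spearman_brute(x, y),
                                                    rel=1e-12)

    def test_constant_sample_reported_missing(self):
        norm = _norm_matrix([[1.0, 5.0, 2.0], [1.0, 6.0, 1.0], [1.0, 7.0, 3.0]],
                            ["flat", "s2", "s3"])
        rho = ms.sample_spearman(norm)
        assert np.isnan(rho.loc["flat", "s2"])
        assert rho.loc["flat", "flat"] == 1.0
        assert rho.loc["s2", "s3"] == pytest.approx(spearman_brute(
            [5.0, 6.0, 7.0], [2.0, 1.0, 3.0]))


class TestNullCalibration:
    def test_null_simulation_de_rate_bounded(self):
        """Global null, 2,000 genes, n=3 per group: the double criterion
        (q < 0.05 and |signed_fc| >= 2) fires in at most a small fraction of
        genes (0.05 in expectation plus 3x Monte-Carlo s.e.)."""
        cfg = ms.SimulationConfig(n_genes=2000, class_proportions={"null": 1.0},
                                  seed=29)
        counts, design, _ = ms.simulate_counts(cfg)
        norm = ms.log2_cpm(counts, ms.tmm_factors(counts))
        a = design.samples_where(genotype="SUN1L", rigidity="soft")
        b = design.samples_where(genotype="KDEL", rigidity="soft")
        table = ms.de_table(norm, a, b, fc_cutoff=2.0, alpha_fdr=0.05)
        rate = table["significant"].mean()
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)
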