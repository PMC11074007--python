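import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pepset.settest import (MAD_SCALE, adjust_pvalues, competitive_set_test,
                            results_to_frame, run_pepsettest, scaled_mad)

from conftest import make_design, make_table


def pooled_two_sample_t(a, b):
    """Textbook pooled two-sample t oracle (independent of the package)."""
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


class TestScaledMad:
    def test_hand_case(self):
        # MAD of (1..5) is 1, so the result is the consistency constant
        assert scaled_mad([1, 2, 3, 4, 5]) == pytest.approx(1.4826)

    def test_constant_vector_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            assert scaled_mad([2.0, 2.0, 2.0]) == 0.0

    def test_consistency_constant(self):
        # 1.4826 reproduces 1/Phi^-1(3/4) to 4 decimals
        assert MAD_SCALE == pytest.approx(1.0 / stats.norm.ppf(0.75), abs=5e-5)

    def test_normal_consistency_monte_carlo(self):
        x = np.random.default_rng(42).standard_normal(10 ** 6)
        assert scaled_mad(x) == pytest.approx(1.0, rel=0.01)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            scaled_mad([1.0])


class TestCompetitiveSetTest:
    def test_centered_case_p_one(self):
        t = np.array([0.0, 0.0, 1.0, -1.0, 2.0, -2.0])
        res = competitive_set_test(t, [0, 1], rho=0.0, scale_method="sd")
        assert res.T_set == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_rho_zero_matches_pooled_t_oracle(self, rng):
        for _ in range(200):
            t = rng.normal(size=rng.integers(10, 60))
            m = int(rng.integers(2, 5))
            res = competitive_set_test(t, np.arange(m), rho=0.0,
                                       scale_method="sd")
            T, p = pooled_two_sample_t(t[:m], t[m:])
            assert res.T_set == pytest.approx(T, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_vif_arithmetic(self, rng):
        # m=10, rho=0.05 -> VIF = 1.45 in the denominator
        t = rng.normal(size=100)
        r0 = competitive_set_test(t, np.arange(10), rho=0.0, scale_method="sd")
        r1 = competitive_set_test(t, np.arange(10), rho=0.05, scale_method="sd")
        m, m2 = 10, 90
        expected_ratio = np.sqrt((1.0 / m + 1.0 / m2) / (1.45 / m + 1.0 / m2))
        assert r1.T_set / r0.T_set == pytest.approx(expected_ratio, abs=1e-12)

    def test_p_nondecreasing_in_rho(self, rng):
        t = rng.normal(size=80)
        t[:5] += 1.0
        ps = [competitive_set_test(t, np.arange(5), rho=r, scale_method="sd").p
              for r in (0.0, 0.1, 0.3, 0.7)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_background_permutation_invariance(self, rng):
        t = rng.normal(size=50)
        res1 = competitive_set_test(t, [3, 7], rho=0.2, scale_method="mad")
        bg = [i for i in range(50) if i not in (3, 7)]
        perm = np.array([3, 7] + list(rng.permutation(bg)))
        res2 = competitive_set_test(t[perm], [0, 1], rho=0.2, scale_method="mad")
        assert res1.p == pytest.approx(res2.p, abs=1e-12)

    def test_negation_symmetry(self, rng):
        t = rng.normal(size=40)
        r1 = competitive_set_test(t, [0, 1, 2], rho=0.0, scale_method="sd")
        r2 = competitive_set_test(-t, [0, 1, 2], rho=0.0, scale_method="sd")
        assert r2.T_set == pytest.approx(-r1.T_set, abs=1e-12)
        assert r2.p == pytest.approx(r1.p, abs=1e-12)

    def test_mad_robust_to_background_outliers(self, rng):
        t = rng.normal(size=200)
        t[:5] += 1.5
        t[100:110] += 25.0  # wild background outliers
        p_sd = competitive_set_test(t, np.arange(5), 0.0, "sd").p
        p_mad = competitive_set_test(t, np.arange(5), 0.0, "mad").p
        assert p_mad < p_sd

    def test_nan_t_excluded(self, rng):
        t = rng.normal(size=30)
        t[2] = np.nan
        t[20] = np.nan
        res = competitive_set_test(t, [0, 1, 2], rho=0.0, scale_method="sd")
        assert res.m == 2
        T, p = pooled_two_sample_t(t[:2], np.delete(t[3:], 17))
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_degenerate_background_errors(self):
        t = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            competitive_set_test(t, [0], rho=0.0, scale_method="sd")

    def test_empty_set_errors(self, rng):
        with pytest.raises(ValueError):
            competitive_set_test(rng.normal(size=10), [], 0.0, "sd")


class TestAdjustPvalues:
    def test_bh_single_identity(self):
        np.testing.assert_allclose(adjust_pvalues([0.3], "BH"), [0.3])

    def test_bh_stepup_hand_case(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_by_harmonic_hand_case(self):
        # harmonic number H4 = 25/12 scales the BH values
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BY")
        np.testing.assert_allclose(out, [1.0 / 12] * 4, atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_by_dominates_bh(self, p):
        bh = adjust_pvalues(p, "BH")
        by = adjust_pvalues(p, "BY")
        assert np.all(by >= bh - 1e-15)
        assert np.all(bh >= np.asarray(p) - 1e-15)
        assert np.all((bh <= 1) & (by <= 1))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(50)
        for method, key in (("BH", "fdr_bh"), ("BY", "fdr_by")):
            ours = adjust_pvalues(p, method)
            theirs = multipletests(p, method=key)[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "BH")

    def test_nan_propagates(self):
        out = adjust_pvalues([0.02, np.nan, 0.04], "BH")
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.04, 0.04], atol=1e-12)


class TestRunPepsettest:
    def test_spiked_protein_ranks_first(self, toy_table, toy_design):
        res = run_pepsettest(toy_table, toy_design, cor_method="mixed",
                             scale_method="sd")
        assert res[0].protein_id == "PB"
        assert res[0].direction == 1
        assert res[0].mean_logFC > 1.0

    def test_sorted_and_adjusted(self, toy_table, toy_design):
        res = run_pepsettest(toy_table, toy_design)
        ps = [r.p for r in res]
        assert ps == sorted(ps)
        assert all(r.p_adj >= r.p - 1e-15 for r in res)
        assert all(0 < r.p <= 1 and 0 < r.p_adj <= 1 for r in res)

    def test_cor_none_matches_oracle(self, toy_table, toy_design):
        res = run_pepsettest(toy_table, toy_design, cor_method="none",
                             scale_method="sd")
        from pepset.linmod import fit_peptides, moderate
        fit = moderate(fit_peptides(toy_table, toy_design.aligned(
            toy_table.sample_ids)))
        idx = toy_table.protein_index()
        for r in res:
            rows = idx[r.protein_id]
            others = np.setdiff1d(np.arange(len(fit.t_mod)), rows)
            T, p = pooled_two_sample_t(fit.t_mod[rows], fit.t_mod[others])
            assert r.p == pytest.approx(p, abs=1e-10)

    def test_shared_peptide_in_both_sets(self, rng):
        y = rng.normal(size=(6, 6))
        prots = [("P1",), ("P1",), ("P1", "P2"), ("P2",), ("P3",), ("P3",)]
        t = make_table(y, protein_map=prots)
        res = {r.protein_id: r for r in run_pepsettest(t, make_design(6),
                                                       cor_method="none",
                                                       scale_method="sd")}
        assert res["P1"].m == 3  # shared peptide counted in P1
        assert res["P2"].m == 2  # ... and in P2
        assert res["P3"].m == 2

    def test_single_peptide_protein_flagged(self, rng):
        y = rng.normal(size=(5, 6))
        prots = [("P1",)] * 4 + [("P2",)]
        res = {r.protein_id: r for r in
               run_pepsettest(make_table(y, protein_map=prots), make_design(6),
                              cor_method="none", scale_method="sd")}
        assert res["P2"].m == 1
        assert "single-peptide" in res["P2"].flag

    def test_by_dominates_bh_end_to_end(self, toy_table, toy_design):
        bh = run_pepsettest(toy_table, toy_design, adjust="BH")
        by = run_pepsettest(toy_table, toy_design, adjust="BY")
        bh_map = {r.protein_id: r.p_adj for r in bh}
        for r in by:
            assert r.p_adj >= bh_map[r.protein_id] - 1e-15

    def test_results_frame_columns(self, toy_table, toy_design):
        df = results_to_frame(run_pepsettest(toy_table, toy_design))
        assert list(df.columns) == ["protein", "n_peptides", "rho", "T", "df",
                                    "p", "p_adj", "mean_logFC", "direction",
                                    "flag"]
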