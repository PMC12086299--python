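"""Normality gate, exact Wilcoxon, Benjamini-Hochberg, Pearson, study tables."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

import eegmicrostates as ms


def wilcoxon_enumeration_oracle(diffs):
    """Brute-force exact two-sided p: enumerate all 2^m sign assignments."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = sp_stats.rankdata(np.abs(diffs))
    v_obs = ranks[diffs > 0].sum()
    m = diffs.size
    vs = np.array([np.sum(ranks[list(signs)]) if any(signs) else 0.0
                   for signs in product([False, True], repeat=m)])
    p_low = np.mean(vs <= v_obs + 1e-12)
    p_high = np.mean(vs >= v_obs - 1e-12)
    return v_obs, min(1.0, 2.0 * min(p_low, p_high))


class TestShapiroWilk:
    def test_skewed_samples_rejected(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            ms.shapiro_wilk(rng.exponential(size=50)).p < 0.05
            for _ in range(100))
        assert rejections > 90

    def test_normal_samples_type_i_rate(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            ms.shapiro_wilk(rng.standard_normal(50)).p < 0.05
            for _ in range(400))
        assert 0.01 < rejections / 400 < 0.10

    def test_constant_vector_rejected(self):
        with pytest.raises(ms.DegenerateDataError):
            ms.shapiro_wilk(np.ones(10))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ms.ParameterError):
            ms.shapiro_wilk([1.0, 2.0])


class TestExactWilcoxon:
    def test_all_positive_differences(self):
        # diffs (1,2,3): V=6; only V in {0,6} as extreme -> p = 2/8 = 0.25
        res = ms.wilcoxon_signed_rank_exact([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.statistic_name == "V"
        assert res.value == pytest.approx(6.0)
        assert res.p == pytest.approx(0.25)

    def test_symmetry_all_negative(self):
        res = ms.wilcoxon_signed_rank_exact([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.value == pytest.approx(0.0)
        assert res.p == pytest.approx(0.25)

    def test_zero_differences_dropped(self):
        res = ms.wilcoxon_signed_rank_exact([1.0, 5.0, 2.0, 3.0],
                                            [1.0, 5.0, 3.0, 5.0])
        ref = ms.wilcoxon_signed_rank_exact([2.0, 3.0], [3.0, 5.0])
        assert res.p == pytest.approx(ref.p)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ms.DegenerateDataError):
            ms.wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("n,seed", [(4, 0), (7, 1), (9, 2), (12, 3),
                                        (10, 4), (12, 5)])
    def test_matches_enumeration_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pre = rng.normal(size=n)
        post = pre + rng.normal(size=n)
        res = ms.wilcoxon_signed_rank_exact(pre, post)
        v_ref, p_ref = wilcoxon_enumeration_oracle(post - pre)
        assert res.value == pytest.approx(v_ref)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            diffs = rng.integers(-4, 5, size=9).astype(float)
            if np.all(diffs == 0):
                continue
            res = ms.wilcoxon_signed_rank_exact(np.zeros_like(diffs), diffs)
            v_ref, p_ref = wilcoxon_enumeration_oracle(diffs)
            assert res.value == pytest.approx(v_ref)
            assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        # untied case: scipy's exact Wilcoxon is an independent reference
        rng = np.random.default_rng(7)
        for _ in range(10):
            diffs = rng.normal(size=19)
            res = ms.wilcoxon_signed_rank_exact(np.zeros(19), diffs)
            ref = sp_stats.wilcoxon(diffs, alternative="two-sided",
                                    method="exact")
            v_scipy = min(ref.statistic,
                          19 * 20 / 2 - ref.statistic)  # scipy reports min
            assert min(res.value, 190 - res.value) == pytest.approx(v_scipy)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_m_uses_normal_approximation(self):
        rng = np.random.default_rng(8)
        diffs = rng.normal(loc=0.3, size=40)
        res = ms.wilcoxon_signed_rank_exact(np.zeros(40), diffs)
        assert res.method == "normal-approximation"
        ref = sp_stats.wilcoxon(diffs, alternative="two-sided",
                                method="approx", correction=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        adj = ms.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ms.benjamini_hochberg([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ms.ParameterError):
            ms.benjamini_hochberg([0.1, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        from statsmodels.stats.multitest import multipletests
        adj = ms.benjamini_hochberg(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(adj, ref, atol=1e-12)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


class TestPearsonChangeCorrelation:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ms.pearson_change_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(9)
        res = ms.pearson_change_correlation(rng.normal(size=19),
                                            rng.normal(size=19))
        assert res.df == 17

    def test_t_r_identity(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x = rng.normal(size=15)
            y = 0.4 * x + rng.normal(size=15)
            res = ms.pearson_change_correlation(x, y)
            t_expected = res.r * np.sqrt(res.df / (1 - res.r**2))
            assert res.value == pytest.approx(t_expected)
            p_expected = 2 * sp_stats.t.sf(abs(res.value), res.df)
            assert res.p == pytest.approx(p_expected)

    def test_planted_rho_recovered_at_large_n(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal(1000)
        x = z
        y = 0.6 * z + np.sqrt(1 - 0.36) * rng.standard_normal(1000)
        res = ms.pearson_change_correlation(x, y)
        assert abs(res.r - 0.6) < 0.06

    def test_zero_variance_rejected(self):
        with pytest.raises(ms.DegenerateDataError):
            ms.pearson_change_correlation(np.ones(5), np.arange(5.0))


@pytest.fixture(scope="module")
def report():
    study = ms.simulate_paired_study(n_subjects=19, effect_ms=8.0,
                                     rho=0.5, seed=20, synthesize=False)
    return ms.process_study_from_truth(study)["report"]


class TestStudyAnalysis:

    def test_prepost_table_schema(self, report):
        t4 = report["parameters_prepost"]
        assert set(t4["site"]) == {"DMPFC", "DLPFC"}
        assert (t4["statistic_name"] == "V").all()
        assert len(t4) == 8  # duration/contribution x D/C x two sites
        assert (t4["p_adjusted"] >= t4["p"] - 1e-12).all()

    def test_correlation_tables_have_df_17(self, report):
        for key in ("parameters_vs_stai", "transitions_vs_stai"):
            table = report[key]
            assert (table["df"] == 17).all()
            assert (table["statistic_name"] == "t").all()

    def test_transitions_table_rows(self, report):
        t5 = report["transitions_prepost"]
        assert len(t5) == 4
        assert set(t5["comparison"]) == {
            "From microstate map C to microstate map D",
            "From microstate map D to microstate map C"}

    def test_baseline_table_rows(self, report):
        base = report["baseline_madrs"]
        assert set(base["comparison"]) == {
            "Occurrence of microstate map A",
            "Duration of microstate map D"}
        assert (base["df"] == 17).all()

    def test_planted_effect_detected(self, report):
        t4 = report["parameters_prepost"]
        dur_d = t4[t4["comparison"] == "Duration of microstate map D"]
        assert (dur_d["p_adjusted"] < 0.05).all()
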