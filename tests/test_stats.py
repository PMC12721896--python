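"""Fold-change classification, exact tests, z-scores and the time course."""

import numpy as np
import pandas as pd
import pytest

from _oracles import binomial_two_tailed_oracle, fisher_two_tailed_oracle
from midaflux import stats


def _summaries(values_ref, values_alt, cvs=10.0):
    ids = [f"P{i}" for i in range(len(values_ref))]
    ref = pd.DataFrame({"protein_id": ids, "mean_fsr": values_ref, "cv": cvs})
    alt = pd.DataFrame({"protein_id": ids, "mean_fsr": values_alt, "cv": cvs})
    return ref, alt


class TestPairedLog2fc:
    def test_basic_directions(self):
        ref, alt = _summaries([0.05, 0.05, 0.04], [0.05, 0.025, 0.08])
        out = stats.paired_log2fc(ref, alt)
        assert out["direction"].tolist() == ["Tie", "Down", "Up"]
        assert out["log2fc"].tolist() == pytest.approx([0.0, -1.0, 1.0])
        assert out["percent_change"].tolist() == pytest.approx([0.0, -50.0, 100.0])

    def test_unpaired_proteins_excluded(self):
        ref = pd.DataFrame({"protein_id": ["P1", "P2"], "mean_fsr": [0.05, 0.04], "cv": 10.0})
        alt = pd.DataFrame({"protein_id": ["P2", "P3"], "mean_fsr": [0.02, 0.04], "cv": 10.0})
        out = stats.paired_log2fc(ref, alt)
        assert out["protein_id"].tolist() == ["P2"]

    def test_nonpositive_means_excluded(self):
        ref, alt = _summaries([0.05, 0.0], [0.05, 0.02])
        assert len(stats.paired_log2fc(ref, alt)) == 1

    def test_swapping_arms_negates_log2fc_and_swaps_calls(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(-2, 0.4, 50)
        b = rng.lognormal(-2, 0.4, 50)
        ref, alt = _summaries(a, b)
        fwd = stats.paired_log2fc(ref, alt)
        rev = stats.paired_log2fc(alt, ref)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert (fwd["direction"] == "Down").sum() == (rev["direction"] == "Up").sum()


class TestCvCutoff:
    def test_average_pooled_over_arms(self):
        assert stats.average_cv_threshold([10.0, 20.0]) == 15.0
        assert stats.average_cv_threshold([12.0]) == 12.0
        assert stats.average_cv_threshold([10.0], [20.0, np.nan]) == 15.0
        with pytest.raises(ValueError):
            stats.average_cv_threshold([np.nan])

    def test_classification_on_percent_change_scale(self):
        comp = pd.DataFrame(
            {
                "protein_id": ["P1", "P2", "P3"],
                "log2fc": [-0.3, -0.1, 0.0],
                "direction": ["Down", "Down", "Tie"],
            }
        )
        comp["percent_change"] = (np.exp2(comp["log2fc"]) - 1) * 100
        out = stats.classify_flux_change(comp, threshold=15.0)
        # |2^-0.3 - 1| = 18.77% above; |2^-0.1 - 1| = 6.70% below
        assert out["above_cv"].tolist() == [True, False, False]
        assert out.loc[0, "percent_change"] == pytest.approx(-18.7739, abs=1e-3)
        assert out.loc[1, "percent_change"] == pytest.approx(-6.6967, abs=1e-3)

    def test_zero_threshold_flags_any_change(self):
        comp = pd.DataFrame(
            {"protein_id": ["P1"], "log2fc": [0.01], "direction": ["Up"], "percent_change": [0.7]}
        )
        assert stats.classify_flux_change(comp, 0.0)["above_cv"].all()


class TestBinomialTwoTailed:
    def test_reference_values(self):
        assert stats.binomial_two_tailed(6, 10) == pytest.approx(0.75390625)
        assert stats.binomial_two_tailed(5, 10) == 1.0
        assert stats.binomial_two_tailed(10, 10) == pytest.approx(2 / 1024)

    def test_agrees_with_exhaustive_enumeration(self):
        for n in range(1, 13):
            for k in range(n + 1):
                expected = float(binomial_two_tailed_oracle(k, n))
                assert stats.binomial_two_tailed(k, n) == pytest.approx(expected, abs=1e-12)

    def test_minlike_method_matches_scipy_convention(self):
        from scipy.stats import binomtest

        for k, n in [(3, 10), (6, 10), (0, 7)]:
            assert stats.binomial_two_tailed(k, n, method="minlike") == pytest.approx(
                binomtest(k, n).pvalue
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.binomial_two_tailed(5, 0)
        with pytest.raises(ValueError):
            stats.binomial_two_tailed(5, 4)


class TestFisherExact:
    def test_reference_values(self):
        assert stats.fisher_exact_two_tailed([[10, 0], [0, 10]]) == pytest.approx(2 / 184756)
        assert stats.fisher_exact_two_tailed([[5, 5], [5, 5]]) == 1.0
        expected = fisher_two_tailed_oracle(1, 9, 9, 1)
        assert stats.fisher_exact_two_tailed([[1, 9], [9, 1]]) == pytest.approx(expected)

    def test_agrees_with_enumeration_on_margin_grid(self):
        # sparse but systematic sweep; the dense sweep runs in the acceptance suite
        for a in range(0, 9, 2):
            for b in range(0, 9 - a):
                for c in range(0, 9 - a):
                    for d in range(0, 9 - c):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        expected = fisher_two_tailed_oracle(a, b, c, d)
                        got = stats.fisher_exact_two_tailed([[a, b], [c, d]])
                        assert got == pytest.approx(expected, abs=1e-10)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_two_tailed([[0, 0], [3, 4]])


class TestProportionsAndContrasts:
    def _comparisons(self, n_down, n_up, n_ties=0, above=None):
        direction = ["Down"] * n_down + ["Up"] * n_up + ["Tie"] * n_ties
        df = pd.DataFrame({"protein_id": range(len(direction)), "direction": direction})
        df["above_cv"] = above if above is not None else False
        return df

    def test_ties_excluded_and_counts_partition(self):
        res = stats.proportion_test(self._comparisons(6, 3, n_ties=2))
        assert (res.n_down, res.n_up, res.n_ties) == (6, 3, 2)
        assert res.n_classified == 9
        assert res.p_binomial == pytest.approx(stats.binomial_two_tailed(6, 9))

    def test_above_cv_counts(self):
        above = [True, True, False, False, False, True, False]
        res = stats.proportion_test(self._comparisons(4, 3, above=above))
        assert res.n_down_above_cv == 2 and res.n_up_above_cv == 1

    def test_arm_contrast_table_and_p(self):
        res_a = stats.proportion_test(self._comparisons(10, 0))
        res_b = stats.proportion_test(self._comparisons(0, 10))
        contrast = stats.arm_contrast(res_a, res_b, "CR", "NO-CR")
        assert contrast.table.tolist() == [[10, 0], [0, 10]]
        assert contrast.p_fisher == pytest.approx(2 / 184756)


class TestZscore:
    def test_unit_variance_and_zero_mean(self):
        assert stats.zscore([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_affine_invariance(self):
        x = np.array([0.3, 0.5, 0.1, 0.9])
        assert stats.zscore(3 * x + 7) == pytest.approx(stats.zscore(x))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            stats.zscore([2.0, 2.0, 2.0])

    def test_by_timepoint_pooled_vs_within_arm(self):
        df = pd.DataFrame(
            {
                "day": [0, 0, 0, 0],
                "group": ["Con", "Con", "CR", "CR"],
                "mean_fsr": [0.4, 0.6, 0.1, 0.3],
            }
        )
        pooled = stats.zscore_by_timepoint(df)
        assert pooled["zscore"].mean() == pytest.approx(0.0, abs=1e-12)
        within = stats.zscore_by_timepoint(df, pooled=False)
        assert within.groupby("group")["zscore"].mean().abs().max() < 1e-12


class TestTimecourse:
    def _daily(self, days, pcts):
        return pd.DataFrame({"day": days, "pct_down": pcts})

    def test_log2_ratio_to_reference_day(self):
        daily = self._daily([0, 25, 31], [54.0, 52.0, 85.0])
        res = stats.timecourse_summary(daily)
        ratio = res.points.set_index("day")["log2_rel_day0"]
        assert ratio[31] == pytest.approx(np.log2(85 / 54), abs=1e-9)
        assert ratio[0] == 0.0
        assert res.points["neg_log2_rel_day0"].tolist() == pytest.approx(
            (-res.points["log2_rel_day0"]).tolist()
        )

    def test_flat_series_reports_no_transition(self):
        daily = self._daily([0, 20, 40], [54.0, 54.0, 54.0])
        res = stats.timecourse_summary(daily)
        assert res.transition_day is None
        assert res.first_day_above_threshold is None

    def test_step_series_midpoint_in_transition_window(self):
        days = [0, 9, 14, 20, 25, 27, 29, 31, 40]
        pcts = [55, 54, 56, 55, 57, 72, 78, 80, 80]
        res = stats.timecourse_summary(self._daily(days, pcts))
        assert 25 <= res.transition_day <= 30
        assert res.first_day_above_threshold == 27

    def test_missing_reference_day_rejected(self):
        with pytest.raises(ValueError):
            stats.timecourse_summary(self._daily([5, 10, 20], [50, 55, 60]))


def test_null_type_one_error_controlled():
    """Sign test rejects at 5% in <= 7% of null proteome comparisons."""
    from midaflux.simulate import null_binomial_pvalues

    pvals = null_binomial_pvalues(n_reps=300, seed=42, n_proteins=120, n_animals=4)
    assert (pvals < 0.05).mean() <= 0.07
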