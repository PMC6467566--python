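"""Population inference: attribution accounting, proportion tests, contrasts."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import audassoc.population as pop
from audassoc import errors


class TestAttributionAccounting:
    def test_s1_worked_example(self):
        # 298 units, 124 significant during ratios, 47 also significant
        # before, 63 tested passively of which 11 significant
        res = pop.attribution_accounting(298, 124, 47, 63, 11)
        assert res.n_context_attributed == 22
        assert res.n_remainder == 55
        assert res.pct_remainder_of_sig == 44.4
        assert res.pct_remainder_of_total == 18.5

    def test_s2_worked_example(self):
        res = pop.attribution_accounting(294, 108, 33, 48, 5)
        assert res.n_context_attributed == 11
        assert res.n_remainder == 64
        assert res.pct_remainder_of_sig_int == 59

    def test_no_confounds_leaves_everything(self):
        res = pop.attribution_accounting(100, 40, 0, 20, 0)
        assert res.n_remainder == 40
        assert res.pct_remainder_of_sig == 100.0

    def test_without_passive_data_context_not_estimable(self):
        res = pop.attribution_accounting(100, 40, 10, None, None)
        assert not res.context_estimable
        assert res.n_context_attributed is None
        assert res.n_remainder == 30

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(errors.InvalidInputError):
            pop.attribution_accounting(100, 40, 45, 20, 0)
        with pytest.raises(errors.InvalidInputError):
            pop.attribution_accounting(100, 10, 5, 10, 10)  # negative remainder


def _signed_rank_oracle(logr):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    ranks = rankdata(np.abs(logr))
    w_obs = ranks[np.asarray(logr) > 0].sum()
    ws = []
    for signs in product((0, 1), repeat=len(logr)):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestSummarizeRatios:
    def test_all_unit_ratios_at_one(self):
        s = pop.summarize_ratios(np.ones(10), np.ones(10))
        assert s.median == 1.0
        assert s.p_median_vs_1 == 1.0
        assert s.n_significant == 0

    def test_counts_of_significant_ratios(self):
        s = pop.summarize_ratios(np.full(20, 2.0), np.full(20, 0.01))
        assert s.n_significant == 20
        assert s.n_significant_gt1 == 20
        assert s.fraction_significant_gt1 == 1.0

    def test_median_test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            ratios = np.exp(rng.normal(0.2, 0.5, size=8))
            s = pop.summarize_ratios(ratios, np.full(8, 0.5))
            assert s.p_median_vs_1 == pytest.approx(
                _signed_rank_oracle(np.log(ratios)), abs=1e-12)

    def test_order_invariance(self, rng):
        ratios = np.exp(rng.normal(0, 0.4, 15))
        ps = rng.uniform(0, 1, 15)
        a = pop.summarize_ratios(ratios, ps)
        perm = rng.permutation(15)
        b = pop.summarize_ratios(ratios[perm], ps[perm])
        assert a == b

    def test_empty_input_rejected(self):
        with pytest.raises(errors.InvalidInputError):
            pop.summarize_ratios([], [])

    def test_null_ratio_false_positive_rate(self, rng):
        # per-unit p-values simulated uniform under the null
        ps = rng.uniform(0, 1, 2000)
        s = pop.summarize_ratios(np.exp(rng.normal(0, 0.2, 2000)), ps)
        assert s.fraction_significant == pytest.approx(0.05, abs=0.015)


class TestCompareProportions:
    def test_equal_proportions_give_half(self):
        assert pop.compare_proportions(50, 100, 50, 100) == pytest.approx(0.5)

    def test_study_count_difference_is_significant(self):
        p = pop.compare_proportions(124, 298, 88, 298, alternative="greater")
        assert p < 0.05

    def test_wrong_direction_exceeds_half(self):
        p = pop.compare_proportions(88, 298, 124, 298, alternative="greater")
        assert p > 0.5

    def test_chi_square_near_fisher_for_small_counts(self):
        p_chi = pop.compare_proportions(8, 20, 3, 22, alternative="greater")
        p_fis = pop.compare_proportions(8, 20, 3, 22, alternative="greater",
                                        method="fisher")
        # documented approximation band: the chi-square p tracks Fisher's
        # exact p within a factor of a few on small tables
        assert 0.2 < p_chi / p_fis < 5.0

    def test_invalid_inputs(self):
        with pytest.raises(errors.InvalidInputError):
            pop.compare_proportions(5, 0, 1, 10)
        with pytest.raises(errors.InvalidInputError):
            pop.compare_proportions(11, 10, 1, 10)


class TestSixConditionComparison:
    def test_identical_conditions_give_p_one(self):
        df = pd.DataFrame({c: np.full(10, 1.5) for c in ["A", "B", "C"]})
        res = pop.six_condition_comparison(df)
        assert (res.p_matrix.to_numpy() == 1.0).all()

    def test_shifted_condition_detected_at_corrected_alpha(self, rng):
        base = rng.lognormal(0.2, 0.1, 20)
        df = pd.DataFrame({
            "S1_NO_GO": base * 1.5,
            "S1_UNCERTAIN": base,
            "S2_GO": base * rng.lognormal(0, 0.02, 20),
        })
        res = pop.six_condition_comparison(df)
        assert res.significant("S1_NO_GO", "S1_UNCERTAIN")
        assert res.significant("S1_NO_GO", "S2_GO")
        assert res.medians["S1_NO_GO"] > res.medians["S1_UNCERTAIN"]

    def test_pairwise_deletion_with_missing_units(self, rng):
        df = pd.DataFrame({
            "A": np.r_[rng.lognormal(0.5, 0.1, 10), np.nan],
            "B": np.r_[rng.lognormal(0.0, 0.1, 10), 2.0],
        })
        res = pop.six_condition_comparison(df)
        assert res.n_units.loc["A", "B"] == 10


class TestFalseAlarmContrasts:
    @staticmethod
    def _records(n_fa=8, fa_scale=0.7):
        rng = np.random.default_rng(2)
        n = 20
        correct = rng.lognormal(0.5, 0.1, n)
        return pd.DataFrame({
            "unit_id": np.arange(n),
            "freq": np.where(np.arange(n) % 2 == 0, 3000.0, 1000.0),
            "sig_during_s1": True,
            "sig_during_s2": True,
            "n_fa_s1": n_fa,
            "n_fa_s2": n_fa,
            "s1_nogo_fa": correct * fa_scale,
            "s1_nogo_correct": correct,
            "s2_nogo_fa": correct * fa_scale,
            "s2_nogo_correct": correct,
            "s2_go_correct": correct * fa_scale,
        })

    def test_go_like_fa_responses_give_expected_medians(self):
        out = pop.false_alarm_contrasts(self._records())
        assert out["s1_nogo_fa_vs_correct"].median == pytest.approx(0.7, rel=1e-6)
        assert out["s1_nogo_fa_vs_correct"].p_vs_1 < 0.05
        assert out["s2_nogo_fa_vs_correct_go"].median == pytest.approx(1.0, rel=1e-6)

    def test_identical_fa_and_correct_responses(self):
        out = pop.false_alarm_contrasts(self._records(fa_scale=1.0))
        assert out["s1_nogo_fa_vs_correct"].median == pytest.approx(1.0)

    def test_units_below_fa_threshold_excluded(self):
        out = pop.false_alarm_contrasts(self._records(n_fa=4))
        assert out == {}


class TestProbabilitySubset:
    def test_printed_probability_medians_give_ratio(self):
        sessions = pd.DataFrame({
            "session_id": [f"s{i}" for i in range(5)],
            "p_task1": 0.73,
            "p_task2": 0.27,
        })
        assert pop.median_probability_ratio(sessions) == pytest.approx(0.73 / 0.27)
        assert round(pop.median_probability_ratio(sessions), 2) == 2.70

    def test_constant_ratios_cannot_be_split(self):
        sessions = pd.DataFrame({
            "session_id": [f"s{i}" for i in range(6)],
            "p_task1": 0.73,
            "p_task2": 0.27,
        })
        units = pd.DataFrame({"session_id": ["s0"] * 3, "significant_gt1": True})
        with pytest.raises(errors.InvalidInputError):
            pop.probability_subset_analysis(sessions, units)

    def test_split_detects_subset_difference(self):
        sessions = pd.DataFrame({
            "session_id": [f"s{i}" for i in range(8)],
            "p_task1": [0.6, 0.62, 0.64, 0.66, 0.74, 0.76, 0.78, 0.80],
            "p_task2": 0.27,
        })
        rows = []
        for i in range(8):
            high = i >= 4
            for u in range(20):
                rows.append({"session_id": f"s{i}",
                             "significant_gt1": u < (14 if high else 4)})
        res = pop.probability_subset_analysis(sessions, pd.DataFrame(rows))
        assert res.prop_high > res.prop_low
        assert res.p_one_tailed < 0.01
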