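"""Window rates, condition ratios, permutation tests, PSTHs, traces, tuning."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import audassoc.spikes as spk
from audassoc import errors


class TestMeanRate:
    def test_count_over_window_length(self):
        spikes = np.array([0.01, 0.05, 0.10, 0.20, 0.24])
        assert spk.mean_rate(spikes, 0.0, 0.25) == pytest.approx(20.0)

    def test_empty_train_gives_zero(self):
        assert spk.mean_rate(np.array([]), 0.0, 0.25) == 0.0

    def test_half_open_boundary(self):
        spikes = np.array([0.0, 0.25])
        assert spk.mean_rate(spikes, 0.0, 0.25) == pytest.approx(4.0)  # only t=0


class TestAnalysisWindow:
    def test_during_window_length_and_before_abutment(self):
        during = spk.AnalysisWindow("t_s1_on", *spk.DURING_SPIKE_WINDOW, kind="DURING")
        before = spk.AnalysisWindow("t_s1_on", *spk.BEFORE_SPIKE_WINDOW, kind="BEFORE")
        assert during.length == pytest.approx(0.250)
        assert before.end_offset == 0.0
        assert during.resolve({"t_s1_on": 1.5}) == (1.5, 1.75)

    def test_bad_windows_rejected(self):
        with pytest.raises(errors.InvalidInputError):
            spk.AnalysisWindow("t_s1_on", 0.2, 0.1)
        with pytest.raises(errors.InvalidInputError):
            spk.AnalysisWindow("t_s1_on", -0.3, -0.05, kind="BEFORE")

    def test_missing_anchor(self):
        w = spk.AnalysisWindow("t_s2_on", 0.0, 0.25)
        with pytest.raises(errors.MissingEventError):
            w.resolve({"t_s2_on": float("nan")})


class TestConditionRatio:
    def test_identical_rates_give_one(self):
        assert spk.condition_ratio([10, 10, 10, 10, 10], [10, 10, 10, 10, 10]) == 1.0

    def test_mean_ratio(self):
        assert spk.condition_ratio([10, 20, 30, 20, 20], [10, 10, 10, 10, 10]) == 2.0

    def test_count_based_hand_arithmetic(self):
        # counts (6,4,5,5) and (3,2,3,4) in 0.25-s windows -> 20 / 12
        num = np.array([6, 4, 5, 5]) / 0.25
        den = np.array([3, 2, 3, 4]) / 0.25
        ratio = spk.condition_ratio(num, den, min_trials=4)
        assert ratio == pytest.approx(20.0 / 12.0, abs=1e-9)

    def test_min_trials_enforced(self):
        with pytest.raises(errors.InvalidInputError):
            spk.condition_ratio([10, 10], [10, 10, 10, 10, 10])

    def test_flooring_of_silent_denominator(self):
        ratio = spk.condition_ratio([10.0] * 5, [0.0] * 5, floor=0.1)
        assert ratio == pytest.approx(100.0)

    @given(c=st.floats(0.1, 50.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(5)
        a = rng.poisson(6.0, 8) / 0.25
        b = rng.poisson(4.0, 8) / 0.25 + 0.4  # keep above floor under scaling
        r1 = spk.condition_ratio(a, b)
        r2 = spk.condition_ratio(c * a, c * b, floor=0.1 * c)
        assert r2 == pytest.approx(r1, rel=1e-9)


def _brute_force_permutation_p(a, b, floor=0.1):
    """Independent exhaustive oracle over all C(n, na) label assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def stat(idx):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        return abs(math.log(max(pooled[sel].mean(), floor)
                            / max(pooled[~sel].mean(), floor)))

    obs = stat(range(n_a))
    assignments = list(combinations(range(len(pooled)), n_a))
    count = sum(stat(idx) >= obs - 1e-12 for idx in assignments)
    return count / len(assignments)


class TestPermutationTest:
    def test_identical_lists_give_p_one(self):
        p = spk.permutation_test_ratio([10, 10, 10], [10, 10, 10])
        assert p == 1.0

    def test_exhaustive_example(self):
        p = spk.permutation_test_ratio([30, 32, 31], [10, 11, 12])
        assert p == pytest.approx(2 / 20)

    def test_exhaustive_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            a = rng.poisson(5.0, 3) / 0.25
            b = rng.poisson(3.0, 3) / 0.25
            assert spk.permutation_test_ratio(a, b) == pytest.approx(
                _brute_force_permutation_p(a, b), abs=1e-12)

    def test_monte_carlo_detects_a_clear_effect(self, rng):
        a = rng.poisson(15.0, 40) / 0.25
        b = rng.poisson(5.0, 40) / 0.25
        p = spk.permutation_test_ratio(a, b, n_perm=999, rng=rng)
        assert p < 0.01

    def test_scale_invariance_of_p(self, rng):
        a = rng.poisson(8.0, 4) / 0.25
        b = rng.poisson(4.0, 4) / 0.25 + 0.4
        p1 = spk.permutation_test_ratio(a, b)
        p2 = spk.permutation_test_ratio(3.0 * a, 3.0 * b, floor=0.3)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_too_few_trials_rejected(self):
        with pytest.raises(errors.InvalidInputError):
            spk.permutation_test_ratio([1.0], [1.0, 2.0])


class TestPairedPermutation:
    def test_no_difference_gives_large_p(self):
        p = spk.paired_permutation_test([5, 6, 7, 8], [5, 6, 7, 8])
        assert p == 1.0

    def test_consistent_difference_gives_small_p(self):
        x = np.array([10.0, 11, 12, 13, 14, 15, 16, 17, 18])
        p = spk.paired_permutation_test(x + 5.0, x)  # exhaustive over 2^9 sign flips
        assert p == pytest.approx(2 / 512)


class TestResponsiveness:
    def test_strongly_evoked_unit_is_responsive(self, rng):
        before = rng.poisson(5.0, 30) / 0.25
        during = rng.poisson(20.0, 30) / 0.25
        flag, p = spk.is_responsive({"S1_NO_GO": (before, during)}, rng=rng)
        assert flag and p["S1_NO_GO"] < 0.05

    def test_silent_unit_is_not_responsive(self, rng):
        zeros = np.zeros(20)
        flag, _ = spk.is_responsive({"S1_NO_GO": (zeros, zeros)}, rng=rng)
        assert not flag


class TestPsth:
    def test_single_repeated_spike_time(self):
        trains = [np.array([0.123])] * 100
        centers, rates = spk.psth(trains, 0.0, 0.5, bin_width=0.010)
        assert rates[12] == pytest.approx(100.0)  # 1 spike / (100 trials x 10 ms)
        assert np.count_nonzero(rates) == 1

    def test_empty_input_gives_zero_bins(self):
        centers, rates = spk.psth([], 0.0, 0.2)
        assert np.all(rates == 0.0) and len(rates) == 20

    def test_homogeneous_rate_recovered(self, rng):
        trains = [np.sort(rng.uniform(0, 1, rng.poisson(20))) for _ in range(400)]
        _, rates = spk.psth(trains, 0.0, 1.0)
        assert rates.mean() == pytest.approx(20.0, rel=0.05)


class TestGeometricAverage:
    def test_two_units(self):
        out = spk.geometric_average_normalized(
            np.array([[20.0], [80.0]]), np.array([10.0, 10.0]))
        assert out[0] == pytest.approx(4.0)  # sqrt(2 * 8)

    def test_identical_traces_pass_through(self):
        trace = np.array([[10.0, 20.0, 5.0]] * 4)
        out = spk.geometric_average_normalized(trace, np.full(4, 10.0))
        np.testing.assert_allclose(out, trace[0] / 10.0)

    def test_matches_log_domain_oracle(self, rng):
        psths = rng.uniform(0.0, 40.0, size=(7, 30))
        baselines = rng.uniform(0.0, 20.0, size=7)
        floor = 0.1
        oracle = np.exp(np.mean(
            np.log(np.maximum(psths, floor) / np.maximum(baselines, floor)[:, None]),
            axis=0))
        out = spk.geometric_average_normalized(psths, baselines)
        np.testing.assert_allclose(out, oracle, atol=1e-12, rtol=0)

    def test_unit_order_invariance(self, rng):
        psths = rng.uniform(1.0, 40.0, size=(6, 10))
        baselines = rng.uniform(1.0, 20.0, size=6)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            spk.geometric_average_normalized(psths, baselines),
            spk.geometric_average_normalized(psths[perm], baselines[perm]),
            atol=1e-12)

    def test_no_units_is_an_error(self):
        with pytest.raises(errors.InvalidInputError):
            spk.geometric_average_normalized(np.empty((0, 5)), np.empty(0))


class TestPerBinTest:
    def test_injected_offset_concentrates_stars(self, rng):
        n_units, n_bins = 14, 40
        a = rng.lognormal(0.0, 0.1, size=(n_units, n_bins))
        b = a * rng.lognormal(0.0, 0.02, size=(n_units, n_bins))
        b[:, 7:26] *= 1.6
        p = spk.per_bin_condition_test(b, a)
        stars = p < 0.05
        assert stars[7:26].mean() > 0.9
        assert stars[[*range(7), *range(26, n_bins)]].mean() < 0.3

    def test_single_unit_is_skipped(self):
        assert spk.per_bin_condition_test(np.ones((1, 5)), np.ones((1, 5))) is None


class TestBestFrequency:
    def test_octave_distance(self):
        assert spk.octave_distance(3000.0, 3000.0) == 0.0
        assert spk.octave_distance(6000.0, 3000.0) == pytest.approx(1.0)
        assert spk.octave_distance(1500.0, 3000.0) == pytest.approx(1.0)

    def test_noiseless_recovery_within_one_frequency_step(self):
        import audassoc.synth as sy

        unit = sy.neutral_unit(best_frequency=2000.0, evoked_gain=3.0,
                               tuning_bandwidth=1.0)
        freqs = np.repeat(sy.TUNING_FREQUENCIES, 3)
        evoked = np.array([
            unit.baseline_rate * (1 + (unit.evoked_gain - 1) * unit.tuning(f))
            for f in freqs])
        base = np.full_like(evoked, unit.baseline_rate)
        bf = spk.best_frequency(freqs, evoked, base)
        step = 8.0 / 39.0  # octaves between adjacent tuning tones
        assert spk.octave_distance(bf, 2000.0) <= step + 1e-9

    def test_untuned_unit_returns_none(self):
        freqs = np.array([1000.0, 2000.0])
        assert spk.best_frequency(freqs, np.zeros(2), np.full(2, 10.0)) is None
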