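"""Synthetic session generator: rate profiles, thinning, session structure."""

import numpy as np
import pytest

import audassoc.synth as sy
from audassoc import errors
from audassoc.task import Outcome, Task


def _trial(task, s1_freq, s2_freq, phase="task", outcome="CORRECT_REJECTION",
           t_release=np.nan, t_s1=0.5):
    from audassoc.task import TaskSpec, ToneSequence, label_sequence

    seq = ToneSequence(s1_freq, s2_freq, s1_onset=t_s1)
    s1l, s2l = label_sequence(TaskSpec(Task(task)), seq)
    return dict(
        phase=phase, task=task, s1_freq=float(s1_freq), s2_freq=float(s2_freq),
        t_s1_on=t_s1, t_s2_on=t_s1 + 1.0, tone_duration=0.2,
        s1_label=s1l.value, s2_label=s2l.value, outcome=outcome,
        t_release=t_release,
    )


GRID = np.arange(0.0, 2.5, sy.PROFILE_DT)


class TestRateProfile:
    def test_all_effects_off_profiles_match_across_tasks(self):
        unit = sy.neutral_unit(evoked_gain=3.0, best_frequency=3000.0)
        p1 = sy.build_rate_profile(unit, _trial("TASK1", 3000, 1000), GRID)
        p2 = sy.build_rate_profile(unit, _trial("TASK2", 3000, 1000), GRID)
        np.testing.assert_allclose(p1.rates, p2.rates)

    def test_nogo_gain_window_ratio_matches_integrated_closed_form(self):
        """The during-window ratio equals the time integral of the gated gain.

        The no-go differential switches on 70 ms after tone onset, so over
        the 250-ms analysis window the Task2/Task1 mean-rate ratio for a
        3-kHz S1 is (70 ms + 180 ms * gain) / 250 ms.
        """
        gain = 1.3
        base = dict(evoked_gain=3.0, best_frequency=3000.0)
        t_s1 = 0.5
        for g_test, expected in ((1.0, 1.0), (gain, (0.070 + 0.180 * gain) / 0.250)):
            unit = sy.neutral_unit(nogo_gain=g_test, **base)
            # S1 at 3 kHz is S1-uncertain in Task 1 and S1-no-go in Task 2
            p_t1 = sy.build_rate_profile(unit, _trial("TASK1", 3000, 1000), GRID)
            p_t2 = sy.build_rate_profile(unit, _trial("TASK2", 3000, 1000), GRID)
            ratio = p_t2.mean(t_s1, t_s1 + 0.25) / p_t1.mean(t_s1, t_s1 + 0.25)
            assert ratio == pytest.approx(expected, rel=1e-9)

    def test_nogo_differential_absent_on_false_alarm_trials(self):
        unit = sy.neutral_unit(nogo_gain=1.5, evoked_gain=3.0, best_frequency=3000.0)
        correct = sy.build_rate_profile(unit, _trial("TASK2", 3000, 1000), GRID)
        fa = sy.build_rate_profile(
            unit, _trial("TASK2", 3000, 1000, outcome="FALSE_ALARM"), GRID)
        assert fa.mean(0.5, 0.75) < correct.mean(0.5, 0.75)
        assert fa.mean(0.5, 0.57) == pytest.approx(correct.mean(0.5, 0.57))

    def test_forward_suppression_halves_the_evoked_increment(self):
        unit = sy.neutral_unit(
            forward_suppression=0.5, evoked_gain=3.0, best_frequency=3000.0)
        prof = sy.build_rate_profile(unit, _trial("TASK1", 3000, 3000), GRID)
        base = unit.baseline_rate
        s1_extra = prof.mean(0.5, 0.75) - base
        s2_extra = prof.mean(1.5, 1.75) - base
        assert s2_extra == pytest.approx(0.5 * s1_extra, rel=1e-9)

    def test_adaptation_scales_with_tone_probability(self):
        unit = sy.neutral_unit(
            adaptation_strength=0.5, evoked_gain=3.0, best_frequency=3000.0)
        common = _trial("TASK1", 3000, 1000)
        rare = sy.build_rate_profile(unit, common, GRID, tone_probs={3000.0: 0.27})
        freq = sy.build_rate_profile(unit, common, GRID, tone_probs={3000.0: 0.73})
        assert rare.mean(0.5, 0.75) > freq.mean(0.5, 0.75)

    def test_motor_ramp_peaks_before_release(self):
        unit = sy.neutral_unit(motor_ramp_amp=30.0, evoked_gain=1.0)
        trial = _trial("TASK1", 3000, 3000, outcome="HIT", t_release=2.0)
        prof = sy.build_rate_profile(unit, trial, GRID)
        peak_t = GRID[np.argmax(prof.rates)]
        assert 1.75 <= peak_t <= 1.85  # ~200 ms before the release at 2.0 s

    def test_cue_offset_is_tonic_and_task_specific(self):
        unit = sy.neutral_unit(cue_offset=5.0, evoked_gain=1.0)
        p1 = sy.build_rate_profile(unit, _trial("TASK1", 3000, 1000), GRID)
        p2 = sy.build_rate_profile(unit, _trial("TASK2", 3000, 1000), GRID)
        assert p1.mean(0.0, 0.4) == pytest.approx(unit.baseline_rate)
        assert p2.mean(0.0, 0.4) == pytest.approx(unit.baseline_rate + 5.0)


class TestThinning:
    def test_poisson_mean_recovered(self, rng):
        grid = np.arange(0.0, 1.0, sy.PROFILE_DT)
        profile = sy.RateProfile(grid, np.full_like(grid, 20.0))
        counts = [len(sy.simulate_spike_train(profile, rng)) for _ in range(10_000)]
        assert np.mean(counts) == pytest.approx(20.0, abs=3 * np.sqrt(20.0 / 10_000))

    def test_zero_profile_gives_empty_train(self, rng):
        grid = np.arange(0.0, 1.0, sy.PROFILE_DT)
        profile = sy.RateProfile(grid, np.zeros_like(grid))
        assert len(sy.simulate_spike_train(profile, rng)) == 0

    def test_thinning_respects_profile_support(self, rng):
        grid = np.arange(0.0, 1.0, sy.PROFILE_DT)
        rates = np.where(grid >= 0.5, 50.0, 0.0)
        spikes = sy.simulate_spike_train(sy.RateProfile(grid, rates), rng)
        assert len(spikes) > 0
        assert spikes.min() >= 0.5

    def test_unbounded_profile_rejected(self):
        grid = np.arange(0.0, 1.0, sy.PROFILE_DT)
        rates = np.full_like(grid, np.inf)
        with pytest.raises(errors.InvalidInputError):
            sy.RateProfile(grid, rates)


class TestLfpSimulation:
    def test_noiseless_zero_amplitude_gives_zero_trace(self, rng):
        params = sy.LfpParams(noise_sd=0.0, deflection_amps=(0.0, 0.0))
        trace = sy.simulate_lfp(params, _trial("TASK1", 3000, 1000), rng, 0.0, 2500)
        assert np.allclose(trace, 0.0)

    def test_noiseless_single_deflection_extremum_equals_amplitude(self, rng):
        params = sy.LfpParams(noise_sd=0.0, deflection_amps=(-0.25, 0.0))
        trace = sy.simulate_lfp(params, _trial("TASK1", 3000, 1000), rng, 0.0, 2500)
        assert np.max(np.abs(trace)) == pytest.approx(0.25, rel=1e-6)

    def test_nogo_gain_raises_rms_for_nogo_label(self, rng):
        from audassoc.lfp import rms

        params = sy.LfpParams(noise_sd=0.0, nogo_gain=1.5)
        # S1 at 3 kHz: no-go label in Task 2, uncertain in Task 1
        nogo = sy.simulate_lfp(params, _trial("TASK2", 3000, 1000), rng, 0.0, 2500)
        go = sy.simulate_lfp(params, _trial("TASK1", 3000, 1000), rng, 0.0, 2500)
        assert rms(nogo, 1000.0, 0.0, (0.5, 1.0)) > rms(go, 1000.0, 0.0, (0.5, 1.0))

    def test_param_validation(self):
        with pytest.raises(errors.InvalidInputError):
            sy.LfpParams(sampling_rate=100.0)
        with pytest.raises(errors.InvalidInputError):
            sy.LfpParams(deflection_latencies=(0.03, 0.7))


class TestSessionGeneration:
    def test_stratified_go_counts_are_exact_per_block(self):
        cfg = sy.SessionConfig(n_blocks_per_task=1, trials_per_block=140,
                               n_units=1, n_lfp_sites=0, include_passive=False,
                               include_tuning=False, seed=3)
        session = sy.generate_session(cfg, units=[sy.neutral_unit()])
        task = session.events[session.events["phase"] == "task"]
        for _, block in task.groupby("block_id"):
            assert (block["required"] == "GO").sum() == int(0.60 * 140)

    def test_zero_fa_rate_yields_no_false_alarms(self):
        cfg = sy.SessionConfig(n_blocks_per_task=1, trials_per_block=60,
                               fa_rate_s1_family=0.0, fa_rate_s2_family=0.0,
                               n_units=1, n_lfp_sites=0, include_passive=False,
                               include_tuning=False, seed=3)
        session = sy.generate_session(cfg, units=[sy.neutral_unit()])
        assert (session.events["outcome"] == Outcome.FALSE_ALARM.value).sum() == 0

    def test_fixed_seed_reproduces_the_bundle(self):
        cfg = sy.SessionConfig(n_blocks_per_task=1, trials_per_block=40,
                               n_units=2, n_lfp_sites=1,
                               passive_trials_per_block=20, seed=11)
        units = [sy.neutral_unit(), sy.neutral_unit(baseline_rate=10.0)]
        s1 = sy.generate_session(cfg, units=units)
        s2 = sy.generate_session(cfg, units=units)
        assert s1.events.equals(s2.events)
        for u in s1.spikes:
            for t in s1.spikes[u]:
                np.testing.assert_array_equal(s1.spikes[u][t], s2.spikes[u][t])
        np.testing.assert_array_equal(s1.lfp, s2.lfp)

    def test_adding_units_does_not_perturb_existing_ones(self):
        cfg = sy.SessionConfig(n_blocks_per_task=1, trials_per_block=30,
                               n_units=1, n_lfp_sites=0, include_passive=False,
                               include_tuning=False, seed=11)
        base = [sy.neutral_unit()]
        s_small = sy.generate_session(cfg, units=base)
        s_big = sy.generate_session(cfg, units=base + [sy.neutral_unit(baseline_rate=5.0)])
        for t in s_small.spikes[0]:
            np.testing.assert_array_equal(s_small.spikes[0][t], s_big.spikes[0][t])

    def test_session_includes_passive_and_tuning_blocks(self, small_session):
        phases = set(small_session.events["phase"])
        assert phases == {"task", "passive", "tuning"}
        tuning = small_session.events[small_session.events["phase"] == "tuning"]
        assert len(tuning) == 400  # 40 frequencies x 10 repetitions
        assert len(np.unique(tuning["s1_freq"])) == 40
        # passive trials have no behavioral outcome
        passive = small_session.events[small_session.events["phase"] == "passive"]
        assert (passive["outcome"] == "").all()

    def test_alternating_task_blocks(self, small_session):
        task = small_session.events[small_session.events["phase"] == "task"]
        block_tasks = task.groupby("block_id")["task"].first().tolist()
        assert all(a != b for a, b in zip(block_tasks, block_tasks[1:]))

    def test_config_validation(self):
        with pytest.raises(errors.ConfigError):
            sy.SessionConfig(go_fraction=0.9)
        with pytest.raises(errors.ConfigError):
            sy.SessionConfig(nogo_sequence_probs=(0.2, 0.2, 0.2))
        with pytest.raises(errors.ConfigError):
            sy.SessionConfig(fa_rate_s1_family=1.2)

    def test_preset_tone_probabilities(self):
        cfg = sy.paper_like_config()
        assert cfg.tone_probability(Task.TASK1, 3000.0) == pytest.approx(0.73)
        assert cfg.tone_probability(Task.TASK2, 3000.0) == pytest.approx(0.27)
        assert cfg.tone_probability(Task.TASK1, 1000.0) == pytest.approx(0.27)
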