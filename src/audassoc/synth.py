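"""Synthetic go/no-go sessions with the statistical structure the analysis assumes.

The generator emulates the study conditions the analysis pipeline was built
for: two tasks in alternating blocks of ~140 trials, the go response
required in ~60% of trials, condition-dependent evoked-rate gains (stronger
responses to tones that signal the no-go response, switching on ~70 ms
after tone onset), tonic pre-tone cue offsets, stimulus-specific adaptation
driven by each block's tone probabilities, forward suppression of a
repeated S2, pre-release motor ramps, false alarms at configurable rates
per no-go sequence family, passive blocks replaying the two probability
schedules, and a 40-tone best-frequency block.

Spiking is an inhomogeneous Poisson process sampled by thinning against a
piecewise-constant rate profile on a 1-ms grid; LFPs are sums of
Gaussian-windowed evoked deflections plus 1/f-shaped Gaussian noise
band-limited to the recording bandwidth (1-140 Hz).

Randomness is split into per-(stream, unit, trial) substreams derived from
one top-level seed, so adding units or LFP sites never perturbs the data
already generated for existing ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task as tm
from .errors import ConfigError, InvalidInputError
from .io import Session

logger = logging.getLogger(__name__)

__all__ = [
    "UnitParams",
    "LfpParams",
    "SessionConfig",
    "RateProfile",
    "build_rate_profile",
    "simulate_spike_train",
    "simulate_lfp",
    "generate_session",
    "neutral_unit",
    "paper_like_units",
    "paper_like_config",
    "TUNING_FREQUENCIES",
]

#: 40 tuning-block frequencies, log-spaced over 8 octaves (0.0625-16 kHz).
TUNING_FREQUENCIES = 62.5 * 2.0 ** (np.arange(40) * 8.0 / 39.0)

#: Grid step (s) for rate profiles.
PROFILE_DT = 0.001

# Stream tags for substream derivation.
_STREAM_EVENTS = 1
_STREAM_SPIKES = 2
_STREAM_LFP = 3


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for a (stream, ...) key under one top seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


@dataclass
class UnitParams:
    """Response parameters of one simulated multiunit.

    ``evoked_gain`` multiplies the ongoing rate during a tone (gated by the
    unit's Gaussian log-frequency tuning); ``nogo_gain`` further multiplies
    the during-tone rate, from 70 ms after onset, when the tone's label is
    S1-no-go or S2-no-go on a correctly performed task trial.
    ``cue_offset`` is a tonic additive rate shift present throughout Task 2
    trials (the two tasks are cued by different LEDs).
    ``adaptation_strength`` scales the evoked component down in proportion
    to the scheduled probability of the tone's frequency (stimulus-specific
    adaptation); ``forward_suppression`` shrinks the S2 response when S2
    repeats S1's frequency.
    """

    baseline_rate: float = 20.0
    best_frequency: float = 3000.0
    tuning_bandwidth: float = 1.5  # Gaussian sigma, octaves
    evoked_gain: float = 3.0
    nogo_gain: float = 1.0
    cue_offset: float = 0.0  # spikes/s, added in Task 2
    adaptation_strength: float = 0.0
    forward_suppression: float = 0.0
    motor_ramp_amp: float = 0.0  # spikes/s at ramp peak

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise InvalidInputError("baseline_rate must be > 0")
        if self.evoked_gain <= 0 or self.nogo_gain <= 0:
            raise InvalidInputError("gains must be > 0")
        for name in ("adaptation_strength", "forward_suppression"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        if self.best_frequency <= 0 or self.tuning_bandwidth <= 0:
            raise InvalidInputError("best_frequency and tuning_bandwidth must be > 0")

    def tuning(self, freq: float) -> float:
        """Gaussian tuning weight in log2-frequency space, 1 at best frequency."""
        octaves = math.log2(freq / self.best_frequency)
        return math.exp(-0.5 * (octaves / self.tuning_bandwidth) ** 2)


@dataclass
class LfpParams:
    """Parameters of one simulated LFP site.

    The evoked potential per tone is the sum of two Gaussian-windowed
    deflections (amplitudes in mV, latencies/widths in s); the second
    deflection is scaled by ``nogo_gain`` when the tone signals the no-go
    response, mirroring the observation that condition differences are most
    pronounced during the second negative deflection.  Noise is Gaussian
    with power ~ 1/f^exponent, band-limited to 1-140 Hz.
    """

    sampling_rate: float = 1000.0
    deflection_amps: tuple[float, float] = (-0.060, -0.090)
    deflection_latencies: tuple[float, float] = (0.030, 0.110)
    deflection_widths: tuple[float, float] = (0.010, 0.035)
    nogo_gain: float = 1.0
    noise_sd: float = 0.020
    noise_exponent: float = 1.0
    noise_band: tuple[float, float] = (1.0, 140.0)

    def __post_init__(self) -> None:
        if self.sampling_rate < 200.0:
            raise InvalidInputError("sampling_rate must be >= 200 Hz")
        for lat in self.deflection_latencies:
            if not 0.0 <= lat <= 0.5:
                raise InvalidInputError("deflection latencies must lie in [0, 0.5] s")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.nogo_gain <= 0:
            raise InvalidInputError("nogo_gain must be > 0")


@dataclass
class SessionConfig:
    """Structure of one synthetic session.

    ``nogo_sequence_probs`` are the block-schedule probabilities of the
    three no-go sequences, in the order ``(go, other)``, ``(other, go)``,
    ``(other, other)`` where *go* is the task's go frequency; the go
    sequence itself occupies ``go_fraction``.  The defaults (0.60 with
    split 0.13/0.13/0.14) put the scheduled per-tone probability of the
    task's go frequency at exactly 0.73 in its own task and 0.27 in the
    other, the probability structure of the study the generator emulates.
    """

    n_blocks_per_task: int = 2
    trials_per_block: int = 140
    go_fraction: float = 0.60
    nogo_sequence_probs: tuple[float, float, float] = (0.13, 0.13, 0.14)
    block_go_jitter: float = 0.0  # uniform half-width on per-block go fraction
    fa_rate_s1_family: float = 0.16
    fa_rate_s2_family: float = 0.05
    miss_rate: float = 0.05
    n_units: int = 12
    n_lfp_sites: int = 4
    include_passive: bool = True
    passive_blocks_per_schedule: int = 1
    passive_trials_per_block: int = 100
    include_tuning: bool = True
    response_window: tuple[float, float] = tm.RESPONSE_WINDOW_MONKEY_L
    tone_duration: float = 0.200
    onset_interval: float = 1.000
    nogo_onset_delay: float = 0.070  # no-go differential latency after tone onset
    ramp_onset: float = 0.300  # motor ramp start before release (s)
    ramp_peak: float = 0.200  # motor ramp peak before release (s)
    evoked_offset_margin: float = 0.050  # evoked response outlasts tone by this much
    lfp_pre: float = 0.600  # LFP coverage before S1 onset (s)
    lfp_post: float = 1.000  # LFP coverage after S2 offset (s)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.50 <= self.go_fraction <= 0.77:
            raise ConfigError("go_fraction must lie in the admissible range [0.50, 0.77]")
        probs = (self.go_fraction, *self.nogo_sequence_probs)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                "go_fraction plus the three no-go sequence probabilities must sum to 1"
            )
        for name in ("fa_rate_s1_family", "fa_rate_s2_family", "miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.trials_per_block < 4:
            raise ConfigError("trials_per_block must be >= 4")
        if self.n_blocks_per_task < 1:
            raise ConfigError("n_blocks_per_task must be >= 1")

    def sequence_probs(self, task: tm.Task) -> dict[tuple[float, float], float]:
        """Scheduled probability of each (S1, S2) frequency pair under a task."""
        spec = tm.TaskSpec(task, response_window=self.response_window)
        g, o = spec.go_frequency, spec.other_frequency
        p_sn, p_ng, p_nn = self.nogo_sequence_probs
        return {(g, g): self.go_fraction, (g, o): p_sn, (o, g): p_ng, (o, o): p_nn}

    def tone_probability(self, task: tm.Task, freq: float) -> float:
        """Scheduled per-tone probability of ``freq`` under a task's schedule."""
        total = 0.0
        for (f1, f2), p in self.sequence_probs(task).items():
            total += p * ((f1 == freq) + (f2 == freq)) / 2.0
        return total


def neutral_unit(**overrides) -> UnitParams:
    """Unit with every condition-dependent modulation switched off."""
    params = dict(
        nogo_gain=1.0,
        cue_offset=0.0,
        adaptation_strength=0.0,
        forward_suppression=0.0,
        motor_ramp_amp=0.0,
    )
    params.update(overrides)
    return UnitParams(**params)


def paper_like_units(n: int, rng: np.random.Generator, **overrides) -> list[UnitParams]:
    """Heterogeneous population with association, cue, context and motor effects.

    Effect sizes are chosen for statistical power of the downstream tests,
    not fitted to any recording: best frequencies log-uniform over 1-8 kHz,
    no-go gains lognormal around 1.3, small tonic cue offsets of either
    sign.  Adaptation and forward suppression are kept weak: the paradigm
    separates repeated tones by 800 ms, by which time cortical forward
    suppression has largely recovered, and in this paradigm the acoustic
    context accounts for only a minority of the condition differences, so
    the association effect must dominate the context effects.
    """
    units = []
    for _ in range(int(n)):
        params = dict(
            baseline_rate=float(rng.uniform(10.0, 30.0)),
            best_frequency=float(2.0 ** rng.uniform(10.0, 13.0)),  # 1-8 kHz
            tuning_bandwidth=float(rng.uniform(1.0, 2.0)),
            evoked_gain=float(rng.uniform(2.0, 4.0)),
            nogo_gain=float(np.exp(rng.normal(np.log(1.3), 0.08))),
            cue_offset=float(rng.normal(0.0, 1.0)),
            adaptation_strength=float(rng.uniform(0.05, 0.2)),
            forward_suppression=float(rng.uniform(0.0, 0.15)),
            motor_ramp_amp=float(rng.uniform(5.0, 15.0)),
        )
        params.update(overrides)
        units.append(UnitParams(**params))
    return units


def paper_like_config(**overrides) -> SessionConfig:
    """Session preset emulating the study's block and probability structure."""
    return SessionConfig(**overrides)


def session_config_from_dict(data: dict) -> SessionConfig:
    """Build a SessionConfig from a plain mapping (e.g. parsed YAML)."""
    kwargs = dict(data)
    for key, f in SessionConfig.__dataclass_fields__.items():
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    unknown = set(kwargs) - set(SessionConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown session config keys: {sorted(unknown)}")
    return SessionConfig(**kwargs)


@dataclass
class RateProfile:
    """Piecewise-constant firing-rate profile on a regular grid.

    ``rates[i]`` applies on the half-open interval
    ``[t_grid[i], t_grid[i] + dt)``.
    """

    t_grid: np.ndarray
    rates: np.ndarray
    dt: float = PROFILE_DT

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.t_grid.shape != self.rates.shape:
            raise InvalidInputError("t_grid and rates must have equal shape")
        if not np.all(np.isfinite(self.rates)):
            raise InvalidInputError("rate profile must be finite (bounded)")
        if np.any(self.rates < 0):
            raise InvalidInputError("rate profile must be nonnegative")

    @property
    def t_end(self) -> float:
        return float(self.t_grid[-1] + self.dt)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.clip(
            np.searchsorted(self.t_grid, t, side="right") - 1, 0, len(self.t_grid) - 1
        )
        out = self.rates[idx]
        out = np.where((t < self.t_grid[0]) | (t >= self.t_end), 0.0, out)
        return out

    def mean(self, t0: float, t1: float) -> float:
        """Time-averaged rate over [t0, t1) (grid-aligned windows are exact)."""
        mask = (self.t_grid >= t0 - 1e-12) & (self.t_grid < t1 - 1e-12)
        if not mask.any():
            return 0.0
        return float(self.rates[mask].mean())


def build_rate_profile(
    unit: UnitParams,
    trial: dict | pd.Series,
    t_grid: np.ndarray,
    tone_probs: dict[float, float] | None = None,
    config: SessionConfig | None = None,
) -> RateProfile:
    """Closed-form rate profile for one unit on one trial.

    ``trial`` is a mapping with the events-table fields (``phase``,
    ``task``, ``s1_freq``/``s2_freq``, ``t_s1_on``/``t_s2_on``,
    ``tone_duration``, ``s1_label``/``s2_label``, ``outcome``,
    ``t_release``).  ``tone_probs`` maps frequency to its scheduled
    probability in the trial's block (used by adaptation); omit for
    probability-independent profiles.

    The profile is baseline (+ tonic cue offset in Task 2) with a
    multiplicative evoked step during each tone (onset to offset + 50 ms),
    scaled by tuning, adaptation and forward suppression; the no-go
    differential (``nogo_gain``) switches on 70 ms after tone onset on
    correctly performed task trials only -- on false-alarm trials the
    response is go-like.  A triangular motor ramp is added before the bar
    release on trials with a release.  Negative intermediate rates are
    clipped at zero and logged.
    """
    cfg = config or SessionConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    get = trial.get if isinstance(trial, dict) else lambda k, d=None: trial.get(k, d)
    phase = get("phase", "task")
    task = get("task", None)
    outcome = get("outcome", "")
    is_task = phase == "task"

    base = unit.baseline_rate
    if is_task and task == tm.Task.TASK2.value:
        base = base + unit.cue_offset
    rates = np.full_like(t_grid, base, dtype=float)

    tone_dur = float(get("tone_duration", cfg.tone_duration))
    tones = []
    for pos, fkey, tkey, lkey in (
        ("S1", "s1_freq", "t_s1_on", "s1_label"),
        ("S2", "s2_freq", "t_s2_on", "s2_label"),
    ):
        freq = get(fkey, np.nan)
        onset = get(tkey, np.nan)
        if freq is None or onset is None:
            continue
        freq, onset = float(freq), float(onset)
        if math.isnan(freq) or math.isnan(onset):
            continue
        tones.append((pos, freq, onset, get(lkey, "") or ""))

    s1_freq = tones[0][1] if tones else np.nan
    for pos, freq, onset, label in tones:
        span = (t_grid >= onset - 1e-12) & (t_grid < onset + tone_dur + cfg.evoked_offset_margin - 1e-12)
        tun = unit.tuning(freq)
        adapt = 1.0
        if tone_probs is not None and unit.adaptation_strength > 0:
            adapt = 1.0 - unit.adaptation_strength * float(tone_probs.get(freq, 0.0))
        fwd = 1.0
        if pos == "S2" and freq == s1_freq:
            fwd = 1.0 - unit.forward_suppression
        rates[span] *= 1.0 + (unit.evoked_gain - 1.0) * tun * adapt * fwd
        nogo = label in (tm.Condition.S1_NO_GO.value, tm.Condition.S2_NO_GO.value)
        if is_task and nogo and outcome != tm.Outcome.FALSE_ALARM.value:
            late = span & (t_grid >= onset + cfg.nogo_onset_delay - 1e-12)
            rates[late] *= unit.nogo_gain

    t_release = get("t_release", np.nan)
    if (
        is_task
        and unit.motor_ramp_amp > 0
        and t_release is not None
        and not math.isnan(float(t_release))
    ):
        rel = float(t_release)
        up = (t_grid >= rel - cfg.ramp_onset) & (t_grid < rel - cfg.ramp_peak)
        down = (t_grid >= rel - cfg.ramp_peak) & (t_grid < rel)
        rise = cfg.ramp_onset - cfg.ramp_peak
        rates[up] += unit.motor_ramp_amp * (t_grid[up] - (rel - cfg.ramp_onset)) / rise
        rates[down] += unit.motor_ramp_amp * (rel - t_grid[down]) / cfg.ramp_peak

    n_neg = int(np.sum(rates < 0))
    if n_neg:
        logger.warning("clipping %d negative rate samples to 0", n_neg)
        rates = np.clip(rates, 0.0, None)
    return RateProfile(t_grid, rates)


def simulate_spike_train(profile: RateProfile, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning against the profile supremum."""
    sup = float(profile.rates.max(initial=0.0))
    if not math.isfinite(sup):
        raise InvalidInputError("rate profile must be bounded")
    if sup <= 0.0:
        return np.empty(0)
    t0, t1 = float(profile.t_grid[0]), profile.t_end
    n = rng.poisson(sup * (t1 - t0))
    candidates = np.sort(rng.uniform(t0, t1, size=n))
    keep = rng.random(n) < profile(candidates) / sup
    return candidates[keep]


def _colored_noise(
    n: int,
    sampling_rate: float,
    sd: float,
    exponent: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with power ~ 1/f^exponent, band-limited to ``band``."""
    if sd <= 0.0:
        return np.zeros(n)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    gain = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    gain[in_band] = freqs[in_band] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * gain, n=n)
    std = x.std()
    if std > 0:
        x *= sd / std
    return x


def simulate_lfp(
    params: LfpParams,
    trial: dict | pd.Series,
    rng: np.random.Generator,
    t0: float,
    n_samples: int,
    tone_duration: float | None = None,
) -> np.ndarray:
    """One trial's LFP trace: evoked deflections per tone plus colored noise.

    Samples are taken at ``t0 + k / sampling_rate`` on the trial clock.
    The second deflection is scaled by ``params.nogo_gain`` for tones
    labeled no-go on correctly performed task trials (go-like on false
    alarms, matching the spiking generator).
    """
    get = trial.get if isinstance(trial, dict) else lambda k, d=None: trial.get(k, d)
    t = t0 + np.arange(n_samples) / params.sampling_rate
    trace = np.zeros(n_samples)
    is_task = get("phase", "task") == "task"
    outcome = get("outcome", "")
    for fkey, tkey, lkey in (
        ("s1_freq", "t_s1_on", "s1_label"),
        ("s2_freq", "t_s2_on", "s2_label"),
    ):
        freq, onset = get(fkey, np.nan), get(tkey, np.nan)
        if freq is None or onset is None:
            continue
        if math.isnan(float(freq)) or math.isnan(float(onset)):
            continue
        onset = float(onset)
        label = get(lkey, "") or ""
        nogo = label in (tm.Condition.S1_NO_GO.value, tm.Condition.S2_NO_GO.value)
        boost = (
            params.nogo_gain
            if is_task and nogo and outcome != tm.Outcome.FALSE_ALARM.value
            else 1.0
        )
        for k, (amp, lat, width) in enumerate(
            zip(params.deflection_amps, params.deflection_latencies, params.deflection_widths)
        ):
            scale = boost if k == 1 else 1.0
            trace += scale * amp * np.exp(-0.5 * ((t - onset - lat) / width) ** 2)
    trace += _colored_noise(
        n_samples, params.sampling_rate, params.noise_sd, params.noise_exponent,
        params.noise_band, rng,
    )
    return trace


def _stratified_counts(probs: list[float], n: int) -> list[int]:
    """Integer counts summing to n, proportional to probs (largest remainder)."""
    raw = [p * n for p in probs]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(probs)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _block_events(
    cfg: SessionConfig,
    task: tm.Task,
    block_id: int,
    phase: str,
    n_trials: int,
    trial_start_id: int,
    rng: np.random.Generator,
) -> list[dict]:
    spec = tm.TaskSpec(task, response_window=cfg.response_window)
    seq_probs = cfg.sequence_probs(task)
    sequences = list(seq_probs.keys())
    probs = [seq_probs[s] for s in sequences]
    if phase == "task" and cfg.block_go_jitter > 0:
        gf = float(
            np.clip(cfg.go_fraction + rng.uniform(-1, 1) * cfg.block_go_jitter, 0.50, 0.77)
        )
        rest = 1.0 - gf
        base_rest = sum(probs[1:])
        probs = [gf] + [p * rest / base_rest for p in probs[1:]]
    counts = _stratified_counts(probs, n_trials)
    drawn = [s for s, c in zip(sequences, counts) for _ in range(c)]
    order = rng.permutation(len(drawn))

    rows = []
    for i in order:
        f1, f2 = drawn[i]
        trial_id = trial_start_id + len(rows)
        if phase == "task":
            t_led = 0.0
            t_grasp = t_led + float(rng.uniform(0.3, 0.8))
            t_s1 = t_grasp + float(rng.uniform(1.0, 2.0))
        else:
            t_led, t_grasp = np.nan, np.nan
            t_s1 = cfg.lfp_pre + 0.1
        t_s2 = t_s1 + cfg.onset_interval
        s2_off = t_s2 + cfg.tone_duration
        seq = tm.ToneSequence(f1, f2, s1_onset=t_s1, tone_duration=cfg.tone_duration,
                              onset_interval=cfg.onset_interval)
        s1_label, s2_label = tm.label_sequence(spec, seq)
        row = {
            "trial_id": trial_id,
            "block_id": block_id,
            "phase": phase,
            "task": task.value,
            "s1_freq": float(f1),
            "s2_freq": float(f2),
            "t_led_on": t_led,
            "t_grasp": t_grasp,
            "t_s1_on": t_s1,
            "t_s2_on": t_s2,
            "t_release": np.nan,
            "t_reward": np.nan,
            "tone_duration": cfg.tone_duration,
            "s1_label": s1_label.value,
            "s2_label": s2_label.value,
            "required": "",
            "outcome": "",
        }
        if phase == "task":
            required = tm.required_response(spec, seq)
            w0, w1 = (s2_off + cfg.response_window[0], s2_off + cfg.response_window[1])
            release = np.nan
            if required is tm.Response.GO:
                if rng.random() >= cfg.miss_rate:
                    release = s2_off + float(rng.uniform(0.15, 0.60))
            else:
                fa_rate = (
                    cfg.fa_rate_s1_family
                    if s1_label is tm.Condition.S1_NO_GO
                    else cfg.fa_rate_s2_family
                )
                if rng.random() < fa_rate:
                    release = s2_off + float(rng.uniform(0.15, 0.60))
            result = tm.classify_outcome(required, None if math.isnan(release) else release,
                                         (w0, w1))
            row["required"] = required.value
            row["outcome"] = result.outcome.value
            row["t_release"] = release
            if result.outcome is tm.Outcome.HIT:
                row["t_reward"] = release + 0.2
            elif result.outcome is tm.Outcome.CORRECT_REJECTION:
                row["t_reward"] = w1
        rows.append(row)
    return rows


def _tuning_events(cfg: SessionConfig, block_id: int, trial_start_id: int,
                   rng: np.random.Generator) -> list[dict]:
    freqs = np.repeat(TUNING_FREQUENCIES, 10)
    order = rng.permutation(len(freqs))
    rows = []
    for i in order:
        rows.append({
            "trial_id": trial_start_id + len(rows),
            "block_id": block_id,
            "phase": "tuning",
            "task": "",
            "s1_freq": float(freqs[i]),
            "s2_freq": np.nan,
            "t_led_on": np.nan,
            "t_grasp": np.nan,
            "t_s1_on": 0.300,
            "t_s2_on": np.nan,
            "t_release": np.nan,
            "t_reward": np.nan,
            "tone_duration": 0.100,
            "s1_label": "",
            "s2_label": "",
            "required": "",
            "outcome": "",
        })
    return rows


def generate_session(
    config: SessionConfig,
    units: list[UnitParams] | None = None,
    lfp_params: list[LfpParams] | None = None,
) -> Session:
    """Generate a complete synthetic session bundle (events, spikes, LFPs).

    Task blocks alternate between the two tasks (starting task randomized),
    with a stratified pseudorandom sequence order honoring the scheduled
    probabilities exactly per block.  Passive blocks replay the two
    probability schedules without outcomes; the tuning block presents the
    40-tone best-frequency paradigm.  Deterministic for a fixed config,
    units and seed.
    """
    cfg = config
    ev_rng = _substream(cfg.seed, _STREAM_EVENTS)
    if units is None:
        units = paper_like_units(cfg.n_units, _substream(cfg.seed, _STREAM_EVENTS, 99))
    if lfp_params is None:
        lfp_params = [LfpParams(nogo_gain=1.4) for _ in range(cfg.n_lfp_sites)]

    rows: list[dict] = []
    block_id = 0
    start_task = ev_rng.choice([tm.Task.TASK1, tm.Task.TASK2])
    tasks = [tm.Task.TASK1, tm.Task.TASK2]
    if start_task is tm.Task.TASK2:
        tasks = tasks[::-1]
    for b in range(2 * cfg.n_blocks_per_task):
        task = tasks[b % 2]
        rows.extend(
            _block_events(cfg, task, block_id, "task", cfg.trials_per_block, len(rows), ev_rng)
        )
        block_id += 1
    if cfg.include_passive:
        for _ in range(cfg.passive_blocks_per_schedule):
            for task in (tm.Task.TASK1, tm.Task.TASK2):
                rows.extend(
                    _block_events(cfg, task, block_id, "passive",
                                  cfg.passive_trials_per_block, len(rows), ev_rng)
                )
                block_id += 1
    if cfg.include_tuning:
        rows.extend(_tuning_events(cfg, block_id, len(rows), ev_rng))
        block_id += 1

    events = pd.DataFrame(rows)

    tone_probs_cache = {
        t.value: {f: cfg.tone_probability(t, f) for f in tm.TONE_FREQS}
        for t in (tm.Task.TASK1, tm.Task.TASK2)
    }

    spikes: dict[int, dict[int, np.ndarray]] = {}
    for u, unit in enumerate(units):
        unit_trains: dict[int, np.ndarray] = {}
        for row in rows:
            trial_id = row["trial_id"]
            if row["phase"] == "tuning":
                t_end = row["t_s1_on"] + 0.100 + 0.200
                grid = np.arange(0.0, t_end, PROFILE_DT)
                profile = _tuning_profile(unit, row, grid, cfg)
            else:
                t_end = row["t_s2_on"] + cfg.tone_duration + cfg.lfp_post + 0.3
                grid = np.arange(0.0, t_end, PROFILE_DT)
                probs = tone_probs_cache[row["task"]]
                profile = build_rate_profile(unit, row, grid, tone_probs=probs, config=cfg)
            rng = _substream(cfg.seed, _STREAM_SPIKES, u, trial_id)
            unit_trains[trial_id] = simulate_spike_train(profile, rng)
        spikes[u] = unit_trains

    lfp = None
    lfp_trial_ids = None
    lfp_t0 = None
    if lfp_params:
        lfp_rows = [r for r in rows if r["phase"] != "tuning"]
        sr = lfp_params[0].sampling_rate
        span = cfg.lfp_pre + cfg.onset_interval + cfg.tone_duration + cfg.lfp_post
        n_samples = int(round(span * sr))
        lfp = np.zeros((len(lfp_params), len(lfp_rows), n_samples), dtype=np.float32)
        lfp_trial_ids = np.array([r["trial_id"] for r in lfp_rows], dtype=np.int64)
        lfp_t0 = np.array([r["t_s1_on"] - cfg.lfp_pre for r in lfp_rows])
        for s, site in enumerate(lfp_params):
            if site.sampling_rate != sr:
                raise ConfigError("all LFP sites must share one sampling rate")
            for j, row in enumerate(lfp_rows):
                rng = _substream(cfg.seed, _STREAM_LFP, s, row["trial_id"])
                lfp[s, j] = simulate_lfp(site, row, rng, lfp_t0[j], n_samples)

    meta = {
        "schema_version": Session.SCHEMA_VERSION,
        "seed": int(cfg.seed),
        "config": _config_dict(cfg),
        "tone_probabilities": tone_probs_cache,
        "n_units": len(units),
        "n_lfp_sites": len(lfp_params) if lfp_params else 0,
        "lfp_sampling_rate": lfp_params[0].sampling_rate if lfp_params else None,
    }
    return Session(
        events=events,
        spikes=spikes,
        lfp=lfp,
        lfp_trial_ids=lfp_trial_ids,
        lfp_t0=lfp_t0,
        lfp_sampling_rate=lfp_params[0].sampling_rate if lfp_params else None,
        meta=meta,
    )


def _tuning_profile(unit: UnitParams, row: dict, t_grid: np.ndarray,
                    cfg: SessionConfig) -> RateProfile:
    """Rate profile for one tuning-block tone (100 ms, no task modulation)."""
    onset = row["t_s1_on"]
    dur = row.get("tone_duration", 0.100)
    rates = np.full_like(t_grid, unit.baseline_rate, dtype=float)
    span = (t_grid >= onset - 1e-12) & (t_grid < onset + dur + cfg.evoked_offset_margin - 1e-12)
    rates[span] *= 1.0 + (unit.evoked_gain - 1.0) * unit.tuning(row["s1_freq"])
    return RateProfile(t_grid, rates)


def _config_dict(cfg: SessionConfig) -> dict:
    out = {}
    for key, value in cfg.__dict__.items():
        if isinstance(value, tuple):
            value = list(value)
        out[key] = value
    return out
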