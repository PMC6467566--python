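"""LFP statistics: windowed RMS, condition ratios with permutation tests,
and baseline-normalized geometric-mean RMS traces.

The LFP analogue of the spike-rate analysis quantifies the evoked
potential by its root-mean-square (RMS) amplitude over a 500-ms window
from tone onset ("during") or the 500-ms window directly before the tone
("before").  For condition ratios the RMS is computed on the
trial-averaged evoked potential of each condition (averaging first
suppresses non-phase-locked noise); the permutation test reassigns trials
between conditions and recomputes the averaged-potential RMS.  A per-trial
RMS variant is available behind a flag.  Input traces are assumed already
band-limited (1-140 Hz); no further filtering is applied.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
from scipy.special import comb

from .errors import InvalidInputError, MissingDataError, UndefinedRatioError
from .spikes import RatioResult

logger = logging.getLogger(__name__)

__all__ = [
    "DURING_LFP_WINDOW",
    "BEFORE_LFP_WINDOW",
    "rms",
    "window_samples",
    "lfp_condition_ratio",
    "normalized_lfp_trace",
]

#: LFP analysis windows relative to tone onset (s), half-open.
DURING_LFP_WINDOW = (0.0, 0.500)
BEFORE_LFP_WINDOW = (-0.500, 0.0)


def window_samples(trace: np.ndarray, sampling_rate: float, t0: float,
                   window: tuple[float, float]) -> np.ndarray:
    """Samples of a trace falling in the half-open window [w0, w1).

    ``t0`` is the trial-clock time of the first sample.  Raises when the
    window is not fully covered by the recorded samples.
    """
    trace = np.asarray(trace, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise InvalidInputError("window must have positive length")
    t_end = t0 + len(trace) / sampling_rate
    tol = 0.5 / sampling_rate
    if w0 < t0 - tol or w1 > t_end + tol:
        raise MissingDataError(
            f"window [{w0:.3f}, {w1:.3f}) outside trace support [{t0:.3f}, {t_end:.3f})"
        )
    i0 = int(math.ceil((w0 - t0) * sampling_rate - 1e-9))
    i1 = int(math.ceil((w1 - t0) * sampling_rate - 1e-9))
    return trace[max(i0, 0):min(i1, len(trace))]


def rms(trace: np.ndarray, sampling_rate: float, t0: float,
        window: tuple[float, float]) -> float:
    """Root-mean-square amplitude over the half-open window [w0, w1)."""
    x = window_samples(trace, sampling_rate, t0, window)
    if len(x) == 0:
        raise MissingDataError("window contains no samples")
    return float(np.sqrt(np.mean(x ** 2)))


def _condition_rms(traces: np.ndarray, sampling_rate: float, t0: float,
                   window: tuple[float, float], per_trial: bool) -> float:
    if per_trial:
        return float(np.mean([rms(tr, sampling_rate, t0, window) for tr in traces]))
    return rms(traces.mean(axis=0), sampling_rate, t0, window)


def lfp_condition_ratio(
    traces_num: np.ndarray,
    traces_den: np.ndarray,
    sampling_rate: float,
    t0: float,
    window: tuple[float, float] = DURING_LFP_WINDOW,
    numerator: str = "num",
    denominator: str = "den",
    window_kind: str = "DURING",
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    per_trial: bool = False,
    min_trials: int = 5,
) -> RatioResult:
    """Between-condition RMS-LFP ratio with a trial-permutation p-value.

    ``traces_num`` / ``traces_den`` are (n_trials, n_samples) arrays whose
    first sample lies at trial time ``t0`` (all trials aligned).  The
    statistic is the RMS of the trial-averaged potential (or the mean of
    per-trial RMS values when ``per_trial``); the permutation null
    reassigns trials between the two conditions and recomputes it.
    """
    traces_num = np.atleast_2d(np.asarray(traces_num, dtype=float))
    traces_den = np.atleast_2d(np.asarray(traces_den, dtype=float))
    n_a, n_b = len(traces_num), len(traces_den)
    if n_a < min_trials or n_b < min_trials:
        raise InvalidInputError(f"need >= {min_trials} trials per condition")
    num_stat = _condition_rms(traces_num, sampling_rate, t0, window, per_trial)
    den_stat = _condition_rms(traces_den, sampling_rate, t0, window, per_trial)
    if den_stat == 0.0:
        raise UndefinedRatioError("denominator RMS is zero")
    ratio = num_stat / den_stat

    pooled = np.concatenate([traces_num, traces_den], axis=0)
    if num_stat == 0.0:
        obs = math.inf
    else:
        obs = abs(math.log(ratio))
    tol = 1e-12

    def stat_for(idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        a = _condition_rms(pooled[idx_a], sampling_rate, t0, window, per_trial)
        b = _condition_rms(pooled[idx_b], sampling_rate, t0, window, per_trial)
        if a == 0.0 or b == 0.0:
            return math.inf
        return abs(math.log(a / b))

    n_total = comb(n_a + n_b, n_a, exact=True)
    all_idx = np.arange(n_a + n_b)
    if n_total <= n_perm:
        count = 0
        for chosen in combinations(range(n_a + n_b), n_a):
            chosen = np.asarray(chosen)
            rest = np.setdiff1d(all_idx, chosen, assume_unique=True)
            if stat_for(chosen, rest) >= obs - tol:
                count += 1
        p = count / n_total
    else:
        rng = rng or np.random.default_rng()
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            if stat_for(perm[:n_a], perm[n_a:]) >= obs - tol:
                count += 1
        p = (1 + count) / (n_perm + 1)

    return RatioResult(
        numerator=numerator,
        denominator=denominator,
        window_kind=window_kind,
        ratio=ratio,
        p_value=p,
        n_num=n_a,
        n_den=n_b,
        alpha=alpha,
    )


def normalized_lfp_trace(
    traces_by_site: list[np.ndarray],
    sampling_rate: float,
    t0s: list[float] | np.ndarray,
    tone_onset: float,
    tone_duration: float = 0.200,
    bin_width: float = 0.010,
    pre: float = 0.500,
    post: float = 0.800,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Geometric-mean baseline-normalized per-bin RMS trace across sites.

    For each site the trial-averaged potential is binned into consecutive
    half-open 10-ms bins from ``pre`` before tone onset to ``post`` after
    tone offset; each bin's RMS is divided by the mean bin RMS over the
    pre-onset period, and the normalized traces are geometrically averaged
    across sites.  Sites with a zero baseline are excluded and logged.

    Returns (bin_centers relative to tone onset, trace, n_sites_used).
    """
    start = tone_onset - pre
    stop = tone_onset + tone_duration + post
    n_bins = int(round((stop - start) / bin_width))
    centers = start - tone_onset + bin_width * (np.arange(n_bins) + 0.5)
    n_pre_bins = int(round(pre / bin_width))

    log_traces = []
    for site, (traces, site_t0) in enumerate(zip(traces_by_site, np.asarray(t0s, dtype=float))):
        traces = np.atleast_2d(np.asarray(traces, dtype=float))
        avg = traces.mean(axis=0)
        bin_rms = np.empty(n_bins)
        for j in range(n_bins):
            w = (start + j * bin_width, start + (j + 1) * bin_width)
            bin_rms[j] = rms(avg, sampling_rate, site_t0, w)
        baseline = bin_rms[:n_pre_bins].mean()
        if baseline <= 0.0:
            logger.info("normalized LFP trace: excluding site %d (zero baseline)", site)
            continue
        log_traces.append(np.log(np.maximum(bin_rms / baseline, 1e-300)))
    if not log_traces:
        raise UndefinedRatioError("no site with nonzero baseline RMS")
    return centers, np.exp(np.mean(log_traces, axis=0)), len(log_traces)
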