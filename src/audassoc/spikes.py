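"""Spike-level statistics: window rates, condition ratios, permutation tests,
responsiveness preselection, PSTHs, and geometric-mean normalized traces.

The central quantity is a *condition ratio*: the mean spike rate over
trials of one condition divided by the mean over trials of a matched
condition, computed either in the 250-ms window from tone onset to 50 ms
after tone offset ("during") or in the abutting 250-ms window directly
before the tone ("before").  Significance per unit comes from a label
permutation test on the log ratio.  Rates below a small floor (0.1
spikes/s by default) are replaced by the floor before division or logs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy.special import comb
from scipy.stats import wilcoxon

from .errors import InvalidInputError, MissingEventError, UndefinedRatioError

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisWindow",
    "RatioResult",
    "DURING_SPIKE_WINDOW",
    "BEFORE_SPIKE_WINDOW",
    "mean_rate",
    "window_rates",
    "floored_mean",
    "condition_ratio",
    "permutation_test_ratio",
    "paired_permutation_test",
    "ratio_with_test",
    "is_responsive",
    "normalized_response",
    "psth",
    "geometric_average_normalized",
    "per_bin_condition_test",
    "best_frequency",
    "octave_distance",
]

#: Default flooring constant for rates entering logs or divisions (spikes/s).
RATE_FLOOR = 0.1

#: Spike analysis windows relative to tone onset (s), half-open.
DURING_SPIKE_WINDOW = (0.0, 0.250)
BEFORE_SPIKE_WINDOW = (-0.250, 0.0)


@dataclass(frozen=True)
class AnalysisWindow:
    """A window anchored to a named trial event (half-open [start, end))."""

    anchor: str
    start_offset: float
    end_offset: float
    kind: str = "DURING"

    def __post_init__(self) -> None:
        if self.end_offset <= self.start_offset:
            raise InvalidInputError("end_offset must exceed start_offset")
        if self.kind not in ("DURING", "BEFORE"):
            raise InvalidInputError("kind must be DURING or BEFORE")
        if self.kind == "BEFORE" and abs(self.end_offset) > 1e-12:
            raise InvalidInputError("BEFORE windows must abut the anchor from below")

    @property
    def length(self) -> float:
        return self.end_offset - self.start_offset

    def resolve(self, events_row) -> tuple[float, float]:
        """Absolute (t0, t1) on the trial clock for one events-table row."""
        try:
            anchor_time = float(events_row[self.anchor])
        except (KeyError, ValueError, TypeError) as exc:
            raise MissingEventError(f"cannot resolve anchor {self.anchor!r}") from exc
        if math.isnan(anchor_time):
            raise MissingEventError(f"anchor {self.anchor!r} is undefined for this trial")
        return (anchor_time + self.start_offset, anchor_time + self.end_offset)


@dataclass(frozen=True)
class RatioResult:
    """A condition ratio with its permutation p-value."""

    numerator: str
    denominator: str
    window_kind: str
    ratio: float
    p_value: float
    n_num: int
    n_den: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def mean_rate(spike_times: np.ndarray, t0: float, t1: float) -> float:
    """Spike count in [t0, t1) divided by the window length (spikes/s)."""
    if t1 <= t0:
        raise InvalidInputError("window must have positive length")
    spike_times = np.asarray(spike_times, dtype=float)
    count = int(np.count_nonzero((spike_times >= t0) & (spike_times < t1)))
    return count / (t1 - t0)


def window_rates(
    trains: list[np.ndarray],
    windows: list[tuple[float, float]] | tuple[float, float],
) -> np.ndarray:
    """Per-trial mean rates; ``windows`` may be one shared or one per trial."""
    if isinstance(windows, tuple) and np.isscalar(windows[0]):
        windows = [windows] * len(trains)
    if len(windows) != len(trains):
        raise InvalidInputError("one window per train required")
    return np.array([mean_rate(tr, w0, w1) for tr, (w0, w1) in zip(trains, windows)])


def floored_mean(rates: np.ndarray, floor: float = RATE_FLOOR) -> float:
    """Trial-averaged rate, floored at ``floor`` before use in logs/ratios."""
    return max(float(np.mean(rates)), floor)


def condition_ratio(
    rates_num: np.ndarray,
    rates_den: np.ndarray,
    floor: float = RATE_FLOOR,
    min_trials: int = 5,
) -> float:
    """Ratio of trial-averaged rates between two conditions.

    Values > 1 mean the numerator condition evoked the stronger response.
    """
    rates_num = np.asarray(rates_num, dtype=float)
    rates_den = np.asarray(rates_den, dtype=float)
    if len(rates_num) < min_trials or len(rates_den) < min_trials:
        raise InvalidInputError(
            f"need >= {min_trials} trials per condition "
            f"(got {len(rates_num)} and {len(rates_den)})"
        )
    den = max(float(np.mean(rates_den)), floor)
    if den <= 0.0:
        raise UndefinedRatioError("denominator mean rate is zero after flooring")
    return max(float(np.mean(rates_num)), floor) / den


def _log_ratio_stat(pooled: np.ndarray, n_a: int, floor: float) -> float:
    a = max(pooled[:n_a].mean(), floor)
    b = max(pooled[n_a:].mean(), floor)
    return abs(math.log(a / b))


def permutation_test_ratio(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    floor: float = RATE_FLOOR,
) -> float:
    """Two-sided label-permutation p-value for the between-condition ratio.

    The statistic is |log ratio| of the (floored) trial-averaged rates;
    labels are shuffled across the pooled trials preserving group sizes.
    When the number of distinct assignments is at most ``n_perm`` the null
    distribution is enumerated exhaustively (p = k/N); otherwise ``n_perm``
    random permutations are drawn and the add-one estimate
    (1 + k) / (n_perm + 1) is used so that p never reaches 0.
    """
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    n_a, n_b = len(rates_a), len(rates_b)
    if n_a < 2 or n_b < 2:
        raise InvalidInputError("need at least 2 trials per side")
    pooled = np.concatenate([rates_a, rates_b])
    obs = _log_ratio_stat(pooled, n_a, floor)
    tol = 1e-12

    n_total = comb(n_a + n_b, n_a, exact=True)
    if n_total <= n_perm:
        idx_all = np.arange(n_a + n_b)
        count = 0
        for chosen in combinations(range(n_a + n_b), n_a):
            chosen = np.asarray(chosen)
            rest = np.setdiff1d(idx_all, chosen, assume_unique=True)
            stat = _log_ratio_stat(np.concatenate([pooled[chosen], pooled[rest]]), n_a, floor)
            if stat >= obs - tol:
                count += 1
        return count / n_total

    rng = rng or np.random.default_rng()
    perms = np.tile(pooled, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    means_a = np.maximum(perms[:, :n_a].mean(axis=1), floor)
    means_b = np.maximum(perms[:, n_a:].mean(axis=1), floor)
    stats = np.abs(np.log(means_a / means_b))
    count = int(np.count_nonzero(stats >= obs - tol))
    return (1 + count) / (n_perm + 1)


def paired_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided sign-flip permutation test on paired samples.

    Statistic: |mean(x - y)|; under the null the per-pair difference signs
    are exchangeable.  Exhaustive over all 2^n sign assignments when that
    count is at most ``n_perm``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n < 2:
        raise InvalidInputError("need at least 2 pairs")
    obs = abs(d.mean())
    tol = 1e-12
    if 2 ** n <= n_perm:
        count = 0
        for signs in product((-1.0, 1.0), repeat=n):
            if abs((d * signs).mean()) >= obs - tol:
                count += 1
        return count / 2 ** n
    rng = rng or np.random.default_rng()
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    stats = np.abs((signs * d).mean(axis=1))
    count = int(np.count_nonzero(stats >= obs - tol))
    return (1 + count) / (n_perm + 1)


def ratio_with_test(
    rates_num: np.ndarray,
    rates_den: np.ndarray,
    numerator: str,
    denominator: str,
    window_kind: str = "DURING",
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    floor: float = RATE_FLOOR,
    min_trials: int = 5,
) -> RatioResult:
    """Condition ratio plus its permutation p-value, as one result record."""
    ratio = condition_ratio(rates_num, rates_den, floor=floor, min_trials=min_trials)
    p = permutation_test_ratio(rates_num, rates_den, n_perm=n_perm, rng=rng, floor=floor)
    return RatioResult(
        numerator=numerator,
        denominator=denominator,
        window_kind=window_kind,
        ratio=ratio,
        p_value=p,
        n_num=len(rates_num),
        n_den=len(rates_den),
        alpha=alpha,
    )


def is_responsive(
    condition_rates: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[bool, dict[str, float]]:
    """Tone-responsiveness preselection for one unit (or LFP site).

    ``condition_rates`` maps condition name -> (before_rates, during_rates),
    paired by trial.  The unit is responsive if the paired permutation test
    finds a significant before/during difference (p < alpha) in at least
    one condition.  Missing or too-small conditions are skipped and logged.
    """
    p_values: dict[str, float] = {}
    for name, (before, during) in condition_rates.items():
        before = np.asarray(before, dtype=float)
        during = np.asarray(during, dtype=float)
        if len(before) != len(during) or len(before) < 2:
            logger.info("responsiveness: skipping condition %s (unusable pairing)", name)
            continue
        p_values[name] = paired_permutation_test(during, before, n_perm=n_perm, rng=rng)
    responsive = any(p < alpha for p in p_values.values())
    return responsive, p_values


def normalized_response(
    during_rates: np.ndarray,
    before_rates: np.ndarray,
    floor: float = RATE_FLOOR,
) -> float:
    """Trial-averaged during-window rate divided by the before-window rate.

    Both means are floored; a zero floored baseline raises so the caller
    can exclude the unit for this tone.
    """
    den = max(float(np.mean(before_rates)), floor)
    if den <= 0.0:
        raise UndefinedRatioError("baseline mean rate is zero after flooring")
    return max(float(np.mean(during_rates)), floor) / den


def psth(
    trains: list[np.ndarray],
    t_start: float,
    t_stop: float,
    bin_width: float = 0.010,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged rate in consecutive half-open bins.

    Returns (bin_centers, rates); rates are counts / (n_trials x width).
    An empty trial list yields all-zero bins.
    """
    n_bins = int(round((t_stop - t_start) / bin_width))
    if n_bins < 1:
        raise InvalidInputError("PSTH range must cover at least one bin")
    edges = t_start + bin_width * np.arange(n_bins + 1)
    centers = edges[:-1] + bin_width / 2.0
    counts = np.zeros(n_bins)
    for train in trains:
        t = np.asarray(train, dtype=float)
        idx = np.floor((t - t_start) / bin_width).astype(int)
        valid = (idx >= 0) & (idx < n_bins) & (t < t_stop)
        counts += np.bincount(idx[valid], minlength=n_bins)
    n_trials = max(len(trains), 1)
    return centers, counts / (n_trials * bin_width)


def geometric_average_normalized(
    psths: np.ndarray,
    baselines: np.ndarray,
    floor: float = RATE_FLOOR,
) -> np.ndarray:
    """Geometric mean across units of baseline-normalized per-bin rates.

    ``psths`` is (n_units, n_bins); ``baselines`` the per-unit baseline
    rate (mean rate in the 250-ms window directly before the tone).  Each
    bin rate and each baseline is floored before the log, so every unit
    contributes a positive value to every bin.
    """
    psths = np.asarray(psths, dtype=float)
    baselines = np.asarray(baselines, dtype=float)
    if psths.ndim != 2 or psths.shape[0] != len(baselines):
        raise InvalidInputError("psths must be (n_units, n_bins) matching baselines")
    if psths.shape[0] == 0:
        raise InvalidInputError("no eligible units for the population trace")
    num = np.maximum(psths, floor)
    den = np.maximum(baselines, floor)[:, None]
    return np.exp(np.mean(np.log(num / den), axis=0))


def per_bin_condition_test(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    min_units: int = 6,
) -> np.ndarray | None:
    """Paired two-sided Wilcoxon signed-rank per bin across units.

    Inputs are (n_units, n_bins) normalized rates with the same unit order.
    Returns per-bin p-values, or None when fewer than ``min_units`` units
    are available (test skipped, logged).
    """
    a = np.asarray(traces_a, dtype=float)
    b = np.asarray(traces_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("condition traces must share (n_units, n_bins) shape")
    if a.shape[0] < min_units:
        logger.info("per-bin test skipped: %d units < %d", a.shape[0], min_units)
        return None
    p = np.ones(a.shape[1])
    for j in range(a.shape[1]):
        diff = a[:, j] - b[:, j]
        if np.allclose(diff, 0.0):
            p[j] = 1.0
            continue
        p[j] = float(wilcoxon(a[:, j], b[:, j], zero_method="wilcox").pvalue)
    return p


def best_frequency(
    tone_freqs: np.ndarray,
    evoked_rates: np.ndarray,
    baseline_rates: np.ndarray,
) -> float | None:
    """Best frequency from the 40-tone tuning block.

    Inputs are per-presentation arrays; for each distinct frequency the
    mean evoked rate (0-150 ms after onset) minus the mean pre-tone
    baseline is formed, and the frequency maximizing this difference is
    the best frequency.  Returns None (untuned) when no frequency evokes a
    positive difference.
    """
    tone_freqs = np.asarray(tone_freqs, dtype=float)
    evoked_rates = np.asarray(evoked_rates, dtype=float)
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    if not (len(tone_freqs) == len(evoked_rates) == len(baseline_rates)) or len(tone_freqs) == 0:
        raise InvalidInputError("per-presentation arrays must be nonempty and aligned")
    freqs = np.unique(tone_freqs)
    diffs = np.array([
        evoked_rates[tone_freqs == f].mean() - baseline_rates[tone_freqs == f].mean()
        for f in freqs
    ])
    if np.max(diffs) <= 0.0:
        return None
    return float(freqs[int(np.argmax(diffs))])


def octave_distance(bf: float, ref: float) -> float:
    """Absolute distance in octaves between two frequencies."""
    if bf <= 0 or ref <= 0:
        raise InvalidInputError("frequencies must be positive")
    return abs(math.log2(bf / ref))
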