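"""Population-level inference over per-unit condition ratios.

This covers the study-level bookkeeping built on top of per-unit ratio
statistics: median-ratio tests (Wilcoxon signed-rank on log ratios),
one-tailed chi-square proportion comparisons, the Bonferroni-corrected
six-condition comparison, the conservative confound-attribution
accounting that lower-bounds the fraction of units representing
sensorimotor associations, false-alarm versus correct-trial contrasts,
and the tone-probability subset analysis used to rule out
stimulus-specific adaptation as the sole driver of the ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, wilcoxon

from .errors import InvalidInputError

__all__ = [
    "PopulationRatioSummary",
    "AttributionResult",
    "FalseAlarmContrast",
    "SubsetComparison",
    "SixConditionResult",
    "summarize_ratios",
    "compare_proportions",
    "attribution_accounting",
    "six_condition_comparison",
    "false_alarm_contrasts",
    "session_probability_ratios",
    "median_probability_ratio",
    "probability_subset_analysis",
]


def _signed_rank_vs_one(ratios: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for median(log ratio) = 0."""
    logr = np.log(np.asarray(ratios, dtype=float))
    if np.allclose(logr, 0.0):
        return 1.0
    return float(wilcoxon(logr, zero_method="wilcox").pvalue)


@dataclass(frozen=True)
class PopulationRatioSummary:
    """Distribution summary of per-unit ratios with significance counts."""

    n_units: int
    median: float
    minimum: float
    maximum: float
    p_median_vs_1: float
    n_significant: int
    n_significant_gt1: int

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.n_units

    @property
    def fraction_significant_gt1(self) -> float:
        """Among significant ratios, the fraction > 1."""
        if self.n_significant == 0:
            return math.nan
        return self.n_significant_gt1 / self.n_significant


def summarize_ratios(
    ratios: np.ndarray,
    p_values: np.ndarray,
    alpha: float = 0.05,
) -> PopulationRatioSummary:
    """Median-ratio test plus counts of per-unit significant ratios.

    The median test is a two-sided Wilcoxon signed-rank of log(ratio)
    against 0; ``n_significant`` counts units whose own permutation p is
    below ``alpha`` (either direction), ``n_significant_gt1`` those of
    them with ratio > 1.
    """
    ratios = np.asarray(ratios, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if len(ratios) == 0 or len(ratios) != len(p_values):
        raise InvalidInputError("ratio and p-value lists must be nonempty and aligned")
    sig = p_values < alpha
    return PopulationRatioSummary(
        n_units=len(ratios),
        median=float(np.median(ratios)),
        minimum=float(np.min(ratios)),
        maximum=float(np.max(ratios)),
        p_median_vs_1=_signed_rank_vs_one(ratios),
        n_significant=int(sig.sum()),
        n_significant_gt1=int((sig & (ratios > 1.0)).sum()),
    )


def compare_proportions(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    alternative: str = "greater",
    method: str = "chi2",
) -> float:
    """Compare two proportions k1/n1 vs k2/n2.

    ``alternative='greater'`` tests the one-tailed hypothesis that the
    first proportion exceeds the second: the one-tailed p is half the
    two-tailed chi-square p when the observed direction matches, and
    1 - half otherwise.  ``method='fisher'`` switches to Fisher's exact
    test (preferred for small counts).
    """
    if n1 <= 0 or n2 <= 0:
        raise InvalidInputError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise InvalidInputError("counts must satisfy 0 <= k <= n")
    if alternative not in ("greater", "less", "two-sided"):
        raise InvalidInputError("alternative must be greater, less or two-sided")

    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if method == "fisher":
        return float(fisher_exact(table, alternative=alternative)[1])
    if method != "chi2":
        raise InvalidInputError("method must be chi2 or fisher")
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        p_two = 1.0
    else:
        p_two = float(chi2_contingency(table, correction=False)[1])
    if alternative == "two-sided":
        return p_two
    diff = k1 / n1 - k2 / n2
    matches = diff > 0 if alternative == "greater" else diff < 0
    if diff == 0:
        return 0.5
    return p_two / 2.0 if matches else 1.0 - p_two / 2.0


@dataclass(frozen=True)
class AttributionResult:
    """Conservative attribution of significant during-tone ratios.

    Of ``n_during_sig`` units with significant during ratios during task
    performance, those whose before ratio was also significant are
    attributed to the visual cue; the passive-condition significance rate
    among the passive-tested subset, projected onto all significant units
    (rounded half-up), is attributed to the acoustic context; the
    remainder is the minimum count attributable to the sensorimotor
    association itself.
    """

    n_total: int
    n_during_sig: int
    n_cue_attributed: int
    n_passive_tested: int | None
    n_passive_sig: int | None
    n_context_attributed: int | None
    n_remainder: int
    context_estimable: bool = True

    @property
    def pct_remainder_of_sig(self) -> float:
        """Remainder as a percentage of significant during ratios (1 decimal)."""
        return round(100.0 * self.n_remainder / self.n_during_sig, 1)

    @property
    def pct_remainder_of_sig_int(self) -> int:
        """Integer-percent rendering of the same headline number."""
        return int(math.floor(100.0 * self.n_remainder / self.n_during_sig + 0.5))

    @property
    def pct_remainder_of_total(self) -> float:
        return round(100.0 * self.n_remainder / self.n_total, 1)

    @property
    def pct_cue_of_sig(self) -> float:
        return round(100.0 * self.n_cue_attributed / self.n_during_sig, 1)

    @property
    def pct_context_of_passive_tested(self) -> float | None:
        if not self.context_estimable or not self.n_passive_tested:
            return None
        return round(100.0 * self.n_passive_sig / self.n_passive_tested, 1)


def attribution_accounting(
    n_total: int,
    n_during_sig: int,
    n_also_before_sig: int,
    n_passive_tested: int | None,
    n_passive_sig: int | None,
) -> AttributionResult:
    """Subtract cue- and context-attributable counts from the significant ratios.

    The context projection is ``round(n_during_sig * n_passive_sig /
    n_passive_tested)`` with half-up rounding.  When no passive data exist
    (``n_passive_tested`` is None) the context term is marked not
    estimable and only the cue term is subtracted.
    """
    if not 0 <= n_also_before_sig <= n_during_sig <= n_total:
        raise InvalidInputError("need 0 <= n_also_before_sig <= n_during_sig <= n_total")
    if n_passive_tested is None:
        n_context = None
        estimable = False
        remainder = n_during_sig - n_also_before_sig
    else:
        if not 0 <= n_passive_sig <= n_passive_tested <= n_during_sig:
            raise InvalidInputError(
                "need 0 <= n_passive_sig <= n_passive_tested <= n_during_sig"
            )
        if n_passive_tested == 0:
            n_context = 0
        else:
            n_context = int(
                math.floor(n_during_sig * n_passive_sig / n_passive_tested + 0.5)
            )
        estimable = True
        remainder = n_during_sig - n_also_before_sig - n_context
    if remainder < 0:
        raise InvalidInputError(
            "negative remainder: attribution inputs are mutually inconsistent"
        )
    return AttributionResult(
        n_total=int(n_total),
        n_during_sig=int(n_during_sig),
        n_cue_attributed=int(n_also_before_sig),
        n_passive_tested=None if n_passive_tested is None else int(n_passive_tested),
        n_passive_sig=None if n_passive_tested is None else int(n_passive_sig),
        n_context_attributed=n_context,
        n_remainder=int(remainder),
        context_estimable=estimable,
    )


@dataclass(frozen=True)
class SixConditionResult:
    """Pairwise medians and signed-rank p-values over the six conditions."""

    medians: pd.Series
    p_matrix: pd.DataFrame
    n_units: pd.DataFrame
    alpha: float = 0.05

    @property
    def alpha_corrected(self) -> float:
        """Bonferroni threshold for the four planned comparisons per no-go tone."""
        return self.alpha / 4.0

    def significant(self, cond_a: str, cond_b: str) -> bool:
        return bool(self.p_matrix.loc[cond_a, cond_b] < self.alpha_corrected)


def six_condition_comparison(
    responses: pd.DataFrame,
    alpha: float = 0.05,
) -> SixConditionResult:
    """Pairwise Wilcoxon signed-rank tests of normalized responses.

    ``responses`` has one row per unit and one column per condition
    (normalized response of that unit to the same tone under that
    condition); NaNs are handled by pairwise deletion.  Significance for
    the planned no-go-versus-other comparisons is assessed at alpha/4.
    """
    if responses.shape[1] < 2:
        raise InvalidInputError("need at least two conditions")
    conds = list(responses.columns)
    p = pd.DataFrame(np.ones((len(conds), len(conds))), index=conds, columns=conds)
    n = pd.DataFrame(np.zeros((len(conds), len(conds)), dtype=int), index=conds, columns=conds)
    for a, b in combinations(conds, 2):
        pair = responses[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(pair)
        if len(pair) < 2:
            continue
        diff = pair[a].to_numpy() - pair[b].to_numpy()
        if np.allclose(diff, 0.0):
            pval = 1.0
        else:
            pval = float(wilcoxon(pair[a], pair[b], zero_method="wilcox").pvalue)
        p.loc[a, b] = p.loc[b, a] = pval
    medians = responses.median(axis=0)
    return SixConditionResult(medians=medians, p_matrix=p, n_units=n, alpha=alpha)


@dataclass(frozen=True)
class FalseAlarmContrast:
    """Pooled false-alarm versus correct-trial response ratios for one contrast."""

    name: str
    ratios: np.ndarray
    median: float
    p_vs_1: float

    @property
    def n(self) -> int:
        return len(self.ratios)


def false_alarm_contrasts(
    records: pd.DataFrame,
    min_fa_trials: int = 5,
) -> dict[str, FalseAlarmContrast]:
    """The three false-alarm contrasts, pooled across tone frequencies.

    ``records`` has one row per unit x frequency with columns

    * ``sig_during_s1`` / ``sig_during_s2`` -- the unit's during ratio for
      that frequency was significant in correct trials;
    * ``n_fa_s1`` / ``n_fa_s2`` -- false-alarm trial counts for the
      S1-no-go and S2-no-go sequence families;
    * normalized responses ``s1_nogo_fa``, ``s1_nogo_correct``,
      ``s2_nogo_fa``, ``s2_nogo_correct``, ``s2_go_correct``.

    A unit x frequency record enters a contrast only when the relevant
    during ratio is significant and at least ``min_fa_trials`` false-alarm
    trials were recorded; a unit significant at both frequencies
    contributes one record per frequency.  Each contrast reports the
    pooled ratio distribution's median and a two-sided Wilcoxon
    signed-rank p against 1.
    """
    specs = [
        ("s1_nogo_fa_vs_correct", "sig_during_s1", "n_fa_s1", "s1_nogo_fa", "s1_nogo_correct"),
        ("s2_nogo_fa_vs_correct", "sig_during_s2", "n_fa_s2", "s2_nogo_fa", "s2_nogo_correct"),
        ("s2_nogo_fa_vs_correct_go", "sig_during_s2", "n_fa_s2", "s2_nogo_fa", "s2_go_correct"),
    ]
    out: dict[str, FalseAlarmContrast] = {}
    for name, sig_col, n_col, num_col, den_col in specs:
        if not set((sig_col, n_col, num_col, den_col)) <= set(records.columns):
            continue
        eligible = records[
            records[sig_col].astype(bool)
            & (records[n_col] >= min_fa_trials)
            & records[num_col].notna()
            & records[den_col].notna()
        ]
        ratios = (eligible[num_col] / eligible[den_col]).to_numpy(dtype=float)
        ratios = ratios[np.isfinite(ratios) & (ratios > 0)]
        if len(ratios) == 0:
            continue
        out[name] = FalseAlarmContrast(
            name=name,
            ratios=ratios,
            median=float(np.median(ratios)),
            p_vs_1=_signed_rank_vs_one(ratios) if len(ratios) >= 2 else 1.0,
        )
    return out


def session_probability_ratios(sessions: pd.DataFrame) -> pd.Series:
    """Per-session ratio of the analyzed tone's probability, Task 1 / Task 2.

    ``sessions`` needs columns ``session_id``, ``p_task1`` and ``p_task2``
    (the scheduled or empirical probability of the tone in each task).
    """
    for col in ("session_id", "p_task1", "p_task2"):
        if col not in sessions.columns:
            raise InvalidInputError(f"sessions table lacks column {col!r}")
    if (sessions["p_task2"] <= 0).any():
        raise InvalidInputError("task-2 probabilities must be positive")
    ratios = sessions["p_task1"] / sessions["p_task2"]
    return pd.Series(ratios.to_numpy(dtype=float), index=sessions["session_id"].to_numpy())


def median_probability_ratio(sessions: pd.DataFrame) -> float:
    """Median across sessions of the Task 1 / Task 2 tone-probability ratio."""
    return float(session_probability_ratios(sessions).median())


@dataclass(frozen=True)
class SubsetComparison:
    """Proportions of significant ratios > 1 in high- vs low-probability-ratio sessions."""

    median_ratio: float
    k_high: int
    n_high: int
    k_low: int
    n_low: int
    p_one_tailed: float

    @property
    def prop_high(self) -> float:
        return self.k_high / self.n_high

    @property
    def prop_low(self) -> float:
        return self.k_low / self.n_low


def probability_subset_analysis(
    sessions: pd.DataFrame,
    units: pd.DataFrame,
    method: str = "chi2",
) -> SubsetComparison:
    """Split sessions at the median probability ratio and compare significance.

    If task-independent stimulus-specific adaptation were the sole cause
    of during ratios > 1, sessions with a larger Task 1 / Task 2
    probability ratio should yield a larger proportion of units with
    significant ratios > 1; the one-tailed test is oriented in that
    predicted direction.  ``units`` has one row per unit with columns
    ``session_id`` and ``significant_gt1``.  Sessions whose ratio equals
    the median are dropped; fewer than 2 sessions per subset is an error.
    """
    ratios = session_probability_ratios(sessions)
    med = float(ratios.median())
    high_ids = set(ratios.index[ratios > med])
    low_ids = set(ratios.index[ratios < med])
    if len(high_ids) < 2 or len(low_ids) < 2:
        raise InvalidInputError(
            "need at least 2 sessions on each side of the median probability ratio"
        )
    for col in ("session_id", "significant_gt1"):
        if col not in units.columns:
            raise InvalidInputError(f"units table lacks column {col!r}")
    high = units[units["session_id"].isin(high_ids)]
    low = units[units["session_id"].isin(low_ids)]
    if len(high) == 0 or len(low) == 0:
        raise InvalidInputError("no units in one of the probability subsets")
    k_high = int(high["significant_gt1"].astype(bool).sum())
    k_low = int(low["significant_gt1"].astype(bool).sum())
    p = compare_proportions(k_high, len(high), k_low, len(low),
                            alternative="greater", method=method)
    return SubsetComparison(
        median_ratio=med,
        k_high=k_high,
        n_high=len(high),
        k_low=k_low,
        n_low=len(low),
        p_one_tailed=p,
    )
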