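"""End-to-end session analysis: responsiveness -> ratios -> traces -> report.

``analyze_session`` turns one session bundle into tidy per-unit result
tables; ``population_report`` aggregates one or more analyzed sessions
into the population statistics (median-ratio tests, proportion
comparisons, attribution accounting, six-condition comparison,
false-alarm contrasts, tone-probability subset analysis, behavioral
d-prime) as a JSON-serializable report.  Structured per-stage counts are
logged so every denominator in the report is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lfp as lfp_mod
from . import population as pop
from . import spikes as spk
from . import task as tm
from .config import RunConfig
from .errors import InvalidInputError
from .io import Session

logger = logging.getLogger(__name__)

__all__ = ["SessionAnalysis", "analyze_session", "population_report"]

_CORRECT = (tm.Outcome.HIT.value, tm.Outcome.CORRECT_REJECTION.value)

_POSITIONS = {
    "S1": dict(anchor="t_s1_on", label_col="s1_label", freq_col="s1_freq",
               num=tm.Condition.S1_NO_GO.value, den=tm.Condition.S1_UNCERTAIN.value),
    "S2": dict(anchor="t_s2_on", label_col="s2_label", freq_col="s2_freq",
               num=tm.Condition.S2_NO_GO.value, den=tm.Condition.S2_GO.value),
}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(101, *map(int, key)))
    )


def _spike_rates(session: Session, unit: int, rows: pd.DataFrame,
                 anchor: str, window: tuple[float, float]) -> np.ndarray:
    trains = [session.spikes[unit][int(t)] for t in rows["trial_id"]]
    anchors = rows[anchor].to_numpy(dtype=float)
    windows = [(a + window[0], a + window[1]) for a in anchors]
    return spk.window_rates(trains, windows)


def _select(events: pd.DataFrame, phase: str, label_col: str, label: str,
            freq_col: str, freq: float, correct_only: bool) -> pd.DataFrame:
    rows = events[
        (events["phase"] == phase)
        & (events[label_col] == label)
        & (events[freq_col] == freq)
    ]
    if correct_only and phase == "task":
        rows = rows[rows["outcome"].isin(_CORRECT)]
    return rows


@dataclass
class SessionAnalysis:
    """Tidy per-unit/per-site result tables for one session."""

    session_id: str
    ratios: pd.DataFrame
    responsiveness: pd.DataFrame
    normalized: pd.DataFrame
    fa_records: pd.DataFrame
    behavioral: pd.DataFrame
    best_frequencies: pd.DataFrame
    lfp_ratios: pd.DataFrame
    traces: dict = field(default_factory=dict)
    tone_probabilities: dict = field(default_factory=dict)

    @property
    def has_passive(self) -> bool:
        return bool((self.ratios["phase"] == "passive").any())


def _session_tone_probs(session: Session) -> dict:
    raw = session.meta.get("tone_probabilities", {})
    return {
        str(task): {float(f): float(p) for f, p in probs.items()}
        for task, probs in raw.items()
    }


def analyze_session(
    session: Session,
    cfg: RunConfig | None = None,
    session_id: str = "s0",
    with_lfp: bool = True,
    with_traces: bool = True,
) -> SessionAnalysis:
    """Run the full per-session analysis chain on one bundle."""
    cfg = cfg or RunConfig()
    session.validate()
    events = session.events
    units = sorted(session.spikes)
    freqs = list(cfg.frequencies)
    phases = ["task"]
    if (events["phase"] == "passive").any():
        phases.append("passive")

    # --- responsiveness preselection -------------------------------------
    resp_rows = []
    for unit in units:
        for ifreq, freq in enumerate(freqs):
            for iphase, phase in enumerate(phases):
                cond_rates = {}
                for ipos, (pos, info) in enumerate(_POSITIONS.items()):
                    for cond in (info["num"], info["den"]):
                        rows = _select(events, phase, info["label_col"], cond,
                                       info["freq_col"], freq, correct_only=True)
                        if len(rows) < 2:
                            continue
                        before = _spike_rates(session, unit, rows, info["anchor"],
                                              cfg.before_spike_window)
                        during = _spike_rates(session, unit, rows, info["anchor"],
                                              cfg.during_spike_window)
                        cond_rates[cond] = (before, during)
                responsive, p_vals = spk.is_responsive(
                    cond_rates, alpha=cfg.alpha, n_perm=cfg.n_perm,
                    rng=_rng(cfg.seed, 1, unit, ifreq, iphase),
                )
                resp_rows.append({
                    "unit_id": unit, "freq": freq, "phase": phase,
                    "responsive": responsive,
                    **{f"p_{k}": v for k, v in p_vals.items()},
                })
    responsiveness = pd.DataFrame(resp_rows)

    # --- during/before condition ratios ----------------------------------
    ratio_rows = []
    for unit in units:
        for ifreq, freq in enumerate(freqs):
            for ipos, (pos, info) in enumerate(_POSITIONS.items()):
                for iphase, phase in enumerate(phases):
                    num_rows = _select(events, phase, info["label_col"], info["num"],
                                       info["freq_col"], freq, correct_only=True)
                    den_rows = _select(events, phase, info["label_col"], info["den"],
                                       info["freq_col"], freq, correct_only=True)
                    for iwin, (kind, window) in enumerate(
                        (("DURING", cfg.during_spike_window),
                         ("BEFORE", cfg.before_spike_window))
                    ):
                        record = {
                            "unit_id": unit, "freq": freq, "position": pos,
                            "window": kind, "phase": phase,
                            "n_num": len(num_rows), "n_den": len(den_rows),
                            "ratio": np.nan, "p_value": np.nan,
                        }
                        if len(num_rows) >= cfg.min_trials and len(den_rows) >= cfg.min_trials:
                            rates_num = _spike_rates(session, unit, num_rows,
                                                     info["anchor"], window)
                            rates_den = _spike_rates(session, unit, den_rows,
                                                     info["anchor"], window)
                            result = spk.ratio_with_test(
                                rates_num, rates_den, info["num"], info["den"],
                                window_kind=kind, alpha=cfg.alpha, n_perm=cfg.n_perm,
                                rng=_rng(cfg.seed, 2, unit, ifreq, ipos, iwin, iphase),
                                floor=cfg.rate_floor, min_trials=cfg.min_trials,
                            )
                            record["ratio"] = result.ratio
                            record["p_value"] = result.p_value
                        else:
                            logger.info(
                                "ratio skipped: unit=%s freq=%s pos=%s phase=%s "
                                "(n_num=%d, n_den=%d < %d)",
                                unit, freq, pos, phase, len(num_rows), len(den_rows),
                                cfg.min_trials,
                            )
                        ratio_rows.append(record)
    ratios = pd.DataFrame(ratio_rows)
    ratios["significant"] = ratios["p_value"] < cfg.alpha

    # --- normalized responses (six conditions) ----------------------------
    norm_rows = []
    for unit in units:
        for freq in freqs:
            for phase in phases:
                for pos, info in _POSITIONS.items():
                    labels = [info["num"], info["den"]]
                    if pos == "S2":
                        labels.append(tm.Condition.S2_NIL.value)
                    for label in labels:
                        rows = _select(events, phase, info["label_col"], label,
                                       info["freq_col"], freq, correct_only=True)
                        if label == tm.Condition.S2_NIL.value:
                            groups = [
                                (f"{label}_{task}", rows[rows["task"] == task])
                                for task in sorted(rows["task"].unique())
                            ]
                        else:
                            groups = [(label, rows)]
                        for cond_name, grp in groups:
                            if len(grp) < cfg.min_trials:
                                continue
                            during = _spike_rates(session, unit, grp, info["anchor"],
                                                  cfg.during_spike_window)
                            before = _spike_rates(session, unit, grp, info["anchor"],
                                                  cfg.before_spike_window)
                            norm_rows.append({
                                "unit_id": unit, "freq": freq, "phase": phase,
                                "condition": cond_name,
                                "response": spk.normalized_response(
                                    during, before, floor=cfg.rate_floor),
                                "n_trials": len(grp),
                            })
    normalized = pd.DataFrame(norm_rows)

    # --- false-alarm records ----------------------------------------------
    fa_rows = []
    task_ratio = ratios[(ratios["phase"] == "task") & (ratios["window"] == "DURING")]
    for unit in units:
        for freq in freqs:
            rec = {"unit_id": unit, "freq": freq}
            for pos in ("S1", "S2"):
                sub = task_ratio[
                    (task_ratio["unit_id"] == unit)
                    & (task_ratio["freq"] == freq)
                    & (task_ratio["position"] == pos)
                ]
                rec[f"sig_during_{pos.lower()}"] = bool(sub["significant"].any())
            info1, info2 = _POSITIONS["S1"], _POSITIONS["S2"]
            selections = {
                "s1_nogo_fa": (info1, tm.Condition.S1_NO_GO.value,
                               (tm.Outcome.FALSE_ALARM.value,)),
                "s1_nogo_correct": (info1, tm.Condition.S1_NO_GO.value, _CORRECT),
                "s2_nogo_fa": (info2, tm.Condition.S2_NO_GO.value,
                               (tm.Outcome.FALSE_ALARM.value,)),
                "s2_nogo_correct": (info2, tm.Condition.S2_NO_GO.value, _CORRECT),
                "s2_go_correct": (info2, tm.Condition.S2_GO.value,
                                  (tm.Outcome.HIT.value,)),
            }
            for name, (info, label, outcomes) in selections.items():
                rows = events[
                    (events["phase"] == "task")
                    & (events[info["label_col"]] == label)
                    & (events[info["freq_col"]] == freq)
                    & (events["outcome"].isin(outcomes))
                ]
                if name == "s1_nogo_fa":
                    rec["n_fa_s1"] = len(rows)
                if name == "s2_nogo_fa":
                    rec["n_fa_s2"] = len(rows)
                if len(rows) == 0:
                    rec[name] = np.nan
                    continue
                during = _spike_rates(session, unit, rows, info["anchor"],
                                      cfg.during_spike_window)
                before = _spike_rates(session, unit, rows, info["anchor"],
                                      cfg.before_spike_window)
                rec[name] = spk.normalized_response(during, before, floor=cfg.rate_floor)
            fa_rows.append(rec)
    fa_records = pd.DataFrame(fa_rows)

    # --- behavior, best frequencies ----------------------------------------
    task_events = events[events["phase"] == "task"]
    behavioral = tm.behavioral_summary(task_events) if len(task_events) else pd.DataFrame()

    bf_rows = []
    tuning = events[events["phase"] == "tuning"]
    if len(tuning):
        for unit in units:
            trains = [session.spikes[unit][int(t)] for t in tuning["trial_id"]]
            onsets = tuning["t_s1_on"].to_numpy(dtype=float)
            evoked = spk.window_rates(trains, [(a, a + 0.150) for a in onsets])
            base = spk.window_rates(trains, [(a - 0.150, a) for a in onsets])
            bf = spk.best_frequency(tuning["s1_freq"].to_numpy(dtype=float), evoked, base)
            bf_rows.append({
                "unit_id": unit,
                "best_frequency": np.nan if bf is None else bf,
                "octave_distance_3k": np.nan if bf is None else spk.octave_distance(bf, 3000.0),
            })
    best_frequencies = pd.DataFrame(bf_rows)

    # --- LFP ratios ---------------------------------------------------------
    lfp_rows = []
    if with_lfp and session.lfp is not None:
        for site in range(session.n_lfp_sites):
            for ifreq, freq in enumerate(freqs):
                for ipos, (pos, info) in enumerate(_POSITIONS.items()):
                    num_rows = _select(events, "task", info["label_col"], info["num"],
                                       info["freq_col"], freq, correct_only=True)
                    den_rows = _select(events, "task", info["label_col"], info["den"],
                                       info["freq_col"], freq, correct_only=True)
                    num_rows = num_rows[num_rows["trial_id"].isin(session.lfp_trial_ids)]
                    den_rows = den_rows[den_rows["trial_id"].isin(session.lfp_trial_ids)]
                    for iwin, (kind, window) in enumerate(
                        (("DURING", cfg.during_lfp_window),
                         ("BEFORE", cfg.before_lfp_window))
                    ):
                        record = {
                            "site_id": site, "freq": freq, "position": pos,
                            "window": kind, "n_num": len(num_rows), "n_den": len(den_rows),
                            "ratio": np.nan, "p_value": np.nan,
                        }
                        if len(num_rows) >= cfg.min_trials and len(den_rows) >= cfg.min_trials:
                            tr_num, rel0 = _tone_aligned_lfp(session, num_rows, site,
                                                             info["anchor"])
                            tr_den, _ = _tone_aligned_lfp(session, den_rows, site,
                                                          info["anchor"])
                            result = lfp_mod.lfp_condition_ratio(
                                tr_num, tr_den, session.lfp_sampling_rate, rel0,
                                window=window, numerator=info["num"],
                                denominator=info["den"], window_kind=kind,
                                alpha=cfg.alpha, n_perm=min(cfg.n_perm, 500),
                                rng=_rng(cfg.seed, 3, site, ifreq, ipos, iwin),
                                per_trial=cfg.lfp_per_trial_rms,
                                min_trials=cfg.min_trials,
                            )
                            record["ratio"] = result.ratio
                            record["p_value"] = result.p_value
                        lfp_rows.append(record)
    lfp_ratios = pd.DataFrame(lfp_rows)
    if len(lfp_ratios):
        lfp_ratios["significant"] = lfp_ratios["p_value"] < cfg.alpha

    # --- population traces ---------------------------------------------------
    traces = {}
    if with_traces:
        traces = _population_traces(session, ratios, cfg)

    return SessionAnalysis(
        session_id=session_id,
        ratios=ratios,
        responsiveness=responsiveness,
        normalized=normalized,
        fa_records=fa_records,
        behavioral=behavioral,
        best_frequencies=best_frequencies,
        lfp_ratios=lfp_ratios,
        traces=traces,
        tone_probabilities=_session_tone_probs(session),
    )


def _tone_aligned_lfp(session: Session, rows: pd.DataFrame, site: int,
                      anchor: str) -> tuple[np.ndarray, float]:
    """LFP traces for the given trials with t0 re-expressed relative to the anchor."""
    traces, t0s = session.lfp_traces(rows["trial_id"].to_numpy(), site)
    rel = t0s - rows[anchor].to_numpy(dtype=float)
    rel0 = float(np.median(rel))
    if np.max(np.abs(rel - rel0)) > 0.5 / session.lfp_sampling_rate:
        raise InvalidInputError("LFP traces are not uniformly aligned to the anchor")
    return traces, rel0


def _population_traces(session: Session, ratios: pd.DataFrame,
                       cfg: RunConfig) -> dict:
    """Geometric-mean normalized PSTH traces for units with significant ratios."""
    events = session.events
    out = {}
    for pos, info in _POSITIONS.items():
        for freq in cfg.frequencies:
            sig_units = ratios[
                (ratios["phase"] == "task") & (ratios["window"] == "DURING")
                & (ratios["position"] == pos) & (ratios["freq"] == freq)
                & ratios["significant"]
            ]["unit_id"].tolist()
            if len(sig_units) < 1:
                continue
            cond_traces = {}
            bin_edges = (-0.050, 1.0)
            for label in (info["num"], info["den"]):
                rows = _select(events, "task", info["label_col"], label,
                               info["freq_col"], freq, correct_only=True)
                if len(rows) < cfg.min_trials:
                    continue
                psths, baselines = [], []
                for unit in sig_units:
                    trains = [session.spikes[unit][int(t)] for t in rows["trial_id"]]
                    anchors = rows[info["anchor"]].to_numpy(dtype=float)
                    aligned = [tr - a for tr, a in zip(trains, anchors)]
                    _, rates = spk.psth(aligned, bin_edges[0], bin_edges[1],
                                        bin_width=cfg.bin_width)
                    psths.append(rates)
                    baselines.append(
                        float(np.mean(spk.window_rates(
                            trains,
                            [(a + cfg.before_spike_window[0],
                              a + cfg.before_spike_window[1]) for a in anchors],
                        )))
                    )
                cond_traces[label] = (np.array(psths), np.array(baselines))
            if len(cond_traces) < 2:
                continue
            centers, _ = spk.psth([], bin_edges[0], bin_edges[1], bin_width=cfg.bin_width)
            entry = {"bin_centers": centers, "units": sig_units}
            norm = {}
            for label, (psths, baselines) in cond_traces.items():
                entry[f"trace_{label}"] = spk.geometric_average_normalized(
                    psths, baselines, floor=cfg.rate_floor)
                norm[label] = np.maximum(psths, cfg.rate_floor) / \
                    np.maximum(baselines, cfg.rate_floor)[:, None]
            labels = list(cond_traces)
            entry["per_bin_p"] = spk.per_bin_condition_test(
                norm[labels[0]], norm[labels[1]],
                min_units=cfg.min_units_for_trace_test)
            out[f"{pos}_{int(freq)}"] = entry
    return out


def population_report(
    analyses: list[SessionAnalysis],
    cfg: RunConfig | None = None,
) -> dict:
    """Aggregate analyzed sessions into the population-level report."""
    cfg = cfg or RunConfig()
    if not analyses:
        raise InvalidInputError("no session analyses supplied")

    ratios = pd.concat(
        [a.ratios.assign(session_id=a.session_id) for a in analyses], ignore_index=True
    )
    responsiveness = pd.concat(
        [a.responsiveness.assign(session_id=a.session_id) for a in analyses],
        ignore_index=True,
    )
    normalized = pd.concat(
        [a.normalized.assign(session_id=a.session_id) for a in analyses],
        ignore_index=True,
    )
    fa_records = pd.concat(
        [a.fa_records.assign(session_id=a.session_id) for a in analyses],
        ignore_index=True,
    )

    report: dict = {"n_sessions": len(analyses), "alpha": cfg.alpha, "positions": {}}

    for pos in ("S1", "S2"):
        report["positions"][pos] = {}
        for freq in cfg.frequencies:
            entry: dict = {}
            resp_ok = responsiveness[
                (responsiveness["freq"] == freq)
                & (responsiveness["phase"] == "task")
                & responsiveness["responsive"]
            ][["session_id", "unit_id"]]
            key = pd.MultiIndex.from_frame(resp_ok)

            def grab(window: str, phase: str) -> pd.DataFrame:
                sub = ratios[
                    (ratios["freq"] == freq) & (ratios["position"] == pos)
                    & (ratios["window"] == window) & (ratios["phase"] == phase)
                    & ratios["ratio"].notna()
                ]
                if cfg.require_responsive:
                    idx = pd.MultiIndex.from_frame(sub[["session_id", "unit_id"]])
                    sub = sub[idx.isin(key)]
                return sub

            during = grab("DURING", "task")
            before = grab("BEFORE", "task")
            entry["n_units"] = len(during)
            if len(during) == 0:
                report["positions"][pos][freq] = entry
                continue
            d_sum = pop.summarize_ratios(during["ratio"], during["p_value"], cfg.alpha)
            entry["during"] = _summary_dict(d_sum)
            if len(before):
                b_sum = pop.summarize_ratios(before["ratio"], before["p_value"], cfg.alpha)
                entry["before"] = _summary_dict(b_sum)
                entry["p_during_vs_before_proportions"] = pop.compare_proportions(
                    d_sum.n_significant, d_sum.n_units,
                    b_sum.n_significant, b_sum.n_units, alternative="greater")

            # attribution accounting
            both = during.merge(
                before, on=["session_id", "unit_id"], suffixes=("_d", "_b"))
            sig_d = both[both["significant_d"]]
            n_cue = int(sig_d["significant_b"].sum())
            passive = grab("DURING", "passive")
            if len(passive):
                merged = sig_d.merge(passive, on=["session_id", "unit_id"],
                                     suffixes=("", "_p"))
                n_passive_tested = len(merged)
                n_passive_sig = int(merged["significant"].sum())
            else:
                n_passive_tested = None
                n_passive_sig = None
            try:
                attribution = pop.attribution_accounting(
                    d_sum.n_units, d_sum.n_significant, n_cue,
                    n_passive_tested, n_passive_sig)
                entry["attribution"] = _attribution_dict(attribution)
            except InvalidInputError as exc:
                entry["attribution"] = {"error": str(exc)}
            report["positions"][pos][freq] = entry

    # six-condition comparison per frequency
    report["six_condition"] = {}
    for freq in cfg.frequencies:
        table = _six_condition_table(ratios, normalized, freq, cfg)
        if table is None:
            report["six_condition"][freq] = {"note": "insufficient data"}
            continue
        result = pop.six_condition_comparison(table, alpha=cfg.alpha)
        report["six_condition"][freq] = {
            "n_units": int(table.shape[0]),
            "medians": {c: float(m) for c, m in result.medians.items()},
            "p_matrix": {a: {b: float(result.p_matrix.loc[a, b])
                             for b in result.p_matrix.columns}
                         for a in result.p_matrix.index},
            "alpha_corrected": result.alpha_corrected,
        }

    # false-alarm contrasts, pooled across sessions and frequencies
    contrasts = pop.false_alarm_contrasts(fa_records, min_fa_trials=cfg.min_trials)
    report["false_alarm"] = {
        name: {"n": c.n, "median": c.median, "p_vs_1": c.p_vs_1}
        for name, c in contrasts.items()
    }

    # tone-probability bookkeeping / subset analysis (3-kHz tone)
    sessions_df = _probability_table(analyses)
    report["tone_probability"] = {}
    if sessions_df is not None:
        report["tone_probability"]["median_ratio"] = pop.median_probability_ratio(sessions_df)
        units_df = _subset_units_table(ratios, freq=3000.0)
        try:
            subset = pop.probability_subset_analysis(sessions_df, units_df)
            report["tone_probability"]["subset"] = {
                "median_ratio": subset.median_ratio,
                "prop_high": subset.prop_high, "prop_low": subset.prop_low,
                "p_one_tailed": subset.p_one_tailed,
            }
        except InvalidInputError as exc:
            report["tone_probability"]["subset"] = {"note": f"not estimable: {exc}"}

    # behavior
    behavioral = pd.concat(
        [a.behavioral.assign(session_id=a.session_id) for a in analyses
         if len(a.behavioral)],
        ignore_index=True,
    ) if any(len(a.behavioral) for a in analyses) else pd.DataFrame()
    if len(behavioral):
        report["behavior"] = {
            "median_dprime": float(behavioral["dprime"].median()),
            "median_hit_rate": float(behavioral["hit_rate"].median()),
            "median_fa_rate": float(behavioral["fa_rate"].median()),
            "n_task_sequences": int(len(behavioral)),
        }

    # LFP population summary
    lfp_all = pd.concat(
        [a.lfp_ratios.assign(session_id=a.session_id) for a in analyses
         if len(a.lfp_ratios)],
        ignore_index=True,
    ) if any(len(a.lfp_ratios) for a in analyses) else pd.DataFrame()
    if len(lfp_all):
        report["lfp"] = {}
        for pos in ("S1", "S2"):
            sub = lfp_all[
                (lfp_all["position"] == pos) & (lfp_all["window"] == "DURING")
                & (lfp_all["freq"] == 3000.0) & lfp_all["ratio"].notna()
            ]
            if len(sub) == 0:
                continue
            summary = pop.summarize_ratios(sub["ratio"], sub["p_value"], cfg.alpha)
            report["lfp"][pos] = _summary_dict(summary)

    return report


def _summary_dict(s: pop.PopulationRatioSummary) -> dict:
    return {
        "n_units": s.n_units,
        "median": s.median,
        "min": s.minimum,
        "max": s.maximum,
        "p_median_vs_1": s.p_median_vs_1,
        "n_significant": s.n_significant,
        "n_significant_gt1": s.n_significant_gt1,
        "fraction_significant": s.fraction_significant,
    }


def _attribution_dict(a: pop.AttributionResult) -> dict:
    out = {
        "n_total": a.n_total,
        "n_during_sig": a.n_during_sig,
        "n_cue_attributed": a.n_cue_attributed,
        "n_remainder": a.n_remainder,
        "pct_remainder_of_sig": a.pct_remainder_of_sig,
        "pct_remainder_of_sig_int": a.pct_remainder_of_sig_int,
        "pct_remainder_of_total": a.pct_remainder_of_total,
    }
    if a.context_estimable:
        out.update({
            "n_passive_tested": a.n_passive_tested,
            "n_passive_sig": a.n_passive_sig,
            "n_context_attributed": a.n_context_attributed,
        })
    else:
        out["context"] = "not estimable (no passive blocks)"
    return out


def _six_condition_table(ratios: pd.DataFrame, normalized: pd.DataFrame,
                         freq: float, cfg: RunConfig) -> pd.DataFrame | None:
    """Units x condition table of normalized responses, restricted to units
    with a significant during-S1 or during-S2 ratio at this frequency."""
    sig = ratios[
        (ratios["freq"] == freq) & (ratios["phase"] == "task")
        & (ratios["window"] == "DURING") & ratios["significant"]
    ][["session_id", "unit_id"]].drop_duplicates()
    if len(sig) == 0:
        return None
    key = pd.MultiIndex.from_frame(sig)
    sub = normalized[(normalized["freq"] == freq) & (normalized["phase"] == "task")]
    idx = pd.MultiIndex.from_frame(sub[["session_id", "unit_id"]])
    sub = sub[idx.isin(key)]
    if len(sub) == 0:
        return None
    table = sub.pivot_table(index=["session_id", "unit_id"], columns="condition",
                            values="response")
    return table if table.shape[0] >= 2 else None


def _probability_table(analyses: list[SessionAnalysis]) -> pd.DataFrame | None:
    rows = []
    for a in analyses:
        probs = a.tone_probabilities
        try:
            rows.append({
                "session_id": a.session_id,
                "p_task1": probs[tm.Task.TASK1.value][3000.0],
                "p_task2": probs[tm.Task.TASK2.value][3000.0],
            })
        except KeyError:
            continue
    return pd.DataFrame(rows) if rows else None


def _subset_units_table(ratios: pd.DataFrame, freq: float) -> pd.DataFrame:
    sub = ratios[
        (ratios["freq"] == freq) & (ratios["phase"] == "task")
        & (ratios["window"] == "DURING") & (ratios["position"] == "S1")
        & ratios["ratio"].notna()
    ]
    return pd.DataFrame({
        "session_id": sub["session_id"].to_numpy(),
        "significant_gt1": (sub["significant"] & (sub["ratio"] > 1.0)).to_numpy(),
    })
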