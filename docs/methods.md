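# Methods

## Paradigm model

Two tasks share the four two-tone sequences 3–3, 3–1, 1–3, 1–1 (tones of
200 ms at 3 kHz or 1 kHz, stimulus-onset interval 1.0 s, hence an 800-ms
silent delay).  Task 1 requires the go response (bar release inside a
response window after S2 offset) for 3–3; Task 2 for 1–1.  The response
window defaults to 40–1160 ms after S2 offset and is configurable
(40–1760 ms is the other subject's window in the paradigm this emulates).
All intervals in the package are half-open `[start, end)`; all times are
trial-relative seconds, with S1 onset as the canonical analysis anchor.

Condition labels follow the ideal observer: an S1 that is not the first
tone of the task's go sequence already determines no-go (`S1_NO_GO`);
otherwise the trial is unresolved (`S1_UNCERTAIN`) and S2 resolves it
(`S2_GO` / `S2_NO_GO`); after a decisive S1, S2 is uninformative
(`S2_NIL`).  Outcomes are HIT / MISS / FALSE_ALARM / CORRECT_REJECTION by
whether a release falls inside the window.

Behavioral discriminability is d′ = z(hit rate) − z(false-alarm rate),
one value per no-go sequence.  Rates of exactly 0 or 1 are replaced by
1/(2n) and 1 − 1/(2n); the log-linear alternative was rejected as
needlessly elaborate for per-session rates with n ≈ 50–500.

## Statistics

**Windows.**  Spikes: during = [0, 250) ms from tone onset (tone plus a
50-ms offset-response margin), before = [−250, 0) ms.  LFP: during =
[0, 500) ms, before = [−500, 0) ms.  The best-frequency block uses
[0, 150) ms evoked versus [−150, 0) ms baseline for its 100-ms tones.

**Condition ratio.**  Trial-averaged rate (or RMS-LFP) in one condition
divided by the matched condition.  Rates below ε = 0.1 spikes/s are
floored at ε before any division or logarithm, so log-domain statistics
remain finite for silent units; ε is far below any plausible baseline so
it only affects pathological cells.  A minimum of 5 trials per condition
is required (the same threshold as the false-alarm inclusion rule).

**Permutation test.**  Two-sided on |log ratio|: condition labels are
reassigned across the pooled trials preserving group sizes.  When the
number of distinct assignments is ≤ n_perm (default 1000) the null is
enumerated exhaustively and p = k/N; otherwise n_perm draws are scored
with the add-one estimate (1 + k)/(n_perm + 1), which cannot return 0.
Ties with the observed statistic count against rejection (a 1e-12
absolute guard absorbs floating-point noise).  The same machinery drives
the LFP ratio test, where the statistic is recomputed on the re-averaged
potential of each permuted assignment; RMS on the trial-averaged evoked
potential is the default because averaging first suppresses
non-phase-locked noise (a per-trial-RMS variant sits behind
`RunConfig.lfp_per_trial_rms`).

**Responsiveness preselection.**  A unit/site enters the population
summaries only if a paired sign-flip permutation test finds a
before-versus-during difference (p < 0.05) in at least one of the four
informative conditions, evaluated separately per phase (task/passive),
modality and tone frequency.

**Population traces.**  10-ms-bin PSTHs are normalized per unit to its
250-ms pre-tone baseline and geometrically averaged; bins and baselines
are floored at ε first, so every unit contributes positive values.  LFP
traces use per-bin RMS of the site-averaged potential normalized to the
mean pre-onset bin RMS.  Per-bin condition differences use the two-sided
Wilcoxon signed-rank across units, uncorrected (the trace stars are
descriptive), skipped below 6 units.

**Population tests.**  Median-vs-1 tests are two-sided Wilcoxon
signed-rank on log ratios (two-sided because both >1 and <1 ratios are
reported).  Proportion comparisons use the 2×2 chi-square without
continuity correction; the one-tailed p is half the two-tailed p when
the observed direction matches the alternative (Fisher's exact test is
available for small tables).  The six-condition comparison tests all
pairs but judges the planned no-go-versus-other comparisons at α/4 =
0.0125.  False-alarm contrasts pool unit × frequency records (a unit
significant at both frequencies contributes twice) and require ≥ 5
false-alarm trials.

**Attribution accounting.**  Of the units with significant during
ratios, those whose before ratio is also significant are attributed to
the visual cue; the passive-condition significance rate among the
passively tested subset, projected onto all significant units and
rounded half-up, is attributed to acoustic context; the remainder is the
minimum association-related count.  Half-up rounding is the unique
choice consistent with integer unit counts in both worked examples the
test suite pins.  Without passive blocks the context term is reported as
"not estimable" rather than silently zero.

**Tone-probability subset analysis.**  Per session, the ratio of the
analyzed tone's probability in Task 1 versus Task 2; sessions split at
the median ratio (ties dropped), and the proportions of units with
significant ratios > 1 are compared one-tailed in the direction
adaptation would predict (larger probability contrast → larger ratios).

## Synthetic sessions

The generator emulates the paradigm's statistical structure, not its
biophysics.  Defaults are the study conditions: alternating blocks of
140 trials (2 per task by default), go fraction 0.60 (admissible
0.50–0.77), no-go sequences at 0.13/0.13/0.14 so the scheduled per-tone
probability of the task's go frequency is exactly 0.73 in its own task
and 0.27 in the other (median Task1/Task2 ratio 0.73/0.27 ≈ 2.70);
false-alarm rates 0.16 for sequences whose S1 is decisive and 0.05 for
sequences resolved at S2; miss rate 0.05; passive blocks replaying both
schedules with inter-sequence intervals uniform in [3.5, 4.5] s and no
outcomes; and a tuning block of 40 log-spaced tones over 8 octaves
(0.0625–16 kHz, 10 repetitions, 100-ms tones, 500-ms onset interval).
Sequence order is stratified per block (exact scheduled counts, then
permuted) to stabilize small-session tests; per-block go-fraction jitter
is available to emulate block-to-block variation.

Each unit's firing-rate profile is baseline (plus a tonic cue offset in
Task 2) with a multiplicative evoked step during each tone, scaled by
Gaussian log-frequency tuning, by adaptation `1 − a·p(freq)` with `p`
the scheduled tone probability, and by forward suppression when S2
repeats S1.  The no-go differential (`nogo_gain`) multiplies the
during-tone rate from 70 ms after onset — the latency at which the
condition traces diverge — on correctly performed task trials only; on
false alarms the response is go-like, which is what makes the
false-alarm contrasts behave as they do.  A triangular motor ramp
(onset −300 ms, peak −200 ms relative to release) is added on released
trials.  Spikes are sampled by thinning against the profile supremum on
a 1-ms grid; substreams are derived per (stream, unit, trial) from one
seed, so adding units never perturbs existing ones.

LFPs are two Gaussian-windowed deflections per tone (the second scaled
by the site's no-go gain, where the condition differences are most
pronounced) plus Gaussian noise with power ∝ 1/f band-limited to
1–140 Hz, the recording bandwidth the analysis assumes; no further
filtering is applied downstream.

The heterogeneous population preset (`paper_like_units`) draws baselines
10–30 spikes/s, best frequencies log-uniform over 1–8 kHz, evoked gains
2–4, no-go gains lognormal about 1.3, cue offsets ~N(0, 1) spikes/s,
adaptation strengths 0.05–0.2 and forward suppression 0–0.15.  The
context effects are deliberately weak: the 800-ms gap between S1 and S2
is beyond the time scale of most cortical forward suppression, and in
this paradigm the acoustic context accounts for only a minority of the
significant condition differences, so a faithful generator must let the
association effect dominate.  No effect size is fitted to recordings;
they are chosen for statistical power of the downstream tests and
labeled as such.

**What passing tests do and do not show.**  The generator shares trial
structure across units (no unit-to-unit correlation beyond shared
trials), uses piecewise-stationary Poisson firing (no refractoriness,
bursting or slow drift), and makes behavioral errors independent of the
simulated neural state except through the label switch on false alarms.
Passing tests therefore validate the statistical pipeline — calibration,
power, bookkeeping, invariances — not any claim about real cortical
data.

## Numerical choices and degenerate inputs

Half-open windows everywhere, with a 1e-12 tolerance on bin and window
edges; samples/spikes exactly at the upper edge are excluded.  Degenerate
permutation inputs (all values equal) give p = 1 by construction.  A zero
denominator after flooring raises `UndefinedRatioError` and excludes the
unit with a log entry, as does a zero LFP baseline.  Negative
intermediate rates (large negative cue offsets) are clipped at zero and
logged.  Conditions with fewer than the minimum trials are skipped and
logged, so every denominator in the report is auditable.

## Problem sizes

The test suite and acceptance script run at desk scale as the package's
own choice of problem size: calibration over 500 simulated null units
(40 trials per side), recovery over 50 units (80 trials per condition),
and the qualitative pattern on one preset session of 8 blocks per task
(140 trials each) with 16 units, analyzed at 500–1000 permutations.  The
per-unit example ratios and population medians of any particular
recording are not reproducible from synthetic data; the pipeline instead
pins the deterministic bookkeeping exactly and the stochastic machinery
by calibration.

## Known limitations

Single-unit isolation, anatomical localization, time-frequency LFP
analysis, spike-field coherence and hierarchical (session/subject)
models are out of scope.  The during-S2 LFP ratio can be contaminated by
release-related activity inside its 500-ms window; no correction is
applied, matching the analysis this pipeline mirrors, and the caveat
propagates to any conclusion drawn from that statistic.  The exact
permutation scheme (statistic, sidedness, count) is declared here rather
than inferred from any source; alternative schemes would change per-unit
p-values but not the pipeline's structure.
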