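# Methods

This note documents the analysis conventions, the generative model behind
the synthetic observers, the numerical choices, and what the simulator does
and does not emulate.

## Paradigm and data model

One *trial* contains two successively presented circular search stimuli
(*intervals*). One interval always shows the *standard* stimulus (scale
0.7); the other shows a *comparison* at one of seven scales 0.4–1.0. A
stimulus at scale *s* is a disc of radius 7.5·*s* degrees of visual angle;
when a target is present its eccentricity lies in [2·*s*, 5.5·*s*] degrees.
Target presence follows one of four patterns per trial —
(standard, comparison) ∈ {1-0, 0-1, 1-1, 0-0} — each crossed with all seven
scales and repeated 10 times: 280 main trials per participant, preceded by
12 practice trials that are generated, flagged, and never analysed.
Presentation order is counterbalanced within every scale × condition cell
(5 standard-first / 5 comparison-first; odd repetition counts put the extra
trial on the standard-first side).

Observers answer, per interval, "target present?" (R+/R−) and then choose
the interval they are more confident about. All analyses work on two flat
tables (`trials.csv`, one row per interval; `fixations.csv`), in degrees of
visual angle with the origin at the stimulus centre and y increasing upward.

## Screening conventions

* Fixations shorter than 150 ms are excluded. The boundary stays: a
  150 ms fixation is retained (the rule removes "shorter than").
* A trial is invalid when either interval has a blink or no retained
  fixation inside the stimulus disc (full radius 7.5·*s*, no margin).
  Blinks arrive as a per-interval flag; no blink detection is performed.
* A participant is excluded when *strictly more than* 10% of their main
  trials are invalid; practice trials never count toward this fraction.
* `dmin` (minimum Euclidean gaze-target distance) is computed on
  duration-filtered fixations only, for valid target-present intervals.

## Signal detection

HR and FAR are conditional response rates per grouping cell; rates of
exactly 0 or 1 are moved to 0.5/N and 1 − 0.5/N, with N the cell's own
count on the relevant margin (n\_present for HR, n\_absent for FAR).
Sensitivity is d′ = z(HR) − z(FAR) and the criterion is
**c = −(z(HR) + z(FAR))/2**, so that a positive c denotes a conservative
bias (a preference for "absent" responses): with HR ≈ 0.36 and FAR ≈ 0.14
this yields c ≈ +0.72, matching the conservative reading; the sign and the
factor ½ follow the standard equal-variance definition.

Scale cells pool both intervals of a trial, each at its own scale (the
standard stimulus always contributes at 0.7). `RunConfig
.pool_standard_in_scale_cells=False` restricts cells to comparison
intervals instead.

Per-participant measures are regressed on scale − 0.7 by ordinary least
squares, so the intercept is the prediction at the standard scale; slopes
and intercepts are then tested across participants with two-sided
one-sample t-tests (α = 0.05, 95% CIs). Cells with an undefined measure
are dropped; a regression needs ≥ 2 remaining scale levels. With zero
variance across participants the t-test is degenerate: we report t = 0 and
p = 1 on the reference, ±∞ and p = 0 off it.

## Distance analyses

The AUC is the rank (Mann–Whitney) estimator
\[#(d_neg > d_pos) + ½·ties\] / (n_pos·n_neg) — the probability that an
unfavourable interval (miss, or non-chosen) lies farther from the target
than a favourable one; ties get half credit. The chosen-vs-non-chosen AUC
uses trials with exactly one hit interval and compares that interval's
`dmin` between chosen and not-chosen trials.

Rate curves use adjacent half-open bins [k·0.5, (k+1)·0.5) degrees starting
at 0 (window = step = 0.5°); a bin's rate is reported only with ≥ 6
observations. The cross-participant correlation relates each bin's hit
rate to the participants' overall FAR (≥ 3 defined participants per bin);
the per-participant curve correlation relates the hit-rate and
choice-rate curves over their common defined bins (≥ 3).

## Confidence scoring

Response patterns are coded on **responses**, not target presence. The
0-0 preference regression uses y = "comparison chosen" against
x = scale(standard) − scale(comparison). For the 1-0 condition (0-1 trials
mirrored in) the default coding is response-relative: y = "present-response
interval chosen", x = scale(absent-response) − scale(present-response), so
the intercept at x = 0 is the present-response preference at equal scales;
the comparison-relative coding remains available
(`coding="comparison"`). Choices are aggregated to proportions per distinct
x before the OLS fit (each distinct scale difference weighted equally), and
fits require ≥ 2 distinct x values.

Type-2 accuracy is scored on discordant trials (exactly one interval's
type-1 decision correct) as the proportion in which the correct interval
was chosen; participants are averaged, then tested. The outcome-pair
decomposition keeps a participant's cell only with ≥ 6 trials; with the
filter disabled the pair accuracies aggregate exactly back to the overall
type-2 accuracy when weighted by cell counts.

## Synthetic searching observer

The simulator is a generative stand-in for real behaviour with just enough
structure for every analysis to have a defined target:

* **Fixations** — count per interval is 1 + Poisson(λ) with
  λ = mean − 1 (support ≥ 1; default mean 2.36); positions are uniform in
  area over a disc of radius `fixation_spread`·7.5·s (default 0.7, never
  outside the stimulus); durations are gamma (default mean 280 ms,
  sd ≈ 99 ms). The duration default keeps the share of sub-150 ms
  fixations near 9%, so that trial invalidity stays in the few-percent
  range despite frequent single-fixation intervals; real data show more
  short fixations, but also correlated fixation counts that the
  independent-draws model lacks.
* **Detection** — a present target at minimum gaze distance `dmin` is
  detected with probability (1 − lapse)·g(dmin), g logistic with midpoint
  `detect_d50` (default 2.0°) and slope `detect_slope` (default 4.0 /°,
  chosen so detection is effectively impossible beyond ~3°, consistent with
  reliable detection only within ~2–3° of the target). Only fixations of at
  least `min_uptake_duration_ms` (default 150 ms) can drive detection —
  the same premise that motivates the analysis-side duration filter.
* **Response** — detection forces R+; otherwise R+ is a guess with
  probability guess\_rate + criterion\_scale\_gain·(s − 0.7), clamped to
  [0, 1] (defaults 0.14 and 0, i.e. scale-independent guessing; the gain is
  exposed to explore whether a scale-dependent criterion must be generative
  or can arise in analysis).
* **Confidence** — each interval gets a score
  conf\_w\_detect·evidence − conf\_w\_scale·scale + N(0, conf\_noise\_sd),
  with evidence 1 + g(dmin) when detected and low-mean exponential noise
  (mean 0.1) otherwise; the larger score is chosen, exact ties at random.
  Defaults (1.0, 0.5, 0.3) make detection dominate while leaving a
  measurable small-stimulus preference on 0-0 trials.
* **Staircase** — contrast steps are additive in log10 contrast (default
  0.1), halved once after the first two reversals; contrast rises after
  each error and falls after two consecutive correct responses, which
  converges on √0.5 ≈ 70.7% correct. The psychometric is cumulative
  Gaussian with lower asymptote 0.5.
* **Blinks** — independent per interval with probability 0.01; combined
  with fixation screening this puts mean trial invalidity near 4%.

Everything is driven by one integer seed; identical seed and configuration
reproduce the output tables byte for byte.

**What passing tests on simulated data do not show:** the simulator has no
saccade dynamics, no spatial or temporal correlation in fixation placement,
no memory across intervals, no learning or fatigue, and its confidence
rule is a fixed linear comparison. Analyses validated here are therefore
shown to be *correct implementations*, not validated against the richness
of real gaze data.

## Numerical choices

* The cumulative-Gaussian staircase fit maximizes the trial-level Bernoulli
  likelihood (L-BFGS-B, μ ∈ (0, 1], σ ∈ [1e−4, 1]) from four start points;
  fits with degenerate responses or parameters at the lower bounds carry
  `converged=False`. γ is fixed at 0.5 (two-alternative task) and the lapse
  at 0, both overridable.
* Pearson correlations require n ≥ 3 and nonzero variance, else NaN;
  df = n − 2.
* CSVs are written with a fixed float format ("%.10g") so that seeded runs
  are byte-identical.

## Problem sizes

Tests and the acceptance script use cohorts of 22 simulated observers at
280 trials each for parameter recovery, 10,000 Monte-Carlo draws for
rate-level checks (e.g. chance-level type-2 accuracy of an evidence-blind
chooser), 3,000-trial staircase runs with step 0.02 log-units for the
70.7% convergence check (first 1,000 trials discarded as burn-in), and
2,000 trials sampled uniformly over contrasts 0.01–0.1 — the informative
region around the true threshold μ = 0.05 — for psychometric recovery
within ±10%. The hit-rate crossing point is read off the pooled
hit-rate-by-distance curve by linear interpolation at
guess\_rate + (1 − guess\_rate)/2.

## Known limitations

* Inputs must already be in degrees of visual angle and parsed into
  fixations; pixel conversion and event detection are out of scope.
* No meta-d′ or other model-based metacognition measures, no
  unequal-variance SDT, no parametric ROC fits, no mixed-effects
  alternatives to the two-stage statistics — the pipeline mirrors the
  summary-statistics approach it implements.
* The preference-regression coding for the 1-0 condition is a documented
  reconstruction (response-relative by default) because a
  comparison-relative fit cannot express a present-response preference in
  its intercept; both codings are available.
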