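# Methods

This note documents the models and procedures implemented in
`screenrhythms`, the conventions chosen where the problem is genuinely
underdetermined, and what the synthetic-data tests do and do not
demonstrate.

## Weekly activity rhythms

Each participant's screen-on events over the whole observation window are
counted into hour-of-week bins, `bin = 24·weekday + hour` with Monday as
day 0, and divided by the participant's total so the 168 fractions sum to
one. Conventions:

- **Timezone/DST.** Timestamps are local wall-clock time. On daylight-saving
  transition days the 23- or 25-hour wall-clock day is binned by wall-clock
  hour with no correction: behaviour is anchored to local social time.
- **Resolution.** Sub-hour event times are floored to the containing hour;
  all downstream analysis is at one-hour resolution.
- **Window.** The default window is ISO weeks 2–51 of 2014 (Monday
  2014-01-06 … Sunday 2014-12-21, 350 days); the first and last ISO weeks
  of a year straddle year boundaries and holiday behaviour.
- **Inclusion filters.** A participant is retained when they have ≥ 1
  screen-on event on at least 80% of the window's days and average ≥ 280
  combined screen-on + screen-off events per week. Screen-off events count
  only toward the rate criterion; rhythms use screen-on events alone, as
  the activity proxy.

## NMF with HALS

The population matrix X (N × 168, rows non-negative and summing to one) is
factorized as X ≈ W Hᵀ by minimizing E = ½‖X − WHᵀ‖²_F subject to
W, H ≥ 0.

- **Optimizer.** Hierarchical alternating least squares: each column of W
  and then of H receives its exact non-negatively projected least-squares
  update per sweep. The objective is non-increasing across sweeps (asserted
  in tests to 1e-12).
- **Initialization.** Entries i.i.d. uniform on (0, s) with
  s = √(mean(X)/K), one stream per restart seed.
- **Zero handling.** During sweeps entries are clipped at ε = 1e-12 rather
  than 0 so a component cannot die permanently; final factors are
  hard-clipped to exact zeros below ε. A column whose Gram diagonal falls
  to ε is skipped for that sweep.
- **Stopping.** Relative objective decrease < 1e-6 or 500 sweeps.
- **Restarts.** The factorization is non-convex; `fit_multistart` runs
  independent seeds (1000 by default in the pipeline configuration;
  smaller counts are used in tests and the acceptance script, where the
  planted structure is recovered already with tens of restarts) and keeps
  the smallest final error. Restart seeds derive deterministically from
  one master seed.

**Weight normalization.** W Hᵀ is invariant to rescaling component k by c
and its weights by 1/c. To make weights comparable, each H column is
divided by its total mass (components become unit-mass rhythms), the mass
is moved into the corresponding W column, and each person's K weights are
then divided by their sum. Row sums of the reported weight matrix are
exactly one; the product W Hᵀ is unchanged by the rescaling step.

**Labels.** Components are named by the hour-of-day band of their mean
daily peak (component folded to 24 hours by averaging the seven days):
morning 5–10, noon 10–15, evening 15–21, night otherwise (21–05, wrapping
midnight). The band edges are fixed constants of this package. Two
components in one band get ordinal suffixes ordered by earlier peak hour
(night peaks ordered from the evening side so 23h precedes 2h).

## Choosing K: consensus stability and the cophenetic coefficient

For each candidate K the factorization is repeated `n_runs` times (default
30), each run on a random 50% subsample of participants with a fresh
random initialization (Monti-style consensus clustering). Each sampled
participant is assigned to the component with the largest mass-normalized
weight (ties to the lowest index); the consensus matrix entry for a pair
is the fraction of co-sampled runs in which they were assigned together.
The cophenetic correlation coefficient is the Pearson correlation between
the off-diagonal entries of D = 1 − consensus and the dendrogram distances
of average-linkage hierarchical clustering of D. K* is the smallest K
maximizing the coefficient over the sweep (default 2–7).

Why subsampling: when runs differ only in initialization, a converged
optimizer reaches the same merged solution at every K ≤ the true number of
archetypes, so all small K look perfectly stable and the coefficient
cannot discriminate. Resampling participants makes *which* archetypes
merge at too-small K sample-dependent (and which clusters split at
too-large K), so only the correct K stays stable. Half-sampling maximizes
the variability of pair co-occurrence and gave the sharpest separation;
`subsample=1.0` recovers the plain restart-only construction.

## Sleep inference

For each participant and each noon-to-noon window (noon anchoring keeps a
normal night's sleep contiguous; midnight windows would bisect it), the 24
hourly presence bits (≥ 1 screen-on event) are scanned for the longest
maximal run of zeros:

- sleep time = clock hour of the run's first hour; wake-up time = clock
  hour of the first active hour after the run; duration = run length;
  mid-sleep = clock hour of the episode midpoint, sleep + duration/2
  (mod 24);
- ties between equal-length runs go to the earlier run;
- a window yields no record when it has no inactive hour, no active hour,
  or the longest run touches the window's end (no wake-up observable).
  Participants with records on fewer than half their windows are flagged
  in the logs.

Per-person typical sleep, wake and mid-sleep times are the modes of the
per-day distributions (robust to occasional outlier nights); typical
duration is the arithmetic mean. Modal ties are resolved toward the hour
closest to the circular mean, then by the earlier hour in noon-anchored
order (12, 13, …, 23, 0, …, 11).

## Associations

All correlations are sample Pearson r with the two-sided p-value from
t = r√((n−2)/(1−r²)) on n−2 degrees of freedom (as implemented in
`scipy.stats.pearsonr`). Constant inputs are rejected rather than given
r = NaN. Hour-valued sleep variables are linearized on the noon-anchored
axis (12 → 0 … 11 → 23) before correlating, so "later in the night" is
monotone across midnight. No multiple-testing correction is applied; the
p-values are raw. The t-based p agrees with an exact permutation
enumeration to within ~0.02 from n ≈ 6 upward but is coarse at n = 4, as
the test suite documents.

## Synthetic populations

The generator emulates the structure this pipeline is designed to detect,
with every planted quantity recorded as ground truth.

- **Archetypes.** Four unit-mass 168-bin templates: circular-Gaussian
  bumps on hour-of-day (σ = 2 h) peaking at 08h (morning), 13h (noon),
  19h (evening) and 23:30 (night), repeated over seven days; morning and
  noon are damped ×0.7 on weekends, evening ×0.7 on Friday/Saturday,
  night unmodulated.
- **Weights.** Each person draws a dominant chronotype (prevalence
  2:5:5:2 for morning:noon:evening:night — morning and night types are
  rare, which skews those weight histograms low) and then weights from
  Dirichlet(1.5 + 2.5·𝟙[dominant]). The population is a continuous
  spectrum with latent chronotype groups; the groups are what makes
  consensus-based rank selection meaningful.
- **Sleep coupling.** Typical onset = 00:30 + 10·(w_night − mean), typical
  wake = 08:30 − 8·(w_morning − mean) — typical sleep timing for a young
  adult cohort, with night owls retiring later and morning types rising
  earlier. Nightly hours are the rounded typical hours plus independent
  ±1 h jitter; durations are clipped to 4–12 h. Intensity inside the sleep
  window is zeroed.
- **Events.** The weekly intensity is 300 expected screen-on events
  spread by the person's weight-mixed archetype profile, masked by sleep
  and rescaled so masking does not change the expected total; hourly
  counts are Poisson, event times uniform within the hour, and each
  screen-on event is paired with one screen-off event.
- **Ground truth weights.** Both the Dirichlet draws and the *effective*
  mixture shares — the draws reweighted by each archetype's mass surviving
  that person's sleep masking — are recorded. The effective shares are the
  share of observed activity per archetype, which is the estimand of the
  normalized NMF weights; recovery is measured against them because the
  pre-mask draws differ from any function of the emitted data by ~0.04
  mean absolute error by construction.
- **Noise-free mode.** `sleep_jitter_hours=0` with `guarantee_presence=True`
  produces hour-aligned sleep windows bounded by guaranteed activity, on
  which sleep inference must be exact. Under the default (Poisson) regime,
  a quiet evening hour can extend the detected gap beyond the planted
  window, so exactness is only claimed in the noise-free regime.

**What the generator does not emulate:** seasonal and holiday structure,
naps and split sleep, session-duration information, travel/timezone shifts,
missing-data stretches from phones being off, and device-specific logging
quirks. Passing recovery tests therefore demonstrates correctness of the
pipeline's machinery on data matching its assumptions, not robustness to
every artifact of real cohorts.

## Problem sizes

The reference cohort is 200 participants × 50 weeks × 300 events/week. The
test suite and the acceptance script fit it with 10–50 restarts and sweep
K = 2…7 at 30 consensus runs per K; the sign-structure stability check
repeats the full generate→factorize→infer→correlate chain over 100
generator seeds. These sizes recover the planted structure with wide
margins while keeping a full run in the minutes range on one CPU.

## Known limitations

- The longest-gap rule cannot see sleep shorter than one hour boundaries
  or distinguish phone abstinence from sleep.
- Participants whose sleep episodes extend past the noon window boundary
  (onset later than ~04h with long durations) yield no record on such
  days; extreme night owls are summarized from their detectable days only.
- Component labels depend on fixed band edges; a component peaking exactly
  at a band edge belongs to the later band.
- The cophenetic criterion presumes latent group structure; on a perfectly
  continuous population without chronotype groups, no K is
  distinguishedly stable and the selected K is not meaningful.
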