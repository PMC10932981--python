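# Methods

This note documents the models, procedures, and numerical choices behind
`binovision`, in the spirit of a model-description appendix: what is
computed, under what assumptions, and what the synthetic-observer tests do
and do not establish.

## The two-stage interocular gain-control model

Dichoptic masking is modelled with two stages of contrast gain control, one
before and one after binocular combination.  For a grating target of
contrast `c_T` in one eye and a non-fusible noise mask of contrast `c_M` in
the other (contrasts in percent, 0–100):

```
stage 1:   respR = (g_T · c_T)^m / (S + g_T · c_T + w_T · g_M · c_M)
stage 2:   resp  = respR^p / (Z + respR^q)
```

* `g_R, g_L` — per-eye input gains (unitless multipliers on contrast).
* `w_R, w_L` — interocular suppression weights, indexed by the **receiving**
  eye: `w_R` scales the suppression that a right-eye target receives from a
  left-eye mask.  (The alternative indexing — by the mask's eye — is
  inconsistent with the suppression-strength definitions below, so the
  receiving-eye convention is used throughout.)
* `m = 1.3`, `p = 8`, `q = 6.6`, `S = Z = 1` — fixed constants.  `p > q` is
  required: it makes stage 2 strictly increasing, so criterion thresholds
  are unique.

Internal response noise is assumed to have unit standard deviation, so a
threshold is the contrast at which `resp = 1`.  Two roots are precomputed
per constants set by bracketed bisection to 1e-12 and cached:

* `r*` solving `r^p = Z + r^q` (stage-1 response giving `resp = 1`;
  ≈ 1.2030 for the defaults), and
* `x*` solving `x^m / (S + x) = r*` (the effective drive `g·c` at an
  unmasked threshold; ≈ 3.937).

These give closed forms for both predicted thresholds:

* detection: `c_det = x* / g` (exactly inverse-proportional to gain);
* "sideways" masking (target fixed at `c_T`, mask varied):
  `c_mask = ((g_T c_T)^m / r* − S − g_T c_T) / (w_T · g_M)`.
  If the bracketed numerator is not positive the fixed target sits at or
  below its own threshold and no mask level can bring performance down to
  criterion; this degenerate input raises an explicit error rather than
  returning a negative contrast.

**Units.** Model-facing contrasts are in percent (0–100], and the dB forms
of the fitted parameters are `G = 20·log10(g)`, `W = 20·log10(w)`.  With
percent units a control-like detection threshold of −44.0 dB maps to
`G ≈ 15.9`, which is the scale on which the derived suppression strengths
(below) take values of a few dB.  Stimulus contrast elsewhere in the
package is expressed in dB re maximum (`20·log10` of the fractional RMS
contrast), so physical levels are ≤ 0 dB.

**Fitting.** The data vector is a threshold quartet — two detection and two
masking thresholds — with the fixed masking targets set 9 dB above the
measured detection thresholds (protocol constant).  The fit minimises the
RMS error between predicted and observed thresholds **in dB** (thresholds
span a log range; fitting in linear contrast would let the largest
threshold dominate).  With four observations and four parameters the
problem is exactly determined, and a sequential closed form exists: gains
from the detection thresholds, then weights from the mask-threshold closed
form.  The optimiser is a derivative-free Nelder–Mead simplex over
log-parameters (which keeps gains and weights positive), started at the
closed-form solution.  Because the RMSE objective is non-negative, a
(near-)zero residual at the start certifies the global minimum and the
search stops; otherwise up to four additional perturbed restarts
(log-normal, scale 0.2) are run and the best minimum kept.  A
non-convergent fit is returned flagged, never silently.

**Derived measures.**  Net suppression strengths combine the masking eye's
gain with the received weight, in dB: `supstrR = GL + WR`,
`supstrL = GR + WL`.  Four sensory eye imbalances are computed with a fixed
right-minus-left convention: threshold imbalance (detection dB difference),
fusion imbalance (the balance point itself), weight imbalance `WR − WL`,
and strength imbalance `supstrR − supstrL`, plus absolute variants.

## Psychometric functions and thresholds

All tasks are fitted with a logistic,

```
p(x) = γ + (1 − γ − λ) / (1 + exp(−β (x − α))),
```

with the guess rate γ fixed at chance (0.5 for the two single-interval
orientation tasks, 0.25 for the 4AFC stereo task, 0 for the appearance-based
combination task) and the lapse rate λ fixed by policy — 0 by default, with
an optional fixed 0.02.  α and β are maximum-likelihood estimates; the
slope sign is free so masking data (performance falls as the mask rises)
fit without relabelling.  Fitting axes are the axes on which the staircases
are linear: dB contrast (detection/masking), dB interocular ratio
(combination), log2 arc seconds (stereo).  The two repetitions of each
task are pooled at the trial level before fitting.

Numerics: trials are aggregated to per-level binomial counts; a coarse
grid over 15 locations × (2 slope magnitudes + both signs where free)
selects starts for L-BFGS-B with the analytic gradient.  Probabilities are
clipped to [1e-12, 1−1e-12].  Data with no outcome variation (all correct
or all incorrect), or a fitted location far outside the sampled range
(beyond 3 spans), are flagged non-converged with a NaN location — no
silent extrapolation.

Thresholds are read at the 75% point (single-interval tasks) or 62.5%
(4AFC), via the closed-form logistic inverse.  For λ = 0 these criteria sit
at the midpoint of the response range, so the threshold equals α exactly.
The balance point (BP) is the 50% point of a full-range logistic fitted to
the proportion of left-eye-dominant reports against the interocular ratio
in dB; 0 dB means equal contribution, and positive values mean left-eye
dominance.  The canonical BP unit is dB (`20·log10` of the ratio), keeping
every contrast-domain quantity in one unit; a raw `log10` accessor exists
for analyses that report the plain logarithm.  Group comparisons use |BP|.

## Adaptive staircases

Transformed up-down staircases with equal up/down steps:

| task       | rule        | step        | start       | caps              |
|------------|-------------|-------------|-------------|-------------------|
| detection  | 3-down-1-up | 3 dB        | −12 dB      | 9 reversals / 120 trials |
| masking    | 3-up-1-down | 3 dB        | −36 dB      | 9 reversals / 120 trials |
| stereo     | 2-down-1-up | ×√2 (+0.5 log2) | 512 arcsec | 9 reversals / 30 trials |

"Harder" means lower contrast for detection, **higher** mask contrast for
masking (correct responses raise the mask), and smaller disparity for
stereo.  The rules converge where p(correct) = 0.5^(1/n): 79.4% for n = 3,
70.7% for n = 2.  The consecutive-correct counter resets on every level
change and on every error; a reversal is recorded whenever the step
direction changes, with the first run's direction set by the first step.
Levels are clamped to physical bounds (contrast ≤ 0 dB, disparity ≥ 1
arcsec); clamped trials still count.  Staircase pairs (one per eye, or per
disparity sign) are interleaved by drawing each trial uniformly from the
non-terminated members.  Note the stereo staircase's 30-trial cap is spent
largely descending from 512 arcsec for good observers; the threshold
estimate therefore comes from the pooled psychometric fit, not from
reversal averages.

## The synthetic observer

A simulated observer is specified by the quantities the analysis recovers:
per-eye detection thresholds (dB), per-eye suppression weights (WR, WL,
dB), a signed balance point (dB), a log2 stereoacuity, psychometric
spreads, and a lapse rate.  Its internal gain-control parameters are
obtained by inverting the model (`g = x*/c_det`, `w = 10^(W/20)`), so its
masking behaviour is exactly model-consistent.  Trial responses are
Bernoulli draws from logistic functions anchored to pass through the task
criterion exactly at the implied threshold.  Psychometric spreads default
to 2 dB (detection/masking), 3 dB (combination), and 0.5 log2 units
(stereo) — values at which the staircases converge comfortably within
their trial budgets; the lapse default is 0, matching the fitting policy,
so recovery is unbiased by construction.

The simulated protocol mirrors the experiment's order and bookkeeping:
detection staircases first; their fitted thresholds (computed exactly as
the analysis computes them) fix the masking targets at +9 dB; then
masking, combination (7 ratios × 20 trials per repetition, ratios
1:4…4:1 symmetric about 1:1, both eyes scaled so the geometric mean stays
at the 45% base), and the crossed/uncrossed stereo pair; everything twice.
Because the trial tables carry no target-contrast column, the analysis
re-derives the masking targets from the same detection data by the same
computation, so generation and analysis agree deterministically.

Cohort generators draw observer fields independently (per eye, per field)
from group distributions whose defaults are the aging/control summary
statistics the pipeline is meant to reproduce in expectation: detection
−38.3 ± 3.6 vs −44.0 ± 3.6 dB, weights −7.9 ± 3.6 vs −11.8 ± 2.3 dB, mean
|BP| 2.8 vs 1.7 dB, 4-C log2 stereoacuity 6.3 ± 1.0 vs 5.5 ± 0.7, Titmus
5.4 ± 0.8 vs 5.0 ± 1.0, TNO 7.1 ± 1.1 vs 6.3 ± 0.8.  Since only absolute
BP statistics are available at the group level, the signed BP is modelled
half-normally: BP ~ Normal(0, σ) with σ = mean|BP| / √(2/π).  The three
stereo tests share a per-subject latent component (weight 0.6 of the
variance) plus independent parts, so per-test means/SDs match the
generative table while cross-test correlations are positive but below 1;
the between-test mean offsets give the ANOVA a real test-method effect.
Titmus and TNO are administered clinical values — they are drawn directly,
with no trial simulation.

**What the generator does not emulate.**  Fields are drawn independently,
so the between-measure correlation structure observed in real cohorts
(e.g. threshold imbalance correlating with weight imbalance) is not built
in; correlation analyses on synthetic cohorts test machinery, not effect
sizes.  There are no lapses by default, no learning or fatigue across the
session, no criterion drift, and monocular cues to stereo are absent.
Passing recovery tests therefore shows the estimation chain is consistent
and approximately unbiased under the generative model — not that real data
meet these assumptions.

Measured under the default protocol (100-observer suite), staircase-based
threshold estimates carry ≈ 1 dB RMSE per eye.  The masking-weight
estimate compounds three errors (the target eye's detection error enters
the mask-threshold prediction with a gain of ≈ 2, plus the masking eye's
detection error and the mask-threshold error), giving ≈ 2.5 dB RMSE per
weight with negligible bias; the same propagation occurs in the real
experiment's design.

## Group statistics

* **Mann–Whitney U** (two-sided) for every group comparison, reported with
  the tie-corrected normal-approximation Z (no continuity correction), as
  appropriate at n = 28 per group; an exact-enumeration oracle backs the
  implementation in the tests.
* **Two-way between-subjects ANOVA** (group × stereo test) on log2
  thresholds, with Bonferroni-corrected pairwise post hocs among the three
  test methods using the pooled error term.  Treating the three tests per
  subject as independent observations (error df = N − 6) replicates the
  published analysis style; the repeated-measures caveat applies, since
  test scores share a subject.
* **Spearman** correlations among the four signed imbalances, per cohort
  and combined; correlations of stereoacuity with the **absolute**
  imbalances (a strong preference for either eye is what is hypothesised
  to hurt stereo).  Group differences between correlations use the Fisher
  r-to-z transform applied directly to rho with SE √(1/(n−3)) — the
  simple variant, not the variance-adjusted Spearman form.
* **WMW power** by the asymptotic-relative-efficiency method with normal
  parents: effective per-group n of 0.955·n, effect size
  d = Δmean/√((s₁²+s₂²)/2), evaluated with the noncentral t.  On the
  printed group summaries this reproduces 91.4% (4-C stereo) and 99.6%
  (masking weights) at α = 0.05, n = 28; for the detection thresholds it
  gives 99.99% where 99.9% is printed (likely a truncation or tool
  difference — not treated as a reproduction target).

The summary-statistic ANOVA variant reconstructs an exact surrogate sample
per cell (a between-subjects ANOVA depends on the data only through cell
means, SDs and ns) and reuses the data-variant code path.  On the rounded
stereo group summaries it yields F(group) ≈ 22.5 and F(test) ≈ 38.0 —
close to, but not equal to, values computed from unrounded raw data; the
discrepancy is attributable to input rounding and is checked with a
tolerance band rather than treated as exact.

## Problem sizes and determinism

The recovery suite uses 100 simulated observers; quartet-level noise
recovery uses 200 subjects at 0.5 dB threshold noise; the group-direction
study uses 100 replicates of two 28-subject cohorts; staircase convergence
simulations use 300–1000 runs per rule.  These sizes give standard errors
comfortably below the tolerances being asserted.  All randomness flows
through `numpy.random.Generator` objects seeded explicitly; simulation and
analysis are deterministic given a seed, and artifacts are stamped with
seed and package version.

## Known limitations

* The 4-data/4-parameter fit has no redundancy: measurement error maps
  directly into parameters, and no goodness-of-fit test is possible at the
  subject level.
* Fixed lapse-rate policy; a free lapse parameter would need more trials
  per level than the staircase protocol provides.
* The summary-ANOVA reconstruction assumes per-cell normal-sufficient
  statistics are what matters (true for the F tests; not a substitute for
  rank-based alternatives).
* The BP sign convention (positive = left dominant) is a package
  convention; only |BP| is compared across groups.
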