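# binovision

Analysis pipeline for a four-task binocular-vision psychophysics battery,
built to study how interocular suppression, binocular fusion, and
stereopsis differ between an aging cohort and younger controls.  It is
aimed at vision scientists who have (or want to simulate) trial-level data
from:

1. **monocular contrast detection** — 2.5 c/deg gratings, single-interval
   orientation identification, 3-down-1-up staircases (3 dB steps);
2. **sideways dichoptic masking** — target fixed 9 dB above its detection
   threshold, contralateral noise-mask contrast driven by a 3-up-1-down
   staircase (correct responses raise the mask);
3. **binocular orientation combination** — opposite ±4° tilts at seven
   interocular contrast ratios (1:4 … 4:1 around a 45% base), yielding a
   balance point (BP);
4. **4AFC stereoacuity** — crossed/uncrossed disparity, 2-down-1-up
   staircase with √2 steps from 512 arcsec (plus administered Titmus/TNO
   values).

## The model

The core computation is a two-stage interocular gain-control model of
dichoptic masking.  With contrasts in percent, a target `c_T` in one eye
and a mask `c_M` in the other:

```
respR = (g_T c_T)^m / (S + g_T c_T + w_T g_M c_M)      (stage 1)
resp  = respR^p / (Z + respR^q)                        (stage 2)
```

with fixed `m = 1.3, p = 8, q = 6.6, S = Z = 1`, and a threshold defined by
`resp = 1` (unit internal noise).  The four fitted parameters are the
per-eye gains `g_R, g_L` and suppression weights `w_R, w_L` (indexed by the
receiving eye), reported in dB (`G = 20 log10 g`, `W = 20 log10 w`).
Derived measures: net suppression strengths `supstrR = GL + WR`,
`supstrL = GR + WL`, and four sensory eye imbalances (threshold, fusion,
weight, strength; right minus left).  Psychometric functions are logistic
with the guess rate fixed at chance; thresholds are read at 75% correct
(62.5% for 4AFC).  Group statistics: Mann–Whitney U (tie-corrected Z),
a 2×3 group × stereo-test ANOVA with Bonferroni post hocs, Spearman
imbalance correlation matrices with Fisher r-to-z group contrasts, and
Wilcoxon–Mann–Whitney power via the ARE/noncentral-t method.

A synthetic-observer module simulates complete sessions from generative
ground truth (model-consistent by construction), so the whole pipeline can
be exercised and validated without human data.  See `docs/methods.md` for
assumptions, defaults, and limitations.

## Worked example

Simulate two 28-subject cohorts, analyse them, and print the report:

```sh
binovision simulate --seed 11 --n 28 --out study/
binovision analyze-group --trials study/trials.csv \
    --clinical study/ground_truth.csv --out study/report.json
binovision report --report study/report.json
```

which prints (abridged):

```
Group comparison: aging (n=28) vs control (n=28)

measure                            aging           control       Z         p
detection_threshold      -38.42 ± 2.51    -44.46 ± 3.09    5.59    0.0000
masking_weight            -7.68 ± 2.77    -11.57 ± 2.16    4.72    0.0000
masking_strength           2.65 ± 3.97      4.79 ± 4.39   -1.70    0.0883
abs_balance_point          2.12 ± 1.68      2.05 ± 1.46   -0.23    0.8185
stereo_4c                  6.34 ± 0.75      5.42 ± 0.89    3.79    0.0002

Stereo 2x3 ANOVA (log2 arcsec):
  group        F(1,162) = 27.31, p = 5.267e-07
  test         F(2,162) = 57.03, p = 1.776e-19
  interaction  F(2,162) = 2.84, p = 0.06153
```

Reading the numbers: the simulated aging cohort detects gratings at ~6 dB
higher contrast (worse sensitivity) and carries ~4 dB more interocular
suppression weight, yet shows no significant difference in net suppression
strength — the weight increase compensates the gain loss — and needs
roughly twice the disparity (2^6.34 ≈ 81 vs 2^5.42 ≈ 43 arcsec) for
reliable depth judgments.  The same quantities are available
programmatically:

```python
from binovision.pipeline import simulate_and_analyze_cohorts
report = simulate_and_analyze_cohorts(seed=11)
report.descriptives["masking_weight"]["aging"]
# {'mean': -7.676..., 'sd': 2.774..., 'n': 28}
```

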