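# tapvoice

Digital-biomarker pipeline for Parkinson disease (PD): per-time-frame
analysis of smartphone-style **finger-tapping logs** and **voice
recordings**, with linear mixed models for **time x severity interaction**
effects, and a **synthetic cohort generator** with exportable ground truth
for validating the whole chain.

It is written for researchers who want to analyse short repeated-task
recordings — 20 s alternating tapping, 10 s sustained vowels (/a/, /i/),
5 s syllable repetition (/dadada/, /pa-ta-ka/) — as *time courses* rather
than single summaries: each recording is split into five equal time frames
(TF1..TF5) and the question is how performance decays within a trial, and
whether that decay steepens with disease severity.

## The model

For a feature value $y_{ijk}$ of PD subject $i$ with motor score
$u_i$ (UPDRS part III), trial $j$, time frame $k \in \{1..5\}$:

$$y_{ijk} = \beta_0 + \beta_t k + \beta_u u_i + \beta_{tu}\, u_i k + b_i + \varepsilon_{ijk}, \qquad b_i \sim N(0, \tau^2),\ \varepsilon \sim N(0, \sigma^2)$$

fit by REML with a random intercept per subject. The headline quantity is
the **time–severity interaction** $\beta_{tu}$: more severe disease means a
steeper within-trial change. A parallel model with group (control = 0,
PD = 1) in place of $u$ gives the time x group interaction. Around the
models sit the classical battery: pooled-variance t tests on per-subject
means (df = $n_a + n_b - 2$), repeated-measures ANOVA across frames with
Holm-adjusted post hoc contrasts against TF1, and Pearson/least-squares
severity regressions.

Features per domain:

| domain | features |
| --- | --- |
| tapping | total taps (alternation-filtered), inter-tap-interval SD per TF, mean variability |
| phonation | loudness (compressed energy), local jitter, local shimmer per TF; trial means and their CV across TFs |
| speech (DDK) | repeat count, inter-onset-interval SD overall and per TF |

## Worked example

```python
import json
from tapvoice import RunConfig, run_all

cfg = RunConfig(out_dir="demo_run", seed=7, n_pd=4, n_control=4,
                n_sessions=1, n_trials=1)
out = run_all(cfg)            # simulate -> extract -> analyze
rep = json.loads((out / "report.json").read_text())
```

This simulates a small cohort (tap CSVs and 16 kHz WAV audio under
`demo_run/`), runs the full extraction and statistics, and writes
`features.csv`, `report.json` and `tables/*.csv`. Inspecting the group
comparison (control mean (SD), PD mean (SD), pooled t):

```
tapping total_taps        ctrl 81.12 (0.479)   PD 36.62 (0.629)   t=112.58, df=6, p=3.3e-11
tapping mean_variability  ctrl 0.0329 (0.0088) PD 0.0950 (0.0492) t=-2.48,  df=6, p=0.048
a       jitter            ctrl 0.0069 (0.0019) PD 0.0095 (0.0060) t=-0.84,  df=6, p=0.44
```

The simulated PD group taps less than half as often per hand, with ~3x the
inter-tap variability, and shows elevated vowel jitter — directions a real
PD/control contrast shows, at this toy size not all significant. The
time-severity model on /a/ loudness recovers the injected negative
interaction (severer disease, faster within-trial loudness decline):

```
a loudness  tf:updrs3  coef=-0.00132  SE=4.7e-05  p<1e-14
```

and the report's `recovery` section pairs every estimated interaction with
the generator's true slope. With `scenario="null_interaction"` all true
interaction slopes are exactly 0, which is how the inference machinery's
type-I error and CI coverage are audited.

The same stages are exposed on the command line:

```bash
tapvoice simulate --n-pd 20 --n-control 20 --scenario paper_like --seed 7 --out run/
tapvoice extract-taps  --in run/taps  --out tap_features.csv
tapvoice extract-voice --in run/audio --out voice_features.csv
tapvoice analyze --features run/features.csv --cohort run/cohort.csv --out run/report
tapvoice run-all --seed 7 --out run/
```

## Layout

```
src/tapvoice/
  cohort.py    synthetic cohort: profiles, truth, tap/audio synthesis,
               feature-level simulation
  taps.py      alternation filter, intervals, time frames, tap features
  voice.py     loudness, f0, cycle tracks, jitter/shimmer, onsets
  stats.py     t tests, RM-ANOVA + post hoc, LMMs, regression, report
  lmm.py       random-intercept mixed model wrapper + fixed-variance GLS
  pipeline.py  run orchestration, config hashing, stamped artifacts
  cli.py       tapvoice {simulate, extract-taps, extract-voice, analyze, run-all}
docs/methods.md   model details, generator anchoring, design choices, limits
```
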