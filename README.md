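# prodrome

Reconstruction-based anomaly detection for smartphone passive-sensing
streams, aimed at flagging behavioural early-warning signs in the 30-day
window before a clinical relapse — together with a synthetic sensing-cohort
simulator so the whole pipeline is buildable and testable without any
clinical data.

## What it does

1. **Simulate** (`prodrome.synthetic_cohort`) — seeded per-participant raw
   event streams (acceleration samples, app polls, call/text logs,
   conversation episodes, GPS fixes, screen sessions, daily sleep estimates)
   with circadian structure, log-normal participant-level random effects,
   a relapse calendar, configurable near-relapse behavioural shifts
   (multiplicative / additive / SD-scaled, with linear ramp-in), and both
   missingness mechanisms (whole-hour "type 2" and per-channel "type 1").
2. **Featurize** (`prodrome.features`) — an hourly feature matrix: mean
   acceleration norm, unique apps, call/text counts and durations by
   subtype, conversation and screen usage, DBSCAN significant-place dwell
   times (haversine metric, eps 1 km, min 10 samples) plus distance
   travelled, replicated daily sleep features, day-of-week / hour-of-day,
   with an observed/unobserved mask.
3. **Impute** (`prodrome.impute`) — zero-fill for partially observed hours,
   participant hour-of-day means for fully missing hours (location carried
   forward to the last recorded place), and a `fill_fraction` feature that
   is exactly 1 on fully missing hours.
4. **Split** (`prodrome.splits`) — healthy-only train/validation sets
   (H_R/H_CV, 80/20) with a configurable percentage of relapse
   participants' healthy blocks, a mixed pool, and a stratified 100-iteration
   Monte Carlo partition into N_CV/N_T.
5. **Detect** (`prodrome.detectors`) — a fully connected autoencoder over
   single hours, a bidirectional-GRU seq2seq reconstructing 24-hour windows
   in reverse order (dropout/recurrent dropout 0.2, early stopping on H_CV),
   and a per-participant local-outlier-factor baseline with a
   neighbour-convergence loop.  The neural nets run on a small NumPy
   reverse-mode autodiff engine (no GPU frameworks required).
6. **Score** (`prodrome.scoring`) — absolute reconstruction errors, a
   Gaussian error model fitted on H_CV, Mahalanobis hourly scores, daily
   means, and per-participant thresholds in [0, 20] maximising TPR/FPR on
   N_CV (strict `>` flagging on N_T).
7. **Evaluate / interpret** (`prodrome.evaluation`, `prodrome.posthoc`) —
   sensitivity/specificity with median (IQR) Monte Carlo aggregation, mean
   rank across configurations, standardized data-quality regression, an
   anomaly-rate-vs-days-to-relapse timeline, per-participant Cohen's *d*
   feature rankings, a type-2-missingness odds ratio and a one-sided
   Mann-Whitney U test.

## CLI

```sh
prodrome simulate  --out sim/ --seed 1 --n-participants 12 --days 120
prodrome featurize --events sim/ --calendar sim/calendar.csv --out features.csv
prodrome impute    --features features.csv --calendar sim/calendar.csv --out imputed.csv
prodrome split     --calendar sim/calendar.csv --pct-drh 80 --out splits.json
prodrome run-all   --out results/ --seed 1 --arch fnn_ad --hidden 20 --pct-drh 80
```

`run-all` writes `summary.csv` (median/IQR sensitivity and specificity per
configuration), `ranking.csv` when sweeping, `timeline.csv`,
`posthoc.json`, per-config records, and a reproducibility manifest.

## Layout

```
src/prodrome/
  schema.py            feature names, channels, day labels
  synthetic_cohort.py  simulator: cohort generation, signature injection, missingness
  features.py          hourly featurization, haversine, DBSCAN places, dwell/distance
  impute.py            type-1/type-2 imputation and fill fraction
  splits.py            day blocks, H/N split, Monte Carlo partition
  detectors/           autodiff engine, FNN AD, GRU seq2seq, LOF baseline
  scoring.py           error model, Mahalanobis scores, thresholds, flags
  evaluation.py        confusion metrics, aggregation, ranking, regression, timeline
  posthoc.py           Cohen's d rankings, odds ratio, Mann-Whitney U
  pipeline.py          experiment orchestration
  cli.py, io.py        command line and plain-text interchange formats
```
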