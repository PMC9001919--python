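# thermotrace

Annotation and analysis of near-continuous skin-temperature traces from
shuttling ectotherms, plus a seedable simulator so the whole pipeline
runs without external data.

A trace is a uniformly sampled temperature series (default: 2 s
sampling, 0.0625 °C logger quantization, 18 °C ambient reference). The
pipeline:

1. **annotator** — labels each sample thermoregulating (strictly above
   the ambient threshold) or non-thermoregulating, segments bouts,
   detects upper/lower set-point events with a hysteresis state machine
   (a direction change is confirmed only after a reversal of ≥ 2 °C from
   the running extremum; the event lands on the first sample attaining
   that extremum), and classifies the animal as a thermoregulator iff it
   shows more than two confirmed direction changes.
2. **metrics** — per trace: mean temperature, means of upper/lower
   set-points, thermal passivity range (TPR = mean upper − mean lower),
   global maximum, % time thermoregulating, shuttle count, and the
   accuracy index `db` (mean deviation from a reference set-point range:
   zero inside the range, distance to the nearest bound outside). Traces
   whose maximum reaches a plausibility ceiling (default 41 °C) are
   flagged, never dropped.
3. **calibration** — additive logger→cloacal offset (mean difference,
   SE, Pearson R); applying it never auto-shifts annotation thresholds.
4. **simulator** — first-order Newtonian heating/cooling with a
   behavioural controller switching on latent set-points; Gaussian
   measurement noise and logger quantization on top. Cohort generation
   is repeated-measures (each animal in every treatment) with
   per-treatment set-point shifts, convective-cooling multipliers,
   thermoregulation probabilities and tunnel-exit rates. Ground truth is
   returned alongside every trace.
5. **summary_stats** — per-treatment descriptive tables (response means
   over thermoregulators only) and seedable permutation tests (pairwise
   mean differences with Holm adjustment plus an overall among-group
   variance statistic); labels are permuted within animals when the
   cohort is repeated-measures.

## CLI

```sh
thermotrace simulate --mode thermoregulator --seed 42 --out trace.csv
thermotrace annotate --in trace.csv --hysteresis 2.0 --threshold 18.0 --out annotated.csv
thermotrace metrics --in 'annotated*.csv' --ref-lower 29.1 --ref-upper 34.7 --out summaries.csv
thermotrace derive-ref --in summaries.csv --baseline-treatment 0
thermotrace calibrate --pairs pairs.csv --out fit.json
thermotrace simulate-cohort --seed 7 --n-per-treatment 28 --out traces/
thermotrace summarize --in summaries.csv --out table.csv
thermotrace permtest --in summaries.csv --var mean_upper --n-perm 10000 --seed 7
```

Trace CSVs have columns `time_s,temp_c` with metadata in a
`<stem>.meta.json` sidecar; annotated CSVs add `label,event` columns
with events/bouts in `<stem>.annot.json`; simulated traces carry ground
truth in `<stem>.truth.json` and cohorts a `manifest.json`.

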