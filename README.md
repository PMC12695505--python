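# qeegbands

Resting-state quantitative EEG band-power analysis with a fully synthetic
test cohort. The package computes Welch power spectral densities, relative
band powers (delta 0–4 Hz, theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz) per
electrode and per scalp zone, and runs a mixed-design statistical battery:

- seeded resampling ANOVA (3 treatment groups × 2 visits, Wald-type
  statistic with a centred subject bootstrap null),
- per-visit between-group Kruskal–Wallis and pairwise Wilcoxon rank-sum
  tests with unpaired Cliff's δ,
- per-group between-visit Wilcoxon signed-rank tests with the paired
  (sign-mean) Cliff's δ, at zone level and per electrode,
- pooled Spearman correlations between band/zone powers and
  neuropsychological scores with Benjamini–Hochberg FDR adjustment and a
  collapsed significant-neighbourhood view.

Because no public EEG cohort accompanies the analysed design, the
`synthetic_data` module generates a seeded cohort — 1/f background plus
band-limited oscillators whose amplitudes carry configurable (group, visit)
effects, and cognitive scores linked positively to relative alpha and
negatively to relative delta — so every pipeline stage is testable offline.

## Layout

| Module | Role |
| --- | --- |
| `qeegbands.eeg_io` | `EEGRecording`, montage/zones, BrainVision / EDF / plain-matrix read & write, preprocessing (downsample → average reference → 50 Hz notch) |
| `qeegbands.spectral` | Welch PSD (1 s Hann, 50 % overlap), band power, relative band power, zone averages |
| `qeegbands.effect_sizes` | unpaired Cliff's δ, paired sign-mean δ, magnitude labels |
| `qeegbands.stats` | rank tests, resampling mixed ANOVA, Spearman + FDR, significance markers |
| `qeegbands.synthetic_data` | seeded cohort generator (recordings, metadata, scores) |
| `qeegbands.pipeline` | orchestration, CSV/JSON reports, correlation-matrix collapsing |

## CLI

```bash
# 1. generate a synthetic cohort (matrix-dialect recordings + CSV tables)
qeegbands simulate --config examples/cohort.yaml --out cohort/ --seed 20000523

# 2. run the full analysis
qeegbands analyze --recordings cohort/recordings --metadata cohort/metadata.csv \
    --scores cohort/scores.csv --out results/

# 3. collapse the FDR-adjusted correlation matrix (adjusted p < 0.1)
qeegbands report --results results/ --threshold 0.1
```

`simulate` accepts a YAML/JSON file with `CohortConfig` fields
(group sizes, sampling rate, duration, oscillators, per-group visit-2
amplitude effects, score models, missingness, seed). `analyze` accepts
`AnalysisConfig` fields (Welch window/overlap, target rate, notch, ANOVA
iterations and seed — default 10000 iterations, seed 20000523 — alpha,
collapse threshold, optional zone-map YAML overriding the packaged
32-channel 10–20 grouping in `qeegbands/data/zones.yaml`).

Outputs are tidy CSVs (`band_powers`, `electrode_powers`, `anova`,
`between_groups`, `within_groups`, `electrode_paired_delta`,
`correlations`, `collapsed`) plus a JSON run manifest; reruns with the
same config and seeds are byte-identical.

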