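# freegait

Free-living gait analysis from bilateral thigh-worn sensors. Each leg
carries one sensor on the rectus femoris recording tri-axial acceleration
(31.25 Hz, ±16 g) and surface EMG (250 Hz). From these raw streams the
package:

1. **identifies walking bouts** — 4-s non-overlapping windows are projected
   onto thigh-fixed anatomical axes (cranial-caudal axis from a standing
   calibration trial; antero-posterior axis from per-window transverse-plane
   PCA), summarized by six canonical features selected with a two-class
   Davies-Bouldin index (DBI < 2), and classified by a Gaussian-kernel SVM
   with Platt-calibrated posteriors; runs of ≥ 2 consecutive windows with
   posterior ≥ 0.8 become walking bouts (clipped bouts are dropped);
2. **segments strides and gait phases** — stride/step frequencies from a
   Welch PSD of the cranial-caudal acceleration; foot-off at extrema of the
   stride-frequency-filtered signal confirmed in the step-frequency-filtered
   signal; foot contact at the first upward 1 g crossing of the
   5 Hz-filtered signal; strides constrained to stride time 0.91–1.57 s and
   duty factor 0.44–0.73, with ≥ 2 retained strides per leg per bout;
3. **computes inter-limb asymmetry** — per bout, three discrete indices
   `|I − H| / |H|` (duty factor, mean normalized sEMG during stance and
   swing) and four waveform indices `(1 − r)/2` on ensemble-mean
   time-normalized waveforms (sEMG envelope, CC/AP/ML acceleration), plus
   their composite mean, with per-subject outlier screening and group-level
   statistics (ANOVA/Kruskal-Wallis, Tukey HSD, Cohen's d, correlations).

A synthetic-signal module generates bilateral recordings with exact ground
truth (event times, stride time, duty factor, injected asymmetries,
activity labels), so the full pipeline is testable without any recordings.

## CLI

The console script `freegait` exposes the pipeline stages:

```sh
freegait simulate --out day.csv --truth-out truth.json --seed 1   # synthetic recording
freegait calibrate --standing standing.csv --out axes.json        # CC axes from standing trial
freegait simulate-activities --out features.csv --subjects 16     # labelled training features
freegait train --features features.csv --out model.pkl            # DBI selection + SVM
freegait classify --recording day.csv --model model.pkl \
    --calibration axes.json --out windows.csv                     # windows + bouts
freegait segment --recording day.csv --calibration axes.json \
    --out strides.csv                                             # events + strides
freegait analyze --recording day.csv --model model.pkl \
    --calibration axes.json --out-dir results/                    # full pipeline
freegait report --summaries summaries.csv --out report.json       # group statistics
```

Recordings are long-format CSV (`stream,t,channel,value` with `# key=value`
metadata headers) or HDF5 (one group per stream). All thresholds live in
`PipelineConfig` and can be supplied as YAML via `--config`; the config is
serialized alongside outputs for provenance.

## Python API

```python
from freegait import (
    GaitSimConfig, simulate_gait_recording, simulate_activity_windows,
    select_features, train_classifier, run_pipeline, PipelineConfig,
)

rec, truth = simulate_gait_recording(GaitSimConfig(stride_time=1.1, seed=7))
table = simulate_activity_windows(n_subjects=16, seed=0)
features = table.drop(columns=["subject", "activity", "is_walking"])
kept = select_features(features, table.is_walking)
model = train_classifier(features, table.is_walking, feature_subset=kept)
result = run_pipeline(rec, model, PipelineConfig(),
                      cc_axes={leg: truth.axes[leg][0] for leg in ("right", "left")})
print(result.summary)
```

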