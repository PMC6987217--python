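# hmpkit

Analysis toolkit for habitual-motion-path (HMP) deviation scoring of the knee
and its relation to running-induced cartilage volume reductions.

The pipeline: half-squat trials define a per-subject baseline — the frontal
(adduction) and transverse (internal-rotation) knee angles sampled at a 40°
knee flexion during the eccentric (flexion-increasing) phase. Running trials
in different footwear conditions are sampled the same way inside the stance
eccentric phase, and the per-plane distances from the baseline are combined
into a single score:

```
dev_total = dev_front + 0.5 * dev_trans        (degrees)
```

Pre/post-run cartilage volumes of seven knee sub-regions (P, MT, LT, MF, LF,
CMF, CLF) are turned into percent reductions, and a statistical battery
relates them to the deviation score: one-tailed exact Wilcoxon rank-sum on a
high/low deviator median split, dependent-sample t-tests on each subject's
extreme footwear conditions, simple linear regressions, and standardized
mean differences `d = (x̄ⱼ − x̄ᵢ) / sqrt((s²ⱼ + s²ᵢ)/2)`.

A synthetic-data module generates the whole study layout (subjects × 3
footwear conditions: squat/running kinematics, vertical ground-reaction
force, marker clouds, cartilage volumes) with known ground truth, so every
stage is testable offline.

## Layout

| module              | contents |
|---------------------|----------|
| `hmpkit.synthetic`  | ground-truth cohort generator (`CohortConfig`, `SubjectTruth`, `generate_cohort`, …) |
| `hmpkit.kinematics` | least-squares rigid fit (Kabsch), Cardan knee angles, stance/eccentric phase detection, critical-flexion crossing, zero-phase low-pass |
| `hmpkit.hmp`        | baseline, deviation score, per-condition aggregation, subject summaries, median split |
| `hmpkit.cartilage`  | region validation, volume normalization, percent reductions |
| `hmpkit.stats`      | exact one-tailed rank-sum (enumeration ≤ 20 tie-free; tie-corrected normal approximation otherwise), paired t, OLS, effect sizes, study orchestration |
| `hmpkit.io` / `hmpkit.cli` / `hmpkit.config` | CSV/JSON formats, optional C3D reader (needs `ezc3d`), end-to-end pipeline, `hmp` command |

## CLI

```bash
hmp simulate --out data/ --seed 1              # synthetic cohort with truth table
hmp pipeline --data data/ --out results/       # full analysis, writes report.json
# or stage by stage:
hmp baseline --trials data/ --out baseline.csv
hmp deviate  --trials data/ --baseline baseline.csv --critical-deg 40 --out dev.csv
hmp cartilage --records data/cartilage.csv --out red.csv
hmp stats --deviations dev.csv --reductions red.csv --out report.json
```

Analysis constants (critical flexion angle 40°, transverse weight 0.5,
stance threshold 20 N, α = 0.05, tie rules, optional filters) live in
`AnalysisConfig` and can be supplied as YAML via `--config`.

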