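# uterodyn

Quantitative analysis of dynamic utero-placental MRI: organ morphometry
(volume, surface area, sphericity) from anisotropic gapped multislice label
volumes, ΔR2\* time courses, automatic contraction detection with local
baselines and half-maximum durations, maternal/fetal movement screening,
rule-based placental-vs-uterine classification, and group statistics —
together with a synthetic 4D utero-placental phantom generator whose
contraction events have closed-form ground truth.

## Layout

| module | role |
| --- | --- |
| `uterodyn.phantom` | parametric utero-placental phantom: scenario/event specs, continuous shape model, gapped-slice rasteriser, session simulator, seeded validation suites |
| `uterodyn.geometry` | gap-aware volumes; surface areas via per-slice signed-distance interpolation + isosurfacing; sphericity |
| `uterodyn.timecourse` | 5-point moving-average smoothing, ΔR2\*(t) = −(1/TE)·ln(S/Sb), earliest-rest baseline, % normalisation |
| `uterodyn.events` | contraction detection on the placental-volume series, local (linear-in-time) baselines, half-maximum durations, per-event feature extraction, rates |
| `uterodyn.motion` | maternal/fetal mask-difference movement traces and the 2% high-movement flag |
| `uterodyn.classify` | volume gate (>10%) + sphericity (>0.005) classification rule |
| `uterodyn.stats_report` | Mann-Whitney U (exact enumeration / tie-corrected normal), Bonferroni-adjusted thresholds, cohort-style median (LQ, UQ) summaries |
| `uterodyn.pipeline` | one-call session analysis orchestration |
| `uterodyn.io`, `uterodyn.cli` | NIfTI/CSV/JSON session directories and the `uterodyn` command |

## CLI

```sh
# simulate a synthetic session (labels + signal NIfTI, timestamps JSON,
# ground-truth CSV)
uterodyn simulate --config examples/scenario.yaml --out session/ --seed 7

# analyse it: time course, events, motion, classified event table
uterodyn analyze --session session/ --out analysis/

# group comparisons + cohort summary over one or many event tables
uterodyn report --events analysis/ --out report/
```

## Python API

```python
from uterodyn import ScenarioConfig, EventSpec, simulate_session, analyze_session

config = ScenarioConfig(
    n_frames=120,
    events=(EventSpec("placental", onset_s=300, duration_s=240, amplitude=0.2),),
    noise_sd_fraction=0.02,
)
series, ground_truth = simulate_session(config)
result = analyze_session(series)
print(result.rates)
```

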