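# etholight

Analysis toolkit for light-modulated fish behavior and expression assays:
stimulus photometry, moving-dot avoidance scoring, locomotor activity AUC
under light/dark schedules, a normality-gated two-sample testing procedure,
and qPCR relative quantification — plus a synthetic-data generator that emits
the same plain-text formats the analyses consume, so every stage is testable
without external data.

## Modules

| Module | Purpose |
| --- | --- |
| `etholight.lightfield` | Spectra → photon flux (trapezoid of E(λ)·λ/hc), intensity scaling, Michelson contrast, light/dark schedules with flagged acclimation |
| `etholight.stimulus` | Pixel ↔ visual-degree conversion (2·atan(s/2D)), 7-block × 6-dot trial plans (ascending or seeded pseudo-random, 19 s gaps) |
| `etholight.avoidance` | Avoidance index (n_avoid − n_approach)/n_total, cohort size-tuning curves (mean ± SEM), total avoidance as trapezoidal area of AI vs size |
| `etholight.locomotor` | Trajectories → distance-per-bin series (10 s / 60 s bins), per-interval and per-condition AUC, normalized fast dark-photokinesis response (first 2 min after light-off ÷ 5-min preceding-darkness baseline), 30/90-min lights-on windows |
| `etholight.stats_engine` | D'Agostino–Pearson normality gate, two-tailed F-test gate, Student/Welch t or exact Mann–Whitney fallback, star annotation, full decision trace |
| `etholight.expression` | ΔCt relative expression (2^−ΔCt vs beta-actin), fold changes vs a control group's geometric mean, circadian peak/trough timing |
| `etholight.synthetic` | Two-state (rest/move) CTMC swim simulator with condition-dependent rates and genotype multipliers, size-tuned dot-outcome simulator with habituation, qPCR plate simulator, closed-form oracles, parameter-recovery experiment |
| `etholight.io`, `etholight.cli` | CSV/JSON readers/writers with validation, `etholight` CLI |

## CLI

```sh
# write a synthetic fixture (schedule.json + trajectories.csv)
etholight simulate --seed 1 --out fixtures/pk --paradigm photokinesis

# per-condition AUC, normalized dark response, genotype comparison
etholight photokinesis --traj fixtures/pk/trajectories.csv \
    --schedule fixtures/pk/schedule.json --out results/pk

# multi-day activity with 30/90-min lights-on windows
etholight diel --traj ... --schedule ... --out results/diel --windows 30,90

# tuning curves and per-fish total avoidance from a scored event table
etholight avoidance --events events.csv --out results/avoid

# 2^-dCt and fold changes vs a control group
etholight qpcr --wells qpcr.csv --control-group wt --out results/qpcr

# gated two-sample comparison of a (subject_id, group, value) table
etholight stats --data data.csv --out results/stats --alpha-gate 0.05
```

Every command writes a `provenance.json` (version, seed, resolved options)
next to its outputs; logs go to stderr only.

## File formats

All interchange is plain text: trajectories
(`subject_id,genotype,t_s,x_mm,y_mm`, blank coordinates = missing frames),
scored events (`subject_id,genotype,size_deg,presentation_index,outcome`),
spectra (`wavelength_nm,irradiance_W_m2_nm`), qPCR wells
(`sample_id,group,gene,replicate,ct`), and JSON schedules
(`{origin_zt, intervals:[{start_s,end_s,condition,intensity,acclimation}]}`).
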