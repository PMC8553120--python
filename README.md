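# aprt

A fully scriptable re-implementation of a tri-outcome sequential physical-risk
task (the APRT), together with a simulated-agent cohort harness and the
complete scoring and statistical pipeline — so the task's design, outcome
mechanics, psychometrics, and factorial analysis can be exercised and extended
without human participants.

Each of the 64 trials crosses a picture category (animal, cliff, disaster,
hero) with four binary risk factors (injury probability 1/15 vs 1/5, injury
magnitude 5–35 vs 60–90, reward probability 2/3 vs 9/10, reward magnitude
5–25 vs 50–250). Every press yields reward, neutral, or injury; injuries drain
both health (from 100) and points; quitting banks the trial's points, death
forfeits them. A "cool" mode enforces a 1500 ms inter-press delay.

## Layout

| module            | contents                                                         |
|-------------------|------------------------------------------------------------------|
| `aprt.design`     | factor configuration, full-factorial counterbalanced trial sets, practice trials, border-cue encoding, balance reports |
| `aprt.engine`     | per-press outcome sampling, health/points state, death/quit semantics, simulated timestamps, CSV event logs |
| `aprt.agents`     | trait profiles (press drive, injury-cue sensitivity, satisficing target, health caution, delay attenuation), press/quit policies, cohort generation with trait-correlated synthetic scale scores |
| `aprt.scoring`    | the four outcome scores (Points, Go Presses, Injuries, Remaining Health), condition means, low−high difference scores, Cronbach's α, difference-score reliability |
| `aprt.analysis`   | +3 SD Winsorizing, log(x+1) transform, 21-term factorial GEE effect tables with Wald tests, Holm–Sidak step-down correction, interaction decomposition, correlation family screens |
| `aprt.config` / `aprt.pipeline` / `aprt.cli` | YAML/JSON config, end-to-end orchestration with a reproducibility manifest, `aprt` command line |

## Command line

```bash
aprt design   --seed 11 --out design.csv
aprt cohort   --n 200 --seed 3 --out out/
aprt simulate --design design.csv --policy satisficer --target 40 \
              --seed 1 --mode cool --out out/
aprt score    --in out/ --out scores.csv
aprt analyze  --scores scores.csv --participants out/participants.csv \
              --trials out/trials.csv --out out/
aprt run      --seed 7 --n 100 --out out/        # full pipeline + manifest
```

All stages are deterministic under their seeds; `manifest.json` records the
config hash, stage seeds, and SHA-256 of every artifact.

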