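# frailtykit

Toolkit for deriving frailty indicators from heterogeneous ambient-sensor
event streams, Fried-phenotype-style criterion scoring, and the
concurrent-validity statistics used to compare sensor measurements with
ground truth — bundled with a synthetic home-lab session simulator so the
entire pipeline runs end to end with no external data.

## What it does

- **`event_model`** — typed sensor events (motion, pressure mat, stair
  distance, door, weight scale, smart speaker) and ground-truth activity
  intervals, with validated JSON Lines / CSV readers and writers.
- **`indicators`** — sedentary bouts from mat occupancy transitions,
  stair-climb times from paired distance triggers (with direction),
  room-presence durations from confirmed motion transitions, and
  confirmed outings (door-event spans longer than 5 minutes with no
  interior sensor activity).
- **`exhaustion_dialogue`** — the three-question smart-speaker
  conversation (availability gate, yes/no exhaustion question, frequency
  question) as a deterministic state machine over text tokens with a
  single-retry fallback; `sometimes`/`always` frequency answers score the
  exhaustion criterion positive.
- **`frailty_scoring`** — configurable criterion thresholds, weight-change
  tracking, and the 0 / 1–2 / 3+ positive-count mapping to
  non-frail / pre-frail / frail.
- **`agreement`** — Cohen's kappa (from proportions or from categorical
  pairs, with null-SE significance), Bland–Altman limits of agreement
  (bias ± 1.96 SD, the 20%-outside rule, proportional-bias regression),
  detection rates, Pearson correlation, and alignment of derived
  indicators against ground-truth activity records.
- **`homesim`** — simulates three-run sessions (guided, self-paced,
  self-paced slow) and corrupts them into event logs via per-sensor miss
  probabilities, latency jitter, occupancy flicker and token
  misrecognition; `run_validation_study` produces a per-sensor agreement
  report.

## CLI

```sh
frailtykit show-config                  # print effective defaults as YAML
frailtykit -c config.yaml simulate -o out/        # activity + event logs
frailtykit -c config.yaml derive -e out/events_p1.jsonl -o out/
frailtykit -c config.yaml validate -o report.json --plots-dir plots/
frailtykit report report.json           # human-readable summary
```

All parameters (indicator debounce/pairing windows, agreement grid and
tolerances, simulator noise model, seed) live in one YAML file; unknown
keys are rejected. Exit codes: 2 = configuration error, 3 = data error.

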