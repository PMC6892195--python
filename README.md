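# ctsgrade

Rule-based nerve-conduction severity grading for carpal tunnel syndrome
(CTS), for clinical physiologists and for anyone building or validating
electrodiagnostic reporting pipelines.

CTS — entrapment of the median nerve in the carpal tunnel — is graded from
nerve conduction studies (NCS). `ctsgrade` implements a nine-grade revised
scale as a deterministic rule cascade over structured per-hand NCS records,
alongside the widely used seven-grade Bland scale as a comparator, cohort
count/percentage summaries against published reference cohorts, and a
seeded synthetic record generator used for round-trip validation.

## The scale

Each hand is described by the digit III (and conditionally digit II / IV)
sensory conduction velocity (SCV, m/s) and peak-to-peak amplitude (μV), the
ring-finger double-peak interpeak latency (ms), the abductor pollicis brevis
(APB) distal motor latency (DML, ms), base-to-peak amplitude (mV) and motor
conduction velocity (MCV, m/s), and — when the standard responses are
absent — the second-lumbrical latencies/amplitudes from median and ulnar
wrist stimulation. Grades, evaluated most-severe-first:

| Grade | Label | Defining pattern |
|---|---|---|
| 0 | Normal | SCV > 50, sensory amp ≥ 5 μV, DML ≤ 4.2, motor amp ≥ 5 mV, MCV ≥ 50 |
| 1 | Early | SCV ∈ [45, 50] **and** digit IV double peak > 0.5 ms, motor normal |
| 2 | Mild Sensory | SCV ∈ [40, 45), amplitudes and motor normal |
| 3 | Mild Sensory-Motor | as 2 with DML > 4.2 ms |
| 4 | Moderate Sensory | SCV < 40, amplitudes and motor normal |
| 5 | Moderate Sensory-Motor | as 4 with DML > 4.2 ms |
| 6 | Severe Sensory-Motor | digits II+III absent, or both < 3 μV with SCV < 30; DML > 4.2 ms |
| 7 | Extremely Severe | all standard responses absent; median lumbrical prolonged and low vs ulnar |
| 8 | Complete | all standard and median lumbrical responses absent; ulnar lumbrical intact |

A record that matches no printed pattern (e.g. sensory amplitude in the
[3, 5) μV gap, or an isolated motor abnormality with normal sensory
findings) is returned as **Indeterminate** with machine-readable reason
codes rather than forced into a neighbouring grade. Every grade carries an
advisory treatment band (1–2 physiotherapy, 3–4 conservative/steroid,
5–7 surgical, 8 surgeon's judgement).

## Worked example

```sh
ctsgrade simulate --n 12 --mix uniform --seed 7 -o cohort.csv
ctsgrade grade cohort.csv -o graded.csv
ctsgrade summarize graded.csv
```

prints

```
label  count  percent
Normal                            1  8
Early                             0  0
Mild Sensory                      4  33
Mild Sensory-Motor                0  0
Moderate Sensory                  1  8
Moderate Sensory-Motor            1  8
Severe Sensory-Motor              1  8
Extremely Severe Sensory-Motor    3  25
Complete                          1  8
Total hands  12
```

— twelve synthetic hands drawn uniformly over the nine grades, graded and
tallied (percentages are integer round-half-up). The graded CSV keeps the
input columns verbatim and appends `revised_grade`, `revised_label`,
`reasons` and `treatment_band`. The same from Python:

```python
from ctsgrade import classify_revised, treatment_band
from ctsgrade.io_cli import read_records

record = read_records("cohort.csv").records[0]
grade = classify_revised(record)
print(grade.value, grade.label, grade.reasons, treatment_band(grade).value)
# 5 Moderate Sensory-Motor ('scv_moderate_band', 'sensory_amp_normal', 'dml_prolonged') surgical
```

Other subcommands: `ctsgrade validate` (conditional-testing-protocol
checks), `ctsgrade grade --scale bland|both`, `ctsgrade compare`
(both scales plus a correspondence-consistency flag per row) and
`ctsgrade compare-table` (three-scheme percentage comparison against the
published Padua and Bland reference cohorts). Thresholds are configurable
via `--thresholds config.yaml`; every run emits a row-accounting manifest.

## Layout

- `ctsgrade.ncs_model` — record/measurement types, protocol validation
- `ctsgrade.revised_grader` — the 0–8 cascade, thresholds, treatment bands
- `ctsgrade.bland_grader` — Bland comparator and the static correspondence
- `ctsgrade.cohort_stats` — summaries, percentages, reference tables
- `ctsgrade.synthetic_data` — seeded interior-sampling record generator
- `ctsgrade.io_cli` — CSV schema, CLI, manifests

See `docs/methods.md` for the full account of the rules, boundary
conventions and the generator's design.
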