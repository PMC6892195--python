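# Methods

## The grading model

The package grades carpal tunnel syndrome severity from one hand's nerve
conduction measurements by a fixed, deterministic rule cascade evaluated
most-severe-first. The underlying clinical logic: median-nerve compression
first slows the sensory fibres (conduction velocity bands below 50 m/s),
then prolongs the distal motor latency (DML), then abolishes the standard
sensory and thenar motor responses; at that end of the spectrum the
second-lumbrical recordings — the median-innervated 2nd lumbrical retains
conduction longer than any other median territory — separate an extremely
severe lesion (lumbrical response prolonged and low relative to its ulnar
counterpart) from complete median dysfunction (median lumbrical also
absent, ulnar lumbrical intact as the technical control proving the
stimulation worked).

Every measurement is three-valued: `measured`, `absent` (stimulated, no
recordable response — itself a grading criterion at grades 6–8) or
`not_tested`. Collapsing `absent` into a null would make complete median
loss indistinguishable from missing data, which is the clinically critical
distinction the model exists to preserve.

### Conditional testing protocol

Real recording follows a decision tree which the validator
(`validate_record`) and the generator both honour: digit III is always
attempted; digit II only when digit III is below 3 μV or absent; digit IV
only when digit III conducts at 45–50 m/s (the band where the ring-finger
double peak is informative); the 2nd lumbricals only when digits II/III and
APB are all absent. Violations are warnings with one-line renderings —
grading proceeds on whatever is present (`--strict` upgrades them to
rejections).

### Thresholds and boundary conventions

All cut points live in `GradingThresholds` (units: m/s, ms, μV, mV) and
default to the scale's published values. Band edges are pinned exactly
(comparisons carry no epsilon; clinical readings have at most one decimal,
so ties land deliberately):

- Normal sensory velocity is **> 50**; the early band is **[45, 50]**
  inclusive at both ends; mild is **[40, 45)**; moderate is **< 40**. The
  bands derive from four scalar cuts, so they are contiguous and
  non-overlapping by construction.
- Abnormal DML means **> 4.2 ms**; exactly 4.2 is normal. The source
  definitions overlap at 4.2 (the normal grade says ≤ 4.2, the
  sensory-motor grades say ≥ 4.2); resolving in favour of the normal side
  keeps the rule regions disjoint.
- Amplitude normality is **≥ 5** (μV sensory, mV motor); the severe sensory
  cut is **< 3 μV** together with SCV **< 30 m/s** on the measured branch.
- The digit IV double peak is positive strictly **> 0.5 ms**.
- Grade 7's "prolonged" lumbrical latency has no published figure; the
  default is median ≥ ulnar **+ 0.4 ms**, with "low amplitude" as strictly
  below the ulnar amplitude. Both are explicit configuration, not
  hard-coded.
- Grade 6 constrains only the DML on the motor side: a slow *or* normal MCV
  and a low APB amplitude are all permitted.

### Deliberate refusals

Three measurable patterns fall between the printed grades and return
Indeterminate with a diagnostic reason instead of a guess:

- `amplitude_gap` — sensory amplitude in [3, 5) μV anywhere, or < 3 μV
  without the full severe pattern (e.g. SCV exactly 30).
- `isolated_motor_abnormality` — abnormal motor values with fully normal
  sensory findings; every grade above 0 short of 6–8 requires sensory
  involvement.
- `severe_sensory_normal_motor` — absent/tiny sensory responses with a
  normal DML.

A velocity in the early band *without* a positive double peak (or with
digit IV untested) has no positive finding and grades 0 with the advisory
reason `early_criteria_not_met`. Missing measurements required by every
reachable rule (untested digit III, missing APB, missing lumbricals on the
absent pathway) likewise return Indeterminate with a `*_missing` code.

## The Bland comparator

The Bland scale (0–6) is implemented from its standard transcription: 6 —
APB amplitude < 0.2 mV (taking precedence over latency, since amplitude is
that grade's discriminator); 5 — DML > 6.5 ms; 4/3 — DML in the open band
(4.5, 6.5) with the digit III sensory response absent/preserved; 2 — SCV
< 40 m/s with DML ≤ 4.5 ms; 1 — positive comparative finding on otherwise
normal studies; 0 — none of the above. Two limitations are accepted
knowingly: grade 1's inching and palm/wrist comparisons are not in the
record schema, so only the ring-finger double peak operationalises it; and
a DML of exactly 6.5 ms sits between the open moderate band and the > 6.5
rule as transcribed, falling to the grade 0 fallthrough — a measure-zero
transcription artifact, not a clinical claim.

The static correspondence Bland→revised {0→{0}, 1→{1}, 2→{2,3}, 3→{4,5},
4→{6}, 5→{7}, 6→{8}} partitions the revised scale (property-tested). The
two classifiers on the same record need *not* agree through it — the scales
draw their mild/moderate boundaries differently (Bland's mild starts at
SCV < 40; the revised mild band is 40–44.9) — so no cross-classifier
equivalence is asserted, only the per-row consistency flag that
`ctsgrade compare` reports.

## Cohort summaries

Percentages are integer round-half-up of 100·count/total, computed in exact
integer arithmetic (`floor((200c + t) / 2t)`). The convention is pinned by
two published half-way cells, 123/600 → 21 and 81/600 → 14, which bankers'
rounding would break. Indeterminate results are reported on a separate
accounting line and never folded into the nine grade labels.

The published reference counts (the 2246-hand revised cohort, the 600-hand
Padua cohort and the Bland cohort) ship as a packaged CSV. The Bland
category counts sum to 8141 while the printed total is 8501; the
discrepancy is preserved as printed, and the printed total is the
percentage denominator — every printed Bland percentage reproduces under
8501, several fail under 8141. Patient accounting is likewise carried as
printed: 1132 referred − 2 declined − 7 protocol breaches = 1123 patients
(2246 hands).

## The synthetic generator

`generate` draws each hand's target grade from a configurable mix, then
samples measurements uniformly from the *interior* of that grade's defining
region — at least one jitter-scale (defaults: 0.5 m/s, 0.2 ms, 0.5 μV,
0.5 mV) away from every threshold — so the cascade recovers the hidden true
grade exactly by construction. Values are rounded to one decimal, the
precision of real machine readouts; the default jitter exceeds the rounding
step, so rounding cannot cross a cut. Boundary behaviour is deliberately
excluded from generation and pinned instead by hand-written witness tests.
Grade 6 records split evenly between the measured-but-tiny and
fully-absent sensory variants; grade 7 sets the median lumbrical latency to
ulnar + U(0.6, 2.0) ms and its amplitude to 20–70 % of ulnar, comfortably
beyond the 0.4 ms default cut.

`generate_paper_mix` fixes the true-grade multiset to the published
per-grade counts exactly (2246 hands, deterministic counts, seeded ordering
and values), so the simulate → grade → summarize pipeline reproduces the
published count and percentage columns whenever the round trip is exact.

Demographics emulate the study cohort's shape: two hands per synthetic
patient, ages from a normal(56, 15) clipped to [19, 98] (empirical median
≈ 56), sex female with probability 687/1123, and a symptomatic flag that is
always set for graded hands and 25 % of normal hands. The generator does
**not** model bilateral severity correlation, age–severity structure, or
measurement correlation between sites — no distributional detail exists to
emulate — so passing round-trip tests demonstrate the grader/generator
contract on clean interior data, not performance on real clinical
populations, where borderline values, technical artefacts and protocol
deviations are common.

## Numerical and I/O choices

- Comparisons are exact floating-point; no tolerance is applied anywhere in
  the cascade.
- CSV statuses are case-insensitive on read, canonical lowercase on write;
  numeric cells must be empty unless the site was measured; a decimal comma
  is rejected, never coerced (silent locale conversion risks ten-fold
  misreadings of clinical values).
- Rejected rows are reported with row number and reason, never dropped
  silently; every CLI run emits a manifest whose accounting sums
  (read = graded + indeterminate + rejected). Exit codes: 0 OK, 1
  usage/config, 2 schema, 3 all rows rejected.

## Problem sizes

The test suite exercises the round trip on 10,500 generated records across
five seeds (and the acceptance script on a further 10,500 across five
derived seeds); the paper-mix pipeline runs at the full 2246-hand cohort
size. The whole suite completes in a few seconds.

## Known limitations

- The scale's undefined regions (the [3, 5) μV sensory amplitude gap,
  isolated motor abnormality) are refused, not graded; a clinical user must
  review Indeterminate rows.
- Ulnar digit V sensory and FDI motor recordings are carried as context
  only; no grading rule consumes them.
- The treatment band is advisory output and is always rendered with an
  "(advisory)" marker; it encodes no patient-specific factors.
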