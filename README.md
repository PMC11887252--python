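# teemetrics

Motion analytics for simulator-based transesophageal echocardiography (TEE)
training.

Learning TEE means learning to coordinate five probe degrees of freedom —
insertion depth, handle rotation, ante/retroflexion, left/right flexion and
the electronic omniplane angle — while watching only the ultrasound image.
Simulators log every probe manipulation at 10 Hz, which makes objective,
quantitative skill assessment possible. `teemetrics` implements that
assessment for a pre/post training design: each trainee performs the same
16-view examination protocol twice (before and after self-training), and the
package scores both sessions and compares them.

It is aimed at medical-education researchers and simulator developers who
need a reproducible pipeline from raw probe trajectories to cohort-level
statistics — and, because real trainee logs are usually proprietary, it
ships a synthetic cohort generator with the same statistical structure so
every stage can be exercised end to end.

## What is computed

**Plane precision.** Each standard view is defined by three expert landmark
points `P1..P3` with per-point tolerance limits `L1..L3`. For an imaging
plane with unit normal **n** through the transducer tip **o**, the
perpendicular distances `d_i = |(P_i − o)·n|` give

```
precision = clamp(1 − 0.2 · mean_i(d_i / L_i), 0, 1)
```

so a plane through all three landmarks scores 1.0 and a plane exactly at
the tolerance limits scores 0.80 — the pass cutoff. A view is *passed* when
the attempt ends with precision ≥ 0.80 held for at least 3 s and no
esophageal perforation; a session is passed when all 16 views pass.

**RAR index** (rapidity and randomity of probe motion), per coordinate
signal `s` with timestamps `t`:

```
RAR = Σₙ |ds_n/dt|,   ds/dt = (s_{n+1} − s_{n−1}) / (t_{n+1} − t_{n−1})
```

summed over the interior samples of each view attempt, for the four
mechanical coordinates only (depth, rotation, both flexions — the omniplane
angle is electronic and cannot hurt the patient). RAR is a surrogate for
potentially injurious probe motion.

**Improvement rubric.** Each view's Test 1 → Test 2 change is graded on a
−2…+2 scale from time, final precision and RAR (ratios to the Test 1
value), with precedence +2, −2, +1, −1, 0:

| grade | condition |
|---|---|
| +2 | time at least halved, precision ≥ 0.80, RAR not worse |
| +1 | time shorter by 5–99 %, precision ≥ 0.80, RAR within +30 % |
| 0 | time within ±5 %, precision ≥ 0.80, RAR within ±30 % |
| −1 | time longer by >5 %, or precision < 0.80, or RAR doubled |
| −2 | time more than doubled, with precision or RAR deterioration |

Students are classified improved/neutral/worsened by their mean grade.

**Cohort statistics.** Shapiro–Wilk-routed paired t / Wilcoxon signed-rank
comparisons (the unpaired Student t / Mann–Whitney procedures are available
by flag), exact McNemar for paired pass/fail counts, descriptive summaries
(mean ± SD, median and type-7 IQR), and a subanalysis of four
representative views (ME Mitral Commissural, ME Bicaval, ME Asc Ao SAX,
TG Basal SAX).

## Worked example

Simulate a 4-student cohort and analyze it in one go:

```
$ teemetrics run --n-students 4 --seed 7 --out-dir demo
analyzed 4 students -> demo/report.json
rubric: 4 improved, 0 neutral, 0 worsened; mean +1.06 (SD 0.24)
```

`demo/report.json` then contains, among other tables (values from this
exact run):

* total examination time: median 828 s (Test 1) → 300 s (Test 2), expert
  reference 59 s, paired t-test p = 0.018 — training time roughly
  cut to a third;
* mean precision over every logged sample: 0.60 → 0.70;
* ante/retroflexion RAR: median 50 551 → 9 601 — far fewer unnecessary
  flexion movements;
* complete-protocol passes: 2/4 students → 4/4 (exact McNemar p = 0.5 at
  this tiny n);
* per-student mean grades between +0.81 and +1.38, so all 4 classified
  improved.

`demo/views.csv` holds the per-view metrics behind every table and
`demo/grades.csv` the rubric inputs and the clause each grade fired on.
To analyze your own logs instead, write one CSV per session in the
documented long format (see `teemetrics.session_log`) and run
`teemetrics analyze --logs-dir <dir>`.

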