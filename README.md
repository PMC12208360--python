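# codawork

Compositional multilevel analysis of how workers split their work hours
between **sedentary behaviour (SB)**, **light physical activity (LPA)** and
**moderate-to-vigorous physical activity (MVPA)**, across a nested
organisation: institutions → teams → workers. The motivating setting is
accelerometer-based time-use epidemiology in day-care institutions, where the
questions are *which organisational level drives the variation in physical
behaviour* and *which determinants (age, BMI, perceived exertion, pain,
psychosocial factors, team and institution characteristics) are associated
with it*.

Because daily behaviour durations are parts of a whole (a workday), they are
analysed as a composition. A worker's three-part composition
(x_SB, x_LPA, x_MVPA) is mapped to isometric log-ratio coordinates built from
the sequential binary partition SB | {LPA, MVPA}, then LPA | MVPA:

```
ilr1 = sqrt(2/3) * ln( SB / sqrt(LPA * MVPA) )
ilr2 = sqrt(1/2) * ln( LPA / MVPA )
```

On this unconstrained scale the package fits linear mixed models with random
intercepts for institutions and for teams within institutions:

* **Variance-components analysis** — ilr1 and ilr2 are stacked as a joint
  outcome with one REML variance parameter per level, giving each level's %
  contribution to the total behaviour variance.
* **Model 1** — both coordinates regressed on 15 determinants, with a 2-df
  joint Wald test per determinant across the coordinates.
* **Pivot models** — each behaviour rotated into the first ilr position and
  its first coordinate modelled alone; a slope β translates into a
  `100·(exp(β·sqrt(3/2)) − 1)` % change of that behaviour relative to the
  geometric mean of the other two.
* **Prediction curves** — fitted (ilr1, ilr2) along a determinant grid mapped
  back through the inverse ilr transform, as input for ternary plots.

The original worker-level data are not shareable, so the package ships a
synthetic generator that emulates the study design (16 institutions, ~73
teams, ~178 workers, 1–5 measured workdays per worker) with published
determinant distributions, variance components and effect sizes, letting every
pipeline stage be exercised and validated end to end.

## Worked example

```
$ codawork run-all --seed 5 --out run1
...
variance contributions (%): worker=84.831, team=14.555, institution=0.614
report bundle in run1

$ cat run1/summary.txt
codawork 0.1.0  (seed 5, config 52cc45fe7ad4b6b8)

Workers analysed: 178 (152 complete-case) in 72 teams / 16 institutions

Variance contributions to physical-behaviour composition (ilr scale):
  worker       0.0837  (84.8%)
  team         0.0144  (14.6%)
  institution  0.0006  (0.6%)

Determinants jointly associated with the composition (p < 0.05): physical_exertion, max_pain_intensity
  physical_exertion: -4.9% SB per unit (p=0.002)
  physical_exertion: +1.9% LPA per unit (p=0.310)
  physical_exertion: +3.6% MVPA per unit (p=0.059)
  max_pain_intensity: +4.7% SB per unit (p=0.000)
  max_pain_intensity: -2.6% LPA per unit (p=0.049)
  max_pain_intensity: -1.7% MVPA per unit (p=0.233)
```

Reading this: on one simulated study-sized dataset the worker level carries
most of the composition variance (84.8% here; single realisations of a 178-
worker design scatter widely around the generating value of ~95%), and the
two determinants simulated with non-zero effects — physical exertion
(−0.03 on ilr1 per unit) and maximal pain intensity (+0.03) — are the two
the joint test flags. Each `%` line is the pivot-model translation: e.g. one
extra unit of exertion shifts ≈4.9% of sedentary time (relative to the
geometric mean of the active behaviours). The bundle also contains
`descriptives.csv`, `composition_summary.csv`, `variance_components.csv`,
`model1_associations.csv`, `pivot_associations.csv`, `ternary_curves.csv` and
a `manifest.json` from which the entire run can be reproduced byte for byte.

Other entry points: `codawork simulate`, `codawork preprocess`,
`codawork analyse`, each with `--seed`, `--config`, `--out`,
`--min-work-hours` and `--aggregation {geometric,arithmetic}` where relevant.

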