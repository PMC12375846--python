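# prostasim

Person-level microsimulation and cost-effectiveness analysis of prostate
cancer screening strategies, built for the German policy question: should
the statutory early-detection programme keep offering annual digital
rectal examination (DRE), switch to PSA-based risk-adaptive screening
(PSA-RAS), and should MRI triage the biopsy decision?

The package compares ten strategies on a common simulated cohort:

* **no screening** — cancers surface symptomatically only;
* **annual DRE**, ages 45–75, suspicious findings referred to systematic
  biopsy;
* **eight PSA-RAS variants** — start at 45 or 50, stop at 60 or 70, with
  or without MRI triage.  A PSA below 1.5 ng/mL defers rescreening five
  years, 1.5–2.99 ng/mL two years, and ≥ 3 ng/mL triggers work-up
  (MRI-gated combined targeted + systematic biopsy in the MRI arms,
  systematic biopsy otherwise).

## The model

Each man carries a latent natural history simulated by competing hazards:
Weibull-within-susceptible-fraction preclinical onset; a Gleason grade
(< 7 / = 7 / > 7) fixed at onset with age-linked mixture probabilities;
T1→T2→T3 local progression and a metastasis clock with grade-specific
exponential rates (18 disease states: 3 extents × metastasis × 3 grades);
log-linear PSA growth, accelerating after onset, with person-level random
intercept and slope; a clinical-presentation hazard proportional to the
current PSA level and stage; and cause-specific survival after diagnosis
from a mixture cure model S(t) = c + (1 − c)e^(−rt) per stage and grade.

Screening benefit operates through **stage shift**: a screen-detected
cancer draws its survival from the curve of the earlier stage at
detection, with the clock starting at the counterfactual clinical
diagnosis age (the end of the lead time).  Because each man's no-screening
twin is simulated with the identical random substreams, **overdiagnosis**
(screen detection of a cancer that would never have surfaced in his
lifetime) and lead time are exact per-person quantities, not estimates.

The economics layer accumulates direct healthcare costs (2023 €, statutory
health-insurance perspective) and quality-adjusted life-years with a
multiplicative utility model, both discounted at 3 %/year from age 45.
Outcome tables per 100,000 men feed the efficiency frontier (strict and
extended dominance, ICERs between adjacent efficient strategies) and
cost-effectiveness acceptability curves from probabilistic draws.

All registry-style inputs (life table, age-specific incidence, grade
distributions, mortality) are generated by the synthetic-data module from
a known ground truth, so calibration can be validated by parameter
recovery.

## Worked example

```bash
python analysis/01_synthetic_inputs.py
python analysis/02_calibrate.py
python analysis/03_run_strategies.py
python analysis/04_cost_effectiveness.py
python analysis/05_sensitivity.py
```

`01` writes the Gompertz–Makeham life table (life expectancy 36.0 years at
age 45) and registry-style targets whose incidence peaks at 689 per
100,000 person-years in ages 70–75.  `02` recalibrates the onset and
grade-mixture parameters from a deliberately perturbed start and reports

```
  onset scale: fitted 31.066 vs true 31.000 (0.2% off)
  onset susceptible: fitted 0.222 vs true 0.220 (1.0% off)
mortality validation: 100% of age groups inside the 95% interval
```

`03` runs the ten strategies on 50,000 shared life histories (scaled to
per-100,000 outcomes).  Under the shipped synthetic conditions annual DRE
generates by far the most screen-initiated biopsies (82,838 per 100,000
vs 2,042–17,140 for the PSA-RAS arms) and the highest discounted cost
(215.5 M€ vs 173.0–187.8 M€), while MRI triage roughly halves
screen-initiated biopsies relative to the same-age non-MRI arm and lowers
overdiagnosis — the same qualitative ordering as the published German
analysis, though absolute levels depend on the synthetic ground truth.
`04` turns the outcome table into reduction rows, the efficiency frontier
and ICERs; `05` runs the deterministic scenarios (e.g. MRI at €120 per
scan, which cuts the discounted cost of the 50–70-with-MRI arm by 6.0 M€
per 100,000) and a desk-scale probabilistic analysis with CEACs.

The same pipeline is scriptable through the CLI:

```bash
prostasim simulate --n 50000 --seed 1 --out results/base_case
prostasim dsa --scenario scenario1_mri_120 --out results/dsa
```

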