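# colosim

Individual-level microsimulation of colorectal cancer (CRC) natural
history and organized screening, with paired per-1000 outcome accounting
and a data-envelopment-analysis (DEA) efficiency frontier over strategy
grids. It is aimed at screening-policy modellers who need to compare
fecal immunochemical testing (FIT), questionnaire risk scores (NCPCS),
and combined risk-stratification (RS) strategies across start ages, stop
ages, and intervals under realistic participation.

## Model

Each simulated person lives from birth to death (age ≤ 100) in annual
cycles. Adenoma–carcinoma-pathway lesions arise with age- and
sex-specific annual probability and progress

    early adenoma → advanced adenoma → preclinical cancer → clinical cancer

with geometric waiting times; a latent *aggressive* fraction of lesions
carries the fast, cancer-capable rates (mean dwell from genesis to
clinical cancer ≈ 13 y) while the indolent majority never progresses to
cancer. Serrated-pathway cancers arise directly as preclinical cancer
with no detectable precursor. Stage at diagnosis (I–IV) and exponential
stage-specific CRC survival compete with life-table mortality. All
randomness is addressed by keyed substreams
`(cohort_seed, person, stream, age…)`, so every screening strategy is
replayed on identical natural histories (common random numbers): a
strategy's benefit is the paired difference against no screening, not a
difference of independent cohorts.

Screening strategies `TEST:start-stop:interval` offer an initial test
(FIT / NCPCS / RS, per-offer participation), send positives to
diagnostic colonoscopy (per-test compliance), lock screening out for 5
years after a colonoscopy that finds nothing, and schedule polypectomy
surveillance (3 y / 5 y / 10 y-then-release, up to age 80). Efficiency
is assessed per test category by input-oriented variable-returns-to-
scale DEA on (colonoscopies per 1000, life-years gained per 1000), with
near-efficient strategies (LYG > 98% of the frontier) grouped with the
frontier. See `docs/methods.md` for the full model description.

## Worked example

```python
from colosim import datasets, evaluate_strategy, make_cohort, parse_strategy

life_table = datasets.load_life_table()
params = datasets.load_calibrated_params()      # calibrated natural history
cohort = make_cohort(100_000, 0.5, seed=1, life_table=life_table)

row = evaluate_strategy(cohort, params, parse_strategy("FIT:50-70:3"))
print(round(row.colonoscopies), round(row.lyg, 1),
      round(row.incidence_noscreen, 1), round(row.mortality_noscreen, 1))
```

prints `790 69.2 46.3 16.8`: triennial FIT screening from age 50 to 70
costs about 790 colonoscopies per 1000 persons (diagnostic work-ups,
surveillance, and symptomatic work-ups included) and gains about 69
life-years per 1000, against a no-screening background of 46.3 lifetime
CRC cases and 16.8 CRC deaths per 1000. The full 81-strategy grid and
its DEA classification:

```bash
colosim grid --n 100000 --out grid_outcomes.csv
colosim dea grid_outcomes.csv --out dea_classification.csv
```

Sensitivity variants: `--participation low` (mass-screening
participation and compliance) and `--no-surveillance`. `colosim synth`
writes fresh synthetic inputs; `colosim calibrate` re-runs the
benchmark calibration that produced the shipped parameter set.

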