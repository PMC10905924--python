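# Methods

`colosim` is an individual-level (microsimulation) model of colorectal
cancer (CRC) natural history and organized screening, with paired
outcome accounting against a no-screening scenario and a data
envelopment analysis (DEA) of strategy efficiency. This note documents
the model, its parameters and defaults, the synthetic inputs, and the
numerical choices; it is the authoritative description of what the code
does and why.

## Natural history

Each person is simulated from birth to death (capped at age 100) in
annual cycles, with events resolved per cycle in a fixed order: lesion
genesis, per-lesion progression, symptomatic transition and diagnosis,
CRC death, other-cause death. Two carcinogenesis pathways coexist:

* **Adenoma–carcinoma pathway.** New lesions arise with an annual,
  age-banded, sex-specific probability (`adenoma_risk`), starting at
  `min_genesis_age` (20 y). Each lesion independently carries a latent
  *aggressive* flag (probability `aggressive_fraction`). Aggressive
  lesions traverse early adenoma → advanced adenoma → preclinical cancer
  → clinical cancer with geometric annual waiting times
  (`p_early_to_advanced`, `p_advanced_to_preclinical`, both 0.18 by
  default) and an exponential preclinical sojourn (`sojourn_mean`,
  4.5 y). Indolent lesions may advance in size
  (`p_early_to_advanced_indolent`) but never become cancer.
* **Serrated pathway.** Cancer arises directly as preclinical cancer
  (annual age-banded `serrated_risk`), with no adenomatous precursor.
  These lesions are invisible to every test until they are cancers —
  including colonoscopy, which mirrors the behaviour of the model family
  this package re-implements (sessile-serrated precursors assumed
  undetectable).

**Why the aggressive/indolent split.** A homogeneous model cannot
simultaneously produce a mean dwell time (adenoma genesis to clinical
cancer) near 13 years and realistic ratios of adenoma prevalence to
cancer incidence: fast progression rates overproduce cancer, slow ones
stretch the dwell time to several decades. Splitting lesions into a
small cancer-capable fraction with fast rates and an indolent majority
resolves the tension; the defaults above give a measured mean dwell of
13.2 y (the "13-year dwell" model variant) after calibration. The
model has no per-person frailty term; lesion-level heterogeneity is the
only source of risk heterogeneity, which is a simplification relative to
richer microsimulators.

Size classes are tied to states because test sensitivities are
size-stratified: early adenomas start ≤5 mm and grow to 6–9 mm with
annual probability `p_growth` (0.12); advanced adenomas are ≥10 mm.

**Diagnosis and survival.** The first lesion to reach clinical cancer
before death is diagnosed symptomatically (no second primaries). Stage
(I–IV) is drawn from `stage_dist_symptomatic`; CRC death follows an
exponential with stage-specific rate `survival_rate`, competing with
other-cause death. Screen-detected cancers draw from an earlier
(stochastically dominating) distribution `stage_dist_screen`, using the
*same* stage uniform as the symptomatic counterfactual, so detection
mode shifts the stage comonotonically. Survival for screen-detected
cancers is clocked from the counterfactual clinical-onset age rather
than the detection age — this removes lead-time bias, so early
detection can only help, never harm, for a given draw. The stage
distributions and survival rates are free parameters of the model family
(no published transition values exist for this re-implementation); the
screen-stage distribution and the dwell-time split were fixed so the
screening layer reproduces the published per-1000 operating point of the
original model, and the survival rates are then set by calibration (see
below).

## Randomness and common random numbers (CRN)

Every random decision is addressed by a key
`(cohort_seed, person_id, stream, counter…)` hashed with splitmix64 to a
uniform deviate (`streams.py`). Named streams: mortality, sex,
natural_history, participation, test_noise, colonoscopy, complications.
The natural-history stream is consumed once per person in a fixed
pattern that does not depend on death age or screening (a 101×2 genesis
block, then a fixed number of deviates per lesion), so every scenario
replays the same lesion timelines; screening-layer draws are keyed by
age (and lesion), so an offer at age *a* consumes the same deviate under
every strategy. Consequently a strategy that never intervenes
reproduces the no-screening course bit-for-bit, and paired differences
have much lower Monte Carlo variance than independent cohorts (verified
in the test suite with replicate seeds).

## Screening layer

Four tests are specified by size-stratified sensitivity, specificity,
per-offer participation, and compliance with diagnostic colonoscopy
after a positive result: colonoscopy (sensitivity ranges resolved to
midpoints 0.70/0.84/0.95/0.975, specificity 1), FIT (qualitative,
100 ng hemoglobin/mL threshold), the NCPCS questionnaire score treated
as a sensitivity/specificity test, and the RS model (positive if NCPCS
or FIT would be positive) via its published direct characteristics.
Unreported sensitivities (e.g. sub-5 mm adenomas for FIT) are zero. The
per-person NCPCS score sheet (`ncpcs_score`) is implemented for
validation and documentation, but the simulation uses the
sensitivity/specificity shortcut — the published characteristics are
age-aggregated, which is a known age-dependency bias of this approach.
A compositional RS mode (`composed_rs_spec`, combining the FIT and
NCPCS rows as independent tests) is available for exploration but is
not the default.

A strategy is `test : start_age – stop_age : interval` with offers at
`start, start+i, … ≤ stop` while the person is alive, undiagnosed, not
locked out, and not in surveillance. Participation is redrawn
independently at each offer (random non-attendance; sticky attendance
patterns are out of scope). A positive test leads to diagnostic
colonoscopy with the test's compliance probability; non-compliant
positives simply continue to the next offer.

* **Lockout.** A diagnostic colonoscopy that finds nothing (the typical
  consequence of a false-positive test) suspends initial screening until
  5 years after that colonoscopy; offers inside the window are skipped,
  not deferred, so screening resumes at the first grid age ≥ lockout
  end.
* **Surveillance.** After polypectomy: advanced adenoma, ≥3 adenomas, or
  detected cancer → next colonoscopy in 3 y; 1–2 non-advanced adenomas →
  5 y; a clean surveillance exam → one recall at 10 y, and a second
  clean exam releases the person back to routine screening.
  Surveillance is offered up to age 80 regardless of the strategy's stop
  age, and routine initial tests are suspended during a surveillance
  episode. The exact intervals of the original model are not published;
  this default schedule is a stated stand-in and is configurable
  (`SurveillanceConfig`).
* **Harms.** Each colonoscopy carries a per-procedure death probability
  of 3.4 × 10⁻⁵ — a derived default chosen so harms are of the order of
  published values (≈0.2 deaths per 1000 at ≈5900 colonoscopies);
  years lost are computed within the paired run as the counterfactual
  death age (same scenario, complications suppressed) minus the
  complication death age.
* **Symptomatic diagnosis** adds one work-up colonoscopy in *both*
  scenarios (≈46 per 1000 under no screening, consistent with the
  reconstructed baseline used in published incremental ratios), and is
  not followed by surveillance.

## Outcomes

`evaluate_strategy` replays no-screening and the strategy on identical
person streams and reports, per 1000 persons: colonoscopies (diagnostic
+ surveillance + symptomatic), non-colonoscopy tests actually taken
(offers declined by the participation draw are not counted), reduced
lifetime CRC cases and deaths (no-screen minus screen on the same
cohort), life-years gained (sum of death-age differences), colonoscopy
deaths, and years lost to colonoscopy. Life-years are undiscounted.
CSV output is unrounded; the presentation table rounds per-1000 counts
to integers.

## Calibration

Targets are age/sex-banded early- and advanced-adenoma prevalence
(% of alive persons at the band midpoint), CRC incidence and mortality
(per 100,000 person-years), and the rectal fraction of cancers. A
simulated point passes when within ±20% of its benchmark. The search is
blockwise iterative proportional fitting on a fixed CRN cohort:
adenoma-genesis multipliers per sex and age band track early prevalence;
the indolent advance probability tracks advanced prevalence; the
aggressive fraction and serrated rate track incidence; the
stage-specific survival rates track mortality relative to incidence
(with a stronger step exponent because the death probability saturates
in the rate); the rectal fraction is set directly. Ratios are damped
(exponent 0.5, clipped to [¼, 4]) and rate-block pooling is
person-year-weighted so the pooled ratio is an expected-count ratio.
After the banded sweeps, a few *level-polish* steps adjust only the
global incidence and survival scalars until the simulated lifetime
incidence and mortality match the life-table integrals of the benchmark
curves (within 2%). This scheme is robust to the stochastic objective
at moderate cohort sizes, where a generic optimizer is not.

The shipped `params_calibrated.yaml` was produced by
`colosim calibrate` (cohort 100,000, budget 20 sweeps + 4 polish steps,
seed 3) against the packaged synthetic benchmarks; 73% of benchmark
points fall inside the ±20% envelope (all early-prevalence and rectal
points; the residual misses are incidence/mortality band-shape effects
at the age extremes, where the model's genesis-driven incidence shape
and its dispersed post-diagnosis survival cannot follow the synthetic
curves exactly).

## Synthetic inputs

No external data ship with the package. `synthetic.py` generates:

* a **Gompertz–Makeham life table** (hazard `c + a·e^{b·age}`) scaled by
  bisection so life expectancy at birth is 78 y, with sex-specific
  columns offset ±2.5 y. The slope (b = 0.105) was chosen so remaining
  life expectancy at older ages matches a China-2020-like pattern
  (≈13.5 y at age 70) — the quantity that converts averted CRC deaths
  into life-years;
* **benchmark curves**: early-adenoma prevalence logistic in age
  (asymptote 0.40, midpoint 66 y, slope 0.055, male/female multipliers
  1.2/0.8); advanced prevalence as the accumulating integral of the
  early curve pinned to 7% (sex-averaged) at ages 60–65; incidence
  following the lesion-genesis shape (prevalence derivative plus pool
  turnover 0.04/y) lagged by the 12-y dwell and scaled so the
  life-table-weighted lifetime risk is 4.6%; mortality the same shape
  lagged 7 further years, scaled to lifetime 1.7%. The level choices
  sit inside ranges reported by Chinese colonoscopy series and
  registries, and the shapes are chosen to be *reachable* by the model
  family, so calibration failures indicate implementation faults rather
  than fixture artefacts.

The fixture is a synthetic look-alike: it does not reproduce registry
noise, cohort effects, secular trends, or the literal values used by any
published calibration, so passing tests demonstrate internal
consistency and faithful mechanics at a realistic operating point — not
agreement with any specific population's data. `make_ground_truth`
samples jittered parameter sets and summarizes simulated cohorts into
benchmark sets for parameter-recovery experiments.

## Efficiency analysis

Strategies are DEA decision-making units with one input (colonoscopies
per 1000) and one output (LYG per 1000). Scores come from the
input-oriented variable-returns-to-scale LP; with one input and one
output the efficient set is orientation-invariant, so the choice of
orientation does not affect classification. Near-efficient strategies
fall below the frontier with LYG above 98% of the frontier value at
their colonoscopy count (linear interpolation between vertices; flat
beyond the largest frontier input); summaries group efficient and
near-efficient together. Ties at identical (input, output) share their
classification, and the frontier is invariant to duplicated points.
Ratios: ΔCOL/ΔLYG against the category default (least-input efficient
strategy; a zero ΔLYG is reported as infinite with a warning) and
additional colonoscopies per LYG against the no-screening baseline.
DEA runs per test category by default (pooled mode available).

## Problem sizes and determinism

The packaged analyses use 100,000-person cohorts (calibration,
acceptance reproduction); unit and property tests use 2,000–30,000
persons. Cohorts, histories, and screening replays are exactly
reproducible from a single integer seed; hypothesis-based property
tests run derandomized. The paired-design variance demonstration uses
4,000 persons × 8 replicate seeds.

## Known limitations

* Two colonic sites only (rectum/colon); no 13-segment anatomy and no
  continuous polyp-growth model.
* No per-person frailty; adenoma multiplicity is Poisson-like by
  construction.
* An all-cause life table is treated as other-cause mortality, slightly
  double-counting CRC deaths among the very old if the user supplies a
  real all-cause table (the synthetic table is interpreted as
  other-cause by fiat).
* Participation is independent across rounds; persistent attenders or
  refusers are not modelled, and per-round varying participation is out
  of scope.
* NCPCS/RS use age-aggregated sensitivity/specificity, overestimating
  positivity in the young and underestimating it in the old.
* Costs, QALYs/DALYs, and cost-effectiveness ratios are out of scope.
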