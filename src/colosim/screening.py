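"""Organized screening: initial tests, diagnostic colonoscopy, surveillance.

Screening is applied as a *replay* over a person's precomputed natural
history: the lesion timeline is fixed (drawn once from the
natural-history substream), and every screening decision — participation,
test noise, colonoscopy detection, complications — is addressed by
``(cohort_seed, person_id, stream, age[, lesion])`` keyed uniforms.  A
draw at a given age is therefore identical under every strategy, and a
strategy that never intervenes reproduces the no-screening course
bit-for-bit.

Implemented tests: FIT (qualitative, 100 ng hemoglobin/mL threshold),
the NCPCS questionnaire risk score (simulated as a sensitivity/
specificity test; the per-person score sheet exists for validation), the
RS model combining the two, and colonoscopy itself.  Per-offer
participation, compliance with diagnostic colonoscopy after a positive
result, a 5-year screening lockout after a colonoscopy that finds
nothing, and post-polypectomy surveillance scheduling follow the rules
described in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .natural_history import MAX_AGE, NHParams, PersonHistory, STAGES
from .streams import u01

INF = math.inf

PART, TEST, COLO, COMPLIC = 4, 5, 6, 7  # stream ids (see streams.STREAMS)


class ScreeningError(ValueError):
    pass


# ---------------------------------------------------------------------
# Test specifications (sensitivities in proportion units)
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TestSpec:
    """Size-stratified screening-test characteristics.

    Unreported sensitivities are stored as 0 (a test that cannot see a
    lesion class simply never detects it).
    """

    name: str
    sens_small: float      # adenomas <= 5 mm
    sens_medium: float     # adenomas 6-9 mm
    sens_large: float      # adenomas >= 10 mm
    sens_crc: float
    specificity: float
    participation: float = 1.0
    colonoscopy_compliance: float = 1.0

    def __post_init__(self):
        for f in ("sens_small", "sens_medium", "sens_large", "sens_crc",
                  "specificity", "participation", "colonoscopy_compliance"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ScreeningError(f"{self.name}: {f}={v} outside [0, 1]")

    def sensitivity_for(self, lesion, age: float) -> float:
        state = lesion.state(age)
        if state in ("preclinical_cancer", "clinical_cancer"):
            return self.sens_crc
        if lesion.pathway != "adenoma_carcinoma":
            return 0.0  # serrated precursors invisible until cancer
        if state not in ("early_adenoma", "advanced_adenoma"):
            return 0.0
        size = lesion.size_class(age)
        return {"small": self.sens_small, "medium": self.sens_medium,
                "large": self.sens_large}[size]


# Colonoscopy sensitivity ranges resolved to midpoints by default.
COLONOSCOPY = TestSpec("colonoscopy", 0.70, 0.84, 0.95, 0.975, 1.0, 1.0, 1.0)

_TRIAL = {
    "FIT": TestSpec("FIT", 0.0, 0.129, 0.339, 0.833, 0.902, 0.940, 0.763),
    "NCPCS": TestSpec("NCPCS", 0.0, 0.687, 0.775, 0.787, 0.545, 0.997, 0.492),
    "RS": TestSpec("RS", 0.0, 0.709, 0.812, 0.936, 0.520, 0.937, 0.770),
}
# Sensitivity-analysis profile: mass-screening participation and compliance.
_LOW = {
    "FIT": replace(_TRIAL["FIT"], participation=0.420, colonoscopy_compliance=0.648),
    "NCPCS": replace(_TRIAL["NCPCS"], participation=0.154, colonoscopy_compliance=0.335),
    "RS": replace(_TRIAL["RS"], participation=0.140, colonoscopy_compliance=0.389),
}
PROFILES = {"trial": _TRIAL, "low": _LOW}


def get_test_spec(name: str, profile: str = "trial") -> TestSpec:
    if name == "colonoscopy":
        return COLONOSCOPY
    try:
        return PROFILES[profile][name]
    except KeyError:
        raise ScreeningError(f"unknown test {name!r} or profile {profile!r}") from None


def composed_rs_spec(profile: str = "trial") -> TestSpec:
    """RS model built by composing FIT and NCPCS as independent tests.

    Exploration alternative to the published direct RS characteristics
    (the default): positive iff either component is positive, so
    sensitivities combine as 1-(1-a)(1-b) and specificities multiply.
    """
    fit, ncpcs = PROFILES[profile]["FIT"], PROFILES[profile]["NCPCS"]
    both = lambda a, b: 1.0 - (1.0 - a) * (1.0 - b)
    rs = PROFILES[profile]["RS"]
    return TestSpec(
        "RS-composed",
        both(fit.sens_small, ncpcs.sens_small),
        both(fit.sens_medium, ncpcs.sens_medium),
        both(fit.sens_large, ncpcs.sens_large),
        both(fit.sens_crc, ncpcs.sens_crc),
        fit.specificity * ncpcs.specificity,
        rs.participation, rs.colonoscopy_compliance)


# ---------------------------------------------------------------------
# NCPCS questionnaire score (kept for validation/documentation; the
# simulation uses the published sensitivity/specificity shortcut).
# ---------------------------------------------------------------------

@dataclass
class NCPCSInputs:
    sex: str                    # "male" | "female"
    age: float
    bmi_class: str = "<24"      # "<24" | ">=24"
    smoking: str = "never"      # "never" | "current/past"
    drinking: str = "no"        # "no" | "current"
    diabetes: bool = False
    fdr_crc: bool = False       # first-degree relative with CRC
    pnc: bool = True            # previous negative colonoscopy

    def __post_init__(self):
        if self.age < 0:
            raise ScreeningError("age must be non-negative")


NCPCS_THRESHOLD = 15


def ncpcs_score(x: NCPCSInputs) -> tuple[int, bool]:
    """National Colorectal Polyp Care score and positivity (score >= 15)."""
    score = 2 if x.sex == "male" else 0
    if x.age >= 60:
        score += 13
    elif x.age >= 50:
        score += 11
    elif x.age >= 45:
        score += 9
    elif x.age >= 35:
        score += 7
    score += 1 if x.bmi_class == ">=24" else 0
    score += 2 if x.smoking == "current/past" else 0
    score += 2 if x.drinking == "current" else 0
    score += 3 if x.diabetes else 0
    score += 2 if x.fdr_crc else 0
    score += 0 if x.pnc else 3
    return score, score >= NCPCS_THRESHOLD


# ---------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------

GRID_STARTS = (40, 45, 50)
GRID_STOPS = (70, 75, 80)
GRID_INTERVALS = (1, 2, 3)


@dataclass(frozen=True)
class StrategySpec:
    """One screening schedule: test, start/stop ages, interval in years."""

    test: str
    start_age: int
    stop_age: int
    interval: int
    surveillance_enabled: bool = True
    participation_profile: str = "trial"

    def __post_init__(self):
        if self.start_age >= self.stop_age:
            raise ScreeningError("start_age must be < stop_age")
        if self.interval < 1:
            raise ScreeningError("interval must be >= 1 year")

    @property
    def label(self) -> str:
        return f"{self.test}:{self.start_age}-{self.stop_age}:{self.interval}"

    def offer_ages(self):
        return list(range(self.start_age, self.stop_age + 1, self.interval))


def parse_strategy(text: str, **kw) -> StrategySpec:
    """Parse ``TEST:start-stop:interval`` strings, e.g. ``FIT:50-70:3``."""
    try:
        test, ages, interval = text.split(":")
        start, stop = ages.split("-")
        return StrategySpec(test=test, start_age=int(start), stop_age=int(stop),
                            interval=int(interval), **kw)
    except (ValueError, TypeError) as exc:
        raise ScreeningError(f"cannot parse strategy {text!r}") from exc


def default_grid(tests=("FIT", "NCPCS", "RS"), **kw) -> list:
    """The full strategy grid: 3 starts x 3 stops x 3 intervals per test."""
    return [StrategySpec(test=t, start_age=a, stop_age=b, interval=i, **kw)
            for t in tests for a in GRID_STARTS for b in GRID_STOPS
            for i in GRID_INTERVALS]


# ---------------------------------------------------------------------
# Surveillance scheduling
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SurveillanceConfig:
    interval_high: int = 3    # advanced adenoma, >=3 adenomas, or cancer
    interval_low: int = 5     # 1-2 non-advanced adenomas
    interval_clean: int = 10  # clean surveillance exam, once, then release
    max_age: int = 80


DEFAULT_SURVEILLANCE = SurveillanceConfig()


def surveillance_schedule(findings: dict, current_age: float,
                          config: SurveillanceConfig = DEFAULT_SURVEILLANCE,
                          enabled: bool = True):
    """Age of the next surveillance colonoscopy, or None (release).

    ``findings``: n_adenomas (removed at this exam), advanced (any advanced
    adenoma among them), cancer (cancer detected), surveillance_exam (this
    exam was itself a surveillance exam), consecutive_clean (clean
    surveillance exams so far in this episode).
    """
    if not enabled:
        return None
    if findings.get("cancer") or findings.get("advanced") \
            or findings.get("n_adenomas", 0) >= 3:
        nxt = current_age + config.interval_high
    elif findings.get("n_adenomas", 0) >= 1:
        nxt = current_age + config.interval_low
    elif findings.get("surveillance_exam") and \
            findings.get("consecutive_clean", 0) < 1:
        nxt = current_age + config.interval_clean
    else:
        return None  # clean exam: release to routine screening
    return nxt if nxt <= config.max_age else None


# ---------------------------------------------------------------------
# Test application primitives
# ---------------------------------------------------------------------

def _active_lesions(lesions, age, removed):
    return [les for les in lesions
            if les.genesis_age <= age and les.id not in removed]


def _initial_test_core(active, age, spec: TestSpec, u_fp, det_u):
    """Shared decision rule: detection per lesion, else false positive."""
    for les in active:
        sens = spec.sensitivity_for(les, age)
        if sens > 0 and det_u(les) < sens:
            return "true_positive"
    return "false_positive" if u_fp < 1.0 - spec.specificity else "negative"


def apply_initial_test(history: PersonHistory, age: float, spec: TestSpec,
                       rng: np.random.Generator, removed=frozenset()) -> str:
    """Offer one initial screening test; per-person Generator interface.

    Draw order: participation, then one deviate per extant lesion (in
    lesion order), then the false-positive deviate.  The replay engine
    applies the same decision rule with keyed substream draws.
    """
    if rng.random() >= spec.participation:
        return "not_taken"
    active = _active_lesions(history.lesions, age, removed)
    u = rng.random(len(active))
    for les, ui in zip(active, u):
        sens = spec.sensitivity_for(les, age)
        if sens > 0 and ui < sens:
            return "true_positive"
    return "false_positive" if rng.random() < 1.0 - spec.specificity \
        else "negative"


def colonoscopy_exam(lesions, age: float, colo: TestSpec,
                     rng: np.random.Generator, removed=frozenset()):
    """Detect and remove lesions at a colonoscopy (specificity 1).

    Returns (detected lesions, removed adenoma lesions, detected
    preclinical cancer lesion or None).
    """
    active = _active_lesions(lesions, age, removed)
    u = rng.random(len(active))
    detected, removed_adenomas, cancer = [], [], None
    for les, ui in zip(active, u):
        sens = colo.sensitivity_for(les, age)
        if sens <= 0 or ui >= sens:
            continue
        detected.append(les)
        state = les.state(age)
        if state in ("early_adenoma", "advanced_adenoma"):
            removed_adenomas.append(les)
        elif state == "preclinical_cancer":
            if cancer is None or les.clinical_age < cancer.clinical_age:
                cancer = les
    return detected, removed_adenomas, cancer


# ---------------------------------------------------------------------
# Per-person program replay
# ---------------------------------------------------------------------

P_COLONOSCOPY_DEATH = 3.4e-5  # per procedure; derived default (methods note)


@dataclass
class ScreeningLedger:
    """Per-person account of one screening scenario."""

    offers: list = field(default_factory=list)
    tests_taken: list = field(default_factory=list)
    true_positives: int = 0
    false_positives: int = 0
    colonoscopies: list = field(default_factory=list)  # (age, indication)
    adenomas_removed: int = 0
    screen_detected_cancer: bool = False
    lockout_until: float = -INF
    complication_death: bool = False

    def n_colonoscopies(self, indication=None) -> int:
        if indication is None:
            return len(self.colonoscopies)
        return sum(1 for _, ind in self.colonoscopies if ind == indication)


@dataclass
class ScenarioOutcome:
    """Final state of one person under one scenario."""

    death_age: float
    death_cause: str              # "other" | "crc" | "colonoscopy"
    dx_age: float | None = None
    dx_stage: str | None = None
    dx_mode: str | None = None    # "symptomatic" | "screen" | "surveillance"


def _age_key(age: float) -> int:
    return int(round(age * 64))


def run_screening_program(history: PersonHistory, strategy: StrategySpec | None,
                          params: NHParams, cohort_seed: int,
                          profile_specs=None, colo: TestSpec = COLONOSCOPY,
                          surv_config: SurveillanceConfig = DEFAULT_SURVEILLANCE,
                          p_col_death: float = P_COLONOSCOPY_DEATH,
                          allow_complications: bool = True,
                          _tables=None):
    """Replay one person's life under a screening strategy (or none).

    The natural-history stream is never consumed here; all screening
    randomness comes from keyed participation/test/colonoscopy/
    complication substreams, so the same offer age draws the same deviate
    under every strategy.  Returns (ScreeningLedger, ScenarioOutcome).
    """
    pid = history.person_id
    lesions = history.lesions
    horizon = min(history.other_cause_death_age, float(MAX_AGE))
    tables = _tables or params._tables()
    cum_sympt, cum_screen = tables["cum_sympt"], tables["cum_screen"]
    rates = params.survival_rate

    if strategy is not None:
        spec = get_test_spec(strategy.test, strategy.participation_profile)
        offers = strategy.offer_ages()
    else:
        spec, offers = None, []

    ledger = ScreeningLedger()
    removed: set = set()
    offer_idx = 0
    surv_next: float | None = None
    surv_clean = 0
    dx = None            # (age, stage, mode)
    crc_death = INF
    death_age, cause = horizon, "other"

    def next_symptomatic():
        best = INF
        for les in lesions:
            if les.id not in removed and les.clinical_age < best:
                best = les.clinical_age
        return best

    def complication(age) -> bool:
        nonlocal death_age, cause
        if allow_complications and \
                u01(cohort_seed, pid, COMPLIC, _age_key(age)) < p_col_death:
            ledger.complication_death = True
            death_age, cause = age, "colonoscopy"
            return True
        return False

    def do_colonoscopy(age, indication):
        """Full exam with polypectomy; returns False on complication death."""
        nonlocal surv_next, surv_clean, dx, crc_death
        ledger.colonoscopies.append((age, indication))
        if complication(age):
            return False
        active = _active_lesions(lesions, age, removed)
        n_aden = 0
        any_adv = False
        cancer = None
        for les in active:
            sens = colo.sensitivity_for(les, age)
            if sens <= 0:
                continue
            if u01(cohort_seed, pid, COLO, _age_key(age), les.id + 1) >= sens:
                continue
            state = les.state(age)
            if state in ("early_adenoma", "advanced_adenoma"):
                removed.add(les.id)
                n_aden += 1
                any_adv |= state == "advanced_adenoma"
            elif state == "preclinical_cancer":
                if cancer is None or les.clinical_age < cancer.clinical_age:
                    cancer = les
        ledger.adenomas_removed += n_aden
        if cancer is not None and dx is None:
            mode = "surveillance" if indication == "surveillance" else "screen"
            stage = int(np.searchsorted(cum_screen, cancer.u_stage, side="right"))
            rate = rates[stage]
            # survival clocked from the counterfactual clinical onset, so
            # earlier detection never shortens life by lead time alone
            crc_death = cancer.clinical_age + \
                (cancer.surv_exp / rate if rate > 0 else INF)
            dx = (age, STAGES[stage], mode)
            ledger.screen_detected_cancer = True
        findings = {"n_adenomas": n_aden, "advanced": any_adv,
                    "cancer": cancer is not None,
                    "surveillance_exam": indication == "surveillance",
                    "consecutive_clean": surv_clean}
        enabled = strategy is not None and strategy.surveillance_enabled
        nxt = surveillance_schedule(findings, age, surv_config, enabled=enabled)
        clean = n_aden == 0 and cancer is None
        if clean and indication == "surveillance":
            surv_clean += 1
        elif not clean:
            surv_clean = 0
        if clean and indication == "diagnostic":
            # nothing to explain the positive test: suspend screening for
            # five years after this colonoscopy
            ledger.lockout_until = age + 5.0
        surv_next = nxt
        return True

    now = 0.0
    while True:
        t_sym = next_symptomatic() if dx is None else INF
        # next eligible routine offer (suspended during surveillance and
        # after any diagnosis; lockout skips offers rather than deferring,
        # and offers that fell inside a surveillance episode are gone)
        t_offer = INF
        if spec is not None and dx is None and surv_next is None:
            while offer_idx < len(offers) and (
                    offers[offer_idx] < ledger.lockout_until
                    or offers[offer_idx] <= now):
                offer_idx += 1
            if offer_idx < len(offers):
                t_offer = float(offers[offer_idx])
        t_surv = surv_next if surv_next is not None else INF
        t_event = min(t_sym, t_offer, t_surv)
        t_end = min(horizon, crc_death)
        if t_event >= t_end:
            break
        now = t_event

        if t_event == t_surv:
            surv_next = None
            if not do_colonoscopy(t_event, "surveillance"):
                break
        elif t_event == t_offer:
            a = offers[offer_idx]
            offer_idx += 1
            ledger.offers.append(a)
            if u01(cohort_seed, pid, PART, a, 0) >= spec.participation:
                continue
            ledger.tests_taken.append(a)
            active = _active_lesions(lesions, a, removed)
            result = _initial_test_core(
                active, a, spec, u01(cohort_seed, pid, TEST, a, 0),
                lambda les: u01(cohort_seed, pid, TEST, a, les.id + 1))
            if result == "negative":
                continue
            if result == "true_positive":
                ledger.true_positives += 1
            else:
                ledger.false_positives += 1
            if u01(cohort_seed, pid, PART, a, 1) >= spec.colonoscopy_compliance:
                continue
            if not do_colonoscopy(float(a), "diagnostic"):
                break
        else:  # symptomatic clinical cancer: diagnosis plus one diagnostic
            # work-up colonoscopy; no surveillance follows (both arms alike)
            les = min((l for l in lesions if l.id not in removed),
                      key=lambda l: l.clinical_age)
            stage = int(np.searchsorted(cum_sympt, les.u_stage, side="right"))
            rate = rates[stage]
            crc_death = t_sym + (les.surv_exp / rate if rate > 0 else INF)
            dx = (t_sym, STAGES[stage], "symptomatic")
            ledger.colonoscopies.append((t_sym, "symptomatic"))
            if complication(t_sym):
                break

    if cause != "colonoscopy":
        if crc_death < horizon:
            death_age, cause = crc_death, "crc"
        else:
            death_age, cause = horizon, "other"
    outcome = ScenarioOutcome(
        death_age=death_age, death_cause=cause,
        dx_age=dx[0] if dx else None, dx_stage=dx[1] if dx else None,
        dx_mode=dx[2] if dx else None)
    return ledger, outcome
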