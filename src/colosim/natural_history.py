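"""Per-person colorectal cancer natural history.

Two carcinogenesis pathways are simulated from birth to death:

* **Adenoma–carcinoma pathway** — lesions arise as early adenomas and may
  traverse early adenoma → advanced adenoma → preclinical cancer →
  clinical (symptomatic) cancer.  Each new lesion carries a latent
  *aggressive* flag: aggressive lesions progress along the full sequence
  with fast annual probabilities (mean dwell time from genesis to clinical
  cancer near 13 years), while indolent lesions may advance in size but
  never become cancer.  The split is what lets a single parameter set
  produce both a ~13-year dwell time and realistic adenoma-prevalence to
  incidence ratios.
* **Serrated pathway** — cancer arises directly as preclinical cancer
  without an adenomatous precursor; such lesions are invisible to
  endoscopy until they are cancers.

Time advances in annual cycles; lesion genesis and state transitions are
resolved per cycle in a fixed order (genesis, progression, symptomatic
transition, CRC death, other-cause death).  All randomness flows through
the person's ``natural_history`` substream with a consumption pattern
that does not depend on death age or on any screening intervention, so
the common-random-numbers contract holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .demography import MAX_AGE, Cohort, Person
from .streams import substream_seed

STAGES = ("I", "II", "III", "IV")
INF = math.inf


class NaturalHistoryError(ValueError):
    pass


@dataclass
class BandedRate:
    """An annual probability defined on age bands, with per-sex values."""

    edges: list          # k+1 integer edges, last one 101
    male: list           # k values
    female: list

    def expand(self, sex: str) -> np.ndarray:
        vals = self.male if sex == "male" else self.female
        out = np.zeros(MAX_AGE + 1)
        for lo, hi, v in zip(self.edges[:-1], self.edges[1:], vals):
            out[lo:hi] = v
        return out

    def scaled(self, factor, lo_age: int = 0, hi_age: int = MAX_AGE + 1,
               sexes=("male", "female")) -> "BandedRate":
        """Return a copy with values in [lo_age, hi_age) multiplied by factor."""
        new = {"male": list(self.male), "female": list(self.female)}
        for s in sexes:
            for i, (lo, hi) in enumerate(zip(self.edges[:-1], self.edges[1:])):
                if lo < hi_age and hi > lo_age:
                    new[s][i] = min(1.0, new[s][i] * factor)
        return BandedRate(edges=list(self.edges), male=new["male"],
                          female=new["female"])


@dataclass
class NHParams:
    """Natural-history parameter set (annual probabilities unless noted)."""

    adenoma_risk: BandedRate
    serrated_risk: BandedRate
    aggressive_fraction: float = 0.12
    p_early_to_advanced: float = 0.18        # aggressive lesions
    p_advanced_to_preclinical: float = 0.18  # aggressive lesions
    p_early_to_advanced_indolent: float = 0.015
    sojourn_mean: float = 4.5                # years, preclinical -> clinical
    p_growth: float = 0.12                   # small -> 6-9 mm per year
    rectal_fraction: float = 0.30
    stage_dist_symptomatic: tuple = (0.18, 0.27, 0.32, 0.23)
    stage_dist_screen: tuple = (0.45, 0.30, 0.17, 0.08)
    survival_rate: tuple = (0.005, 0.02, 0.08, 0.40)  # CRC death rate by stage
    min_genesis_age: int = 20

    def __post_init__(self):
        self.validate()

    def validate(self):
        for name in ("aggressive_fraction", "p_early_to_advanced",
                     "p_advanced_to_preclinical", "p_early_to_advanced_indolent",
                     "p_growth", "rectal_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise NaturalHistoryError(f"{name}={v} outside [0, 1]")
        if self.sojourn_mean <= 0:
            raise NaturalHistoryError("sojourn_mean must be positive")
        for name in ("stage_dist_symptomatic", "stage_dist_screen"):
            d = np.asarray(getattr(self, name), dtype=float)
            if d.shape != (4,) or np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
                raise NaturalHistoryError(f"{name} must be a distribution over 4 stages")
        cs, cy = (np.cumsum(self.stage_dist_screen),
                  np.cumsum(self.stage_dist_symptomatic))
        if np.any(cs < cy - 1e-12):
            raise NaturalHistoryError(
                "screen-detected stage distribution must be stochastically "
                "earlier than the symptomatic one")
        if np.any(np.asarray(self.survival_rate) < 0):
            raise NaturalHistoryError("survival rates must be non-negative")

    # caches used by the simulation loop -------------------------------
    def _tables(self):
        return {
            "risk": {s: self.adenoma_risk.expand(s) for s in ("male", "female")},
            "serrated": {s: self.serrated_risk.expand(s) for s in ("male", "female")},
            "cum_sympt": np.cumsum(self.stage_dist_symptomatic),
            "cum_screen": np.cumsum(self.stage_dist_screen),
        }

    # --- YAML round trip ----------------------------------------------

    def to_dict(self) -> dict:
        d = {}
        for name in ("aggressive_fraction", "p_early_to_advanced",
                     "p_advanced_to_preclinical", "p_early_to_advanced_indolent",
                     "sojourn_mean", "p_growth", "rectal_fraction",
                     "min_genesis_age"):
            d[name] = getattr(self, name)
        for name in ("stage_dist_symptomatic", "stage_dist_screen", "survival_rate"):
            d[name] = [float(x) for x in getattr(self, name)]
        for name in ("adenoma_risk", "serrated_risk"):
            br = getattr(self, name)
            d[name] = {"edges": [int(e) for e in br.edges],
                       "male": [float(x) for x in br.male],
                       "female": [float(x) for x in br.female]}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NHParams":
        d = dict(d)
        for name in ("adenoma_risk", "serrated_risk"):
            d[name] = BandedRate(**d[name])
        for name in ("stage_dist_symptomatic", "stage_dist_screen", "survival_rate"):
            d[name] = tuple(d[name])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "NHParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_params() -> NHParams:
    """Uncalibrated starting parameter set (see docs/methods.md)."""
    edges = [0, 20, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 101]
    risk_m = [0, 0.0010, 0.0020, 0.0040, 0.0050, 0.0065, 0.0080,
              0.0090, 0.0100, 0.0100, 0.0100, 0.0090]
    risk_f = [v * 0.80 for v in risk_m]
    ser_m = [0, 0.0, 1e-5, 2e-5, 4e-5, 6e-5, 1e-4, 1.5e-4,
             2e-4, 2.5e-4, 3e-4, 3e-4]
    ser_f = [v * 0.85 for v in ser_m]
    return NHParams(
        adenoma_risk=BandedRate(edges=edges, male=risk_m, female=risk_f),
        serrated_risk=BandedRate(edges=edges, male=ser_m, female=ser_f),
    )


# ---------------------------------------------------------------------
# Lesions and person histories
# ---------------------------------------------------------------------

@dataclass(slots=True)
class Lesion:
    """One lesion with its full (counterfactual) state timeline.

    Ages are absolute; ``inf`` marks transitions that never happen.  The
    timeline is drawn once at simulation time and is independent of death
    age and of any screening, so every scenario replays the same lesion.
    """

    id: int
    pathway: str           # "adenoma_carcinoma" | "serrated"
    site: str              # "rectum" | "colon"
    aggressive: bool
    genesis_age: float
    growth_age: float      # becomes 6-9 mm (advanced lesions are >=10 mm)
    advanced_age: float
    preclinical_age: float
    clinical_age: float
    u_stage: float         # shared stage deviate (symptomatic vs screen CDF)
    surv_exp: float        # standard-exponential survival deviate
    removed_age: float = INF

    def state(self, age: float) -> str:
        if age >= self.removed_age:
            return "removed"
        if age < self.genesis_age:
            return "absent"
        if age >= self.clinical_age:
            return "clinical_cancer"
        if age >= self.preclinical_age:
            return "preclinical_cancer"
        if age >= self.advanced_age:
            return "advanced_adenoma"
        return "early_adenoma"

    def size_class(self, age: float) -> str:
        if age >= self.advanced_age:
            return "large"
        return "medium" if age >= self.growth_age else "small"

    @property
    def state_entry_ages(self) -> dict:
        out = {"early_adenoma": self.genesis_age} if \
            self.pathway == "adenoma_carcinoma" else {}
        for name, a in (("advanced_adenoma", self.advanced_age),
                        ("preclinical_cancer", self.preclinical_age),
                        ("clinical_cancer", self.clinical_age)):
            if math.isfinite(a):
                out[name] = a
        return out


@dataclass(slots=True)
class PersonHistory:
    """Event timeline of one person in the absence of screening."""

    person_id: int
    sex: str
    other_cause_death_age: float
    lesions: list
    crc_diagnosis: tuple | None   # (age, stage, mode)
    death: tuple                  # (age, cause)

    @property
    def diagnosed_lesion(self) -> Lesion | None:
        if self.crc_diagnosis is None:
            return None
        age = self.crc_diagnosis[0]
        for les in self.lesions:
            if les.clinical_age == age:
                return les
        return None


def _geom(u: float, p: float) -> float:
    """Inverse-CDF geometric waiting time on {1, 2, ...}; inf when p <= 0."""
    if p <= 0.0:
        return INF
    if p >= 1.0:
        return 1.0
    return math.ceil(math.log1p(-u) / math.log1p(-p))


def _draw_lesions(pid: int, sex: str, params: NHParams, cohort_seed: int,
                  tables) -> list:
    """Draw the full lesion timeline for one person.

    The ``natural_history`` substream is consumed in a fixed pattern
    (a 101x2 genesis block, then 8 deviates per adenoma and 4 per serrated
    lesion), so consumption never depends on the scenario.
    """
    rng = np.random.default_rng(substream_seed(cohort_seed, pid, "natural_history"))
    U = rng.random((MAX_AGE + 1, 2))
    risk = tables["risk"][sex]
    ser = tables["serrated"][sex]
    lo = params.min_genesis_age
    aden_ages = np.nonzero(U[:MAX_AGE, 0] < risk[:MAX_AGE])[0]
    ser_ages = np.nonzero(U[:MAX_AGE, 1] < ser[:MAX_AGE])[0]
    aden_ages = aden_ages[aden_ages >= lo]
    ser_ages = ser_ages[ser_ages >= lo]

    lesions = []
    for a in aden_ages:
        v = rng.random(8)
        aggressive = v[0] < params.aggressive_fraction
        if aggressive:
            t1 = _geom(v[1], params.p_early_to_advanced)
            t2 = _geom(v[2], params.p_advanced_to_preclinical)
        else:
            t1 = _geom(v[1], params.p_early_to_advanced_indolent)
            t2 = INF
        adv = a + t1
        preclin = adv + t2
        clin = preclin - params.sojourn_mean * math.log1p(-v[3])
        lesions.append(Lesion(
            id=len(lesions), pathway="adenoma_carcinoma",
            site="rectum" if v[5] < params.rectal_fraction else "colon",
            aggressive=bool(aggressive), genesis_age=float(a),
            growth_age=a + _geom(v[4], params.p_growth),
            advanced_age=adv, preclinical_age=preclin, clinical_age=clin,
            u_stage=v[6], surv_exp=-math.log1p(-v[7])))
    for a in ser_ages:
        v = rng.random(4)
        clin = a - params.sojourn_mean * math.log1p(-v[0])
        lesions.append(Lesion(
            id=len(lesions), pathway="serrated",
            site="rectum" if v[1] < params.rectal_fraction else "colon",
            aggressive=True, genesis_age=float(a), growth_age=INF,
            advanced_age=INF, preclinical_age=float(a), clinical_age=clin,
            u_stage=v[2], surv_exp=-math.log1p(-v[3])))
    return lesions


def _stage_index(u: float, cum: np.ndarray) -> int:
    return int(np.searchsorted(cum, u, side="right"))


def natural_course(lesions, other_death: float, params: NHParams,
                   cum_sympt: np.ndarray) -> tuple:
    """No-screening outcome: (crc_diagnosis or None, (death_age, cause)).

    The first lesion to reach clinical cancer before death is diagnosed
    symptomatically; later lesions are ignored (no second primaries).
    Ties between CRC and other-cause death resolve to the earlier real
    event time; exact ties count as other-cause.
    """
    horizon = min(other_death, float(MAX_AGE))
    dx_les = None
    for les in lesions:
        if les.clinical_age < horizon and (
                dx_les is None or les.clinical_age < dx_les.clinical_age):
            dx_les = les
    if dx_les is None:
        return None, (horizon, "other")
    stage = _stage_index(dx_les.u_stage, cum_sympt)
    rate = params.survival_rate[stage]
    crc_death = dx_les.clinical_age + (dx_les.surv_exp / rate if rate > 0 else INF)
    dx = (dx_les.clinical_age, STAGES[stage], "symptomatic")
    if crc_death < horizon:
        return dx, (crc_death, "crc")
    return dx, (horizon, "other")


def simulate_history(person: Person, params: NHParams, _tables=None) -> PersonHistory:
    """Simulate one person's CRC natural history (no screening)."""
    tables = _tables or params._tables()
    lesions = _draw_lesions(person.id, person.sex, params, person.cohort_seed,
                            tables)
    dx, death = natural_course(lesions, person.other_cause_death_age, params,
                               tables["cum_sympt"])
    return PersonHistory(person_id=person.id, sex=person.sex,
                         other_cause_death_age=person.other_cause_death_age,
                         lesions=lesions, crc_diagnosis=dx, death=death)


def simulate_cohort(cohort: Cohort, params: NHParams) -> list:
    """Simulate natural histories for a whole cohort (list of PersonHistory)."""
    tables = params._tables()
    seed = cohort.seed
    out = []
    sexes = cohort.sex
    deaths = cohort.other_cause_death_age
    cum_sympt = tables["cum_sympt"]
    for pid in range(cohort.size):
        sex = str(sexes[pid])
        lesions = _draw_lesions(pid, sex, params, seed, tables)
        dx, death = natural_course(lesions, float(deaths[pid]), params, cum_sympt)
        out.append(PersonHistory(person_id=pid, sex=sex,
                                 other_cause_death_age=float(deaths[pid]),
                                 lesions=lesions, crc_diagnosis=dx, death=death))
    return out


# ---------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------

PREVALENCE_BANDS = [(40, 45), (45, 50), (50, 55), (55, 60),
                    (60, 65), (65, 70), (70, 75), (75, 80)]
RATE_BANDS = [(30, 35), (35, 40), (40, 45), (45, 50), (50, 55), (55, 60),
              (60, 65), (65, 70), (70, 75), (75, 80), (80, 85), (85, 90),
              (90, 101)]


def summarize_history(histories, prevalence_bands=None, rate_bands=None):
    """Age/sex summaries of a simulated cohort (no-screening course).

    Returns a tidy DataFrame with columns (metric, sex, age_lo, age_hi,
    value): early/advanced adenoma prevalence (% of persons alive at the
    band midpoint), CRC incidence and mortality (per 100,000 person-years)
    and the overall rectal fraction of diagnosed cancers.
    """
    import pandas as pd

    if not histories:
        raise ValueError("summarize_history requires at least one history")
    prevalence_bands = prevalence_bands or PREVALENCE_BANDS
    rate_bands = rate_bands or RATE_BANDS

    n = len(histories)
    sex = np.array([h.sex for h in histories])
    death = np.array([h.death[0] for h in histories])
    crc_death = np.array([h.death[0] if h.death[1] == "crc" else np.nan
                          for h in histories])
    dx_age = np.array([h.crc_diagnosis[0] if h.crc_diagnosis else np.nan
                       for h in histories])

    rows = []
    # prevalence at band midpoints among the alive
    for lo, hi in prevalence_bands:
        mid = (lo + hi) / 2.0
        for s in ("male", "female"):
            sel = (sex == s) & (death > mid)
            alive_idx = np.nonzero(sel)[0]
            n_alive = len(alive_idx)
            n_early = n_adv = 0
            for i in alive_idx:
                early = adv = False
                for les in histories[i].lesions:
                    if les.pathway != "adenoma_carcinoma":
                        continue
                    st = les.state(mid)
                    early |= st == "early_adenoma"
                    adv |= st == "advanced_adenoma"
                n_early += early
                n_adv += adv
            for metric, cnt in (("early_adenoma_prevalence", n_early),
                                ("advanced_adenoma_prevalence", n_adv)):
                rows.append((metric, s, lo, hi,
                             100.0 * cnt / n_alive if n_alive else 0.0))
    # incidence / mortality per 100k person-years
    for lo, hi in rate_bands:
        py_all = np.clip(np.minimum(death, hi) - lo, 0.0, None)
        for s in ("male", "female"):
            sel = sex == s
            py = float(py_all[sel].sum())
            inc = int(np.nansum((dx_age[sel] >= lo) & (dx_age[sel] < hi)))
            mort = int(np.nansum((crc_death[sel] >= lo) & (crc_death[sel] < hi)))
            rows.append(("crc_incidence", s, lo, hi,
                         1e5 * inc / py if py > 0 else 0.0))
            rows.append(("crc_mortality", s, lo, hi,
                         1e5 * mort / py if py > 0 else 0.0))
    # rectal fraction among diagnosed cancers
    n_dx = n_rect = 0
    for h in histories:
        les = h.diagnosed_lesion
        if les is not None:
            n_dx += 1
            n_rect += les.site == "rectum"
    rows.append(("rectal_fraction", "all", 0, MAX_AGE + 1,
                 n_rect / n_dx if n_dx else 0.0))
    return pd.DataFrame(rows, columns=["metric", "sex", "age_lo", "age_hi",
                                       "value"])


def lifetime_rates(histories) -> dict:
    """Lifetime CRC incidence and mortality per 1000 persons."""
    n = len(histories)
    cases = sum(1 for h in histories if h.crc_diagnosis is not None)
    deaths = sum(1 for h in histories if h.death[1] == "crc")
    return {"incidence_per_1000": 1000.0 * cases / n,
            "mortality_per_1000": 1000.0 * deaths / n}


def empirical_dwell_time(histories, min_cancers: int = 30) -> float:
    """Mean years from adenoma genesis to clinical cancer among
    adenoma-carcinoma-pathway cancers."""
    dwells = []
    for h in histories:
        les = h.diagnosed_lesion
        if les is not None and les.pathway == "adenoma_carcinoma":
            dwells.append(les.clinical_age - les.genesis_age)
    if len(dwells) < min_cancers:
        raise NaturalHistoryError(
            f"only {len(dwells)} adenoma-carcinoma cancers; "
            f"need at least {min_cancers}")
    return float(np.mean(dwells))


def export_event_log(histories, path) -> None:
    """Tidy per-event CSV (person_id, age, event, detail)."""
    import pandas as pd

    rows = []
    for h in histories:
        for les in h.lesions:
            for state, age in les.state_entry_ages.items():
                rows.append((h.person_id, age, state,
                             f"lesion={les.id};pathway={les.pathway};site={les.site}"))
        if h.crc_diagnosis:
            age, stage, mode = h.crc_diagnosis
            rows.append((h.person_id, age, "crc_diagnosis",
                         f"stage={stage};mode={mode}"))
        rows.append((h.person_id, h.death[0], "death", f"cause={h.death[1]}"))
    df = pd.DataFrame(rows, columns=["person_id", "age", "event", "detail"])
    df.sort_values(["person_id", "age"]).to_csv(path, index=False)
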