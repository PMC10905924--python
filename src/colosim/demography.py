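"""Life tables, cohort construction, and other-cause mortality sampling.

The life table supplies annual probabilities of death from causes other
than colorectal cancer (CRC deaths are simulated separately by the
natural-history module).  Feeding an all-cause table in slightly
double-counts CRC mortality — a small bias shared with common
microsimulation practice, documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .streams import STREAMS, u01, u01_array, substream_seed

MAX_AGE = 100


class LifeTableError(ValueError):
    pass


@dataclass
class LifeTable:
    """Annual other-cause death probabilities on integer ages 0..100.

    ``qx`` is the sex-averaged column; ``qx_male``/``qx_female`` are
    optional sex-specific columns (both present or both absent).
    The age-100 probability is an absorbing cap of 1.
    """

    qx: np.ndarray
    qx_male: np.ndarray | None = None
    qx_female: np.ndarray | None = None

    def __post_init__(self):
        self.qx = np.asarray(self.qx, dtype=float)
        for name in ("qx_male", "qx_female"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if (self.qx_male is None) != (self.qx_female is None):
            raise LifeTableError("sex-specific columns must come in pairs")
        self.validate()

    def validate(self) -> None:
        for name in ("qx", "qx_male", "qx_female"):
            v = getattr(self, name)
            if v is None:
                continue
            if v.shape != (MAX_AGE + 1,):
                raise LifeTableError(f"{name} must cover ages 0..{MAX_AGE}")
            if np.any(~np.isfinite(v)) or np.any(v < 0) or np.any(v > 1):
                raise LifeTableError(f"{name} must lie in [0, 1]")
            if v[MAX_AGE] != 1.0:
                raise LifeTableError(f"{name} must equal 1 at age {MAX_AGE}")

    def column(self, sex: str | None = None) -> np.ndarray:
        if sex is None or self.qx_male is None:
            return self.qx
        return self.qx_male if sex == "male" else self.qx_female

    def survival(self, sex: str | None = None) -> np.ndarray:
        """S[a] = P(alive at exact age a), S[0] = 1, length 102."""
        q = self.column(sex)
        s = np.empty(MAX_AGE + 2)
        s[0] = 1.0
        np.cumprod(1.0 - q, out=s[1:])
        return s

    def life_expectancy(self, sex: str | None = None) -> float:
        """Mean age at death with deaths uniform within each year."""
        s = self.survival(sex)
        deaths = s[:-1] - s[1:]
        return float(np.sum(deaths * (np.arange(MAX_AGE + 1) + 0.5)))

    # --- I/O ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        d = {"age": np.arange(MAX_AGE + 1), "qx": self.qx}
        if self.qx_male is not None:
            d["qx_male"] = self.qx_male
            d["qx_female"] = self.qx_female
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        # %.17g keeps the round trip bit-exact for float64
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip").sort_values("age")
        kw = {}
        if "qx_male" in df.columns:
            kw = {"qx_male": df["qx_male"].to_numpy(),
                  "qx_female": df["qx_female"].to_numpy()}
        return cls(qx=df["qx"].to_numpy(), **kw)


def sample_other_cause_death_age(life_table: LifeTable, u: float,
                                 sex: str | None = None) -> float:
    """Invert the other-cause survival curve at ``u`` ∈ (0,1).

    Returns the age at which cumulative survival first drops below ``u``,
    with the within-year position interpolated from the same deviate
    (equivalent in law to a uniform placement, and deterministic given u).
    """
    if not (0.0 < u < 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    s = life_table.survival(sex)
    return _invert_survival(s, np.asarray([u]))[0]


def _invert_survival(s: np.ndarray, u: np.ndarray) -> np.ndarray:
    # s is decreasing from 1 to 0 over length 102; death year k satisfies
    # s[k] >= u > s[k+1]
    k = np.searchsorted(-s, -u, side="right") - 1
    k = np.clip(k, 0, MAX_AGE)
    denom = s[k] - s[k + 1]
    frac = np.where(denom > 0, (s[k] - u) / np.where(denom > 0, denom, 1.0), 0.5)
    return k + np.clip(frac, 0.0, 1.0)


@dataclass
class Person:
    """One simulated individual with named, independent RNG substreams."""

    id: int
    sex: str
    cohort_seed: int
    other_cause_death_age: float
    stream_seeds: dict = field(default_factory=dict)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(self.stream_seeds[stream])


@dataclass
class Cohort:
    """A fixed population shared (via CRN) by every scenario under study."""

    seed: int
    sex: np.ndarray            # array of "male"/"female"
    other_cause_death_age: np.ndarray
    life_table: LifeTable

    @property
    def size(self) -> int:
        return len(self.sex)

    @property
    def male_fraction(self) -> float:
        return float(np.mean(self.sex == "male"))

    def person(self, i: int) -> Person:
        seeds = {name: substream_seed(self.seed, i, name) for name in STREAMS}
        return Person(id=i, sex=str(self.sex[i]), cohort_seed=self.seed,
                      other_cause_death_age=float(self.other_cause_death_age[i]),
                      stream_seeds=seeds)

    @property
    def persons(self):
        return [self.person(i) for i in range(self.size)]


def make_cohort(n: int, male_fraction: float = 0.5, seed: int = 0,
                life_table: LifeTable | None = None) -> Cohort:
    """Build a CRN cohort: sex and other-cause death age per person.

    Deterministic given ``seed``; draws are keyed per person so the same
    cohort is reproduced regardless of ``n`` ordering or later additions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if life_table is None:
        from .datasets import load_life_table
        life_table = load_life_table()
    ids = np.arange(n)
    u_sex = u01_array((seed, STREAMS["sex"]), ids)
    sex = np.where(u_sex < male_fraction, "male", "female")
    u_death = u01_array((seed, STREAMS["mortality"]), ids)
    death = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        if m.any():
            death[m] = _invert_survival(life_table.survival(s), u_death[m])
    return Cohort(seed=seed, sex=sex, other_cause_death_age=death,
                  life_table=life_table)
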