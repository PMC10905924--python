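"""Synthetic external inputs: life table, benchmark curves, ground truth.

Real calibration targets for this kind of model come from registries and
colonoscopy series.  To keep every stage testable without external data,
this module generates a *china-2020-like* parametric stand-in: a
Gompertz–Makeham life table scaled to a target life expectancy, and
smooth age/sex benchmark curves (adenoma prevalence, CRC incidence and
mortality, rectal fraction) whose life-table-weighted lifetime risk hits
a configured target.  The shipped defaults aim at a lifetime CRC risk of
4.6% and e0 = 78 y; they are synthetic look-alikes, not registry values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import BenchmarkSet
from .demography import MAX_AGE, LifeTable
from .natural_history import (NHParams, PREVALENCE_BANDS, RATE_BANDS,
                              default_params, simulate_cohort,
                              summarize_history)


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic input generator (all defaults documented
    in docs/methods.md)."""

    # life table: hazard = scale * (makeham_c + gompertz_a * exp(gompertz_b * age))
    gompertz_a: float = 3e-5
    gompertz_b: float = 0.105
    makeham_c: float = 5e-4
    target_e0: float | None = 78.0
    sex_gap_years: float = 5.0        # female minus male life expectancy

    # early-adenoma prevalence: logistic in age
    adenoma_asymptote: float = 0.40   # proportion, not %
    adenoma_midpoint_age: float = 66.0
    adenoma_slope: float = 0.055
    prevalence_sex_mult: tuple = (1.2, 0.8)   # (male, female)

    # advanced adenomas accumulate: cumulative early-curve shape, pinned
    # to a target prevalence level in the 60-65 band
    advanced_level: float = 0.07      # proportion at ages 60-65 (sex-avg)
    advanced_pin_age: float = 62.5

    # cancer: incidence follows the lesion-genesis rate (the derivative of
    # the prevalence curve plus pool turnover), lagged by the dwell time
    # and scaled to a lifetime-risk target
    incidence_lag: float = 12.0
    incidence_leak: float = 0.04      # adenoma-pool turnover per year
    lifetime_risk: float = 0.046
    incidence_sex_mult: tuple = (1.2, 0.8)
    mortality_lag: float = 7.0        # years after incidence
    lifetime_mortality: float = 0.017
    genesis_start_age: float = 20.0

    rectal_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lifetime_risk < 0.2):
            raise SyntheticError("lifetime_risk must lie in (0, 0.2)")
        if self.target_e0 is not None and not (60.0 < self.target_e0 < 90.0):
            raise SyntheticError("target_e0 must lie in (60, 90)")


# ---------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------

def _qx_from_hazard(h: np.ndarray) -> np.ndarray:
    q = 1.0 - np.exp(-h)
    q[MAX_AGE] = 1.0
    return q


def _e0_of_scale(cfg: SyntheticConfig, scale: float) -> float:
    ages = np.arange(MAX_AGE + 1)
    h = scale * (cfg.makeham_c + cfg.gompertz_a * np.exp(cfg.gompertz_b * ages))
    return LifeTable(qx=_qx_from_hazard(h)).life_expectancy()


def _scale_for_e0(cfg: SyntheticConfig, target: float) -> float:
    lo, hi = 1e-3, 1e3
    if not (_e0_of_scale(cfg, hi) <= target <= _e0_of_scale(cfg, lo)):
        raise SyntheticError(f"target e0={target} unattainable for this hazard")
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if _e0_of_scale(cfg, mid) > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def make_life_table(config: SyntheticConfig | None = None) -> LifeTable:
    """Gompertz–Makeham life table; hazard scaled so that e0 matches the
    target within 0.2 y (bisection), with sex-specific columns offset by
    half the configured sex gap.  ``target_e0=None`` skips the scaling."""
    cfg = config or SyntheticConfig()
    ages = np.arange(MAX_AGE + 1)
    base = cfg.makeham_c + cfg.gompertz_a * np.exp(cfg.gompertz_b * ages)

    def table_for(target):
        s = _scale_for_e0(cfg, target) if target is not None else 1.0
        return _qx_from_hazard(s * base)

    qx = table_for(cfg.target_e0)
    if cfg.target_e0 is None:
        return LifeTable(qx=qx)
    half = cfg.sex_gap_years / 2.0
    return LifeTable(qx=qx,
                     qx_male=table_for(cfg.target_e0 - half),
                     qx_female=table_for(cfg.target_e0 + half))


# ---------------------------------------------------------------------
# Benchmark curves
# ---------------------------------------------------------------------

def _logistic(age, cfg: SyntheticConfig):
    return cfg.adenoma_asymptote / (
        1.0 + np.exp(-cfg.adenoma_slope * (np.asarray(age, float)
                                           - cfg.adenoma_midpoint_age)))


def _lifetime_weighted(rate_by_age: np.ndarray, survival: np.ndarray) -> float:
    """Life-table-weighted cumulative risk of an age-specific annual rate."""
    return float(np.sum(survival[:-1] * rate_by_age))


def make_benchmarks(config: SyntheticConfig | None = None,
                    life_table: LifeTable | None = None) -> BenchmarkSet:
    """Benchmark curves on the standard age bands.

    Early-adenoma prevalence is logistic in age; advanced prevalence is a
    scaled, lagged copy; incidence uses the lagged early-curve shape with
    its level chosen so the life-table-weighted lifetime risk equals the
    configured target (and likewise for mortality).
    """
    cfg = config or SyntheticConfig()
    lt = life_table or make_life_table(cfg)
    ages = np.arange(MAX_AGE + 1, dtype=float)
    rows = []

    # advanced prevalence rises faster than early prevalence because the
    # advanced pool accumulates; use the early curve integrated from the
    # genesis start age, pinned to the configured level at the pin age
    early_curve = _logistic(ages, cfg)
    early_curve = np.where(ages >= cfg.genesis_start_age, early_curve, 0.0)
    cum_early = np.concatenate([[0.0], np.cumsum(early_curve)])
    adv_scale = cfg.advanced_level / np.interp(cfg.advanced_pin_age,
                                               np.arange(MAX_AGE + 2), cum_early)
    for sex, pm in zip(("male", "female"), cfg.prevalence_sex_mult):
        for lo, hi in PREVALENCE_BANDS:
            mid = (lo + hi) / 2.0
            early = float(_logistic(mid, cfg)) * pm
            adv = float(np.interp(mid, np.arange(MAX_AGE + 2), cum_early)) \
                * adv_scale * pm
            rows.append(("early_adenoma_prevalence", sex, lo, hi, 100.0 * early))
            rows.append(("advanced_adenoma_prevalence", sex, lo, hi, 100.0 * adv))

    # incidence shape: genesis rate (prevalence derivative + pool turnover)
    # lagged by the dwell time; scaled to the configured lifetime risk
    def genesis_shape(lag):
        a = ages - lag
        p = _logistic(a, cfg)
        dp = p * cfg.adenoma_slope * (1.0 - p / cfg.adenoma_asymptote)
        shape = dp + cfg.incidence_leak * p
        return np.where(a >= cfg.genesis_start_age, shape, 0.0)

    def scaled_rates(shape, lifetime_target, sex_mult):
        per_sex_lt = {}
        for sex, m in zip(("male", "female"), sex_mult):
            per_sex_lt[sex] = _lifetime_weighted(shape * m, lt.survival(sex))
        mean_lt = 0.5 * (per_sex_lt["male"] + per_sex_lt["female"])
        k = lifetime_target / mean_lt
        return {sex: shape * m * k
                for sex, m in zip(("male", "female"), sex_mult)}

    inc = scaled_rates(genesis_shape(cfg.incidence_lag), cfg.lifetime_risk,
                       cfg.incidence_sex_mult)
    mort = scaled_rates(genesis_shape(cfg.incidence_lag + cfg.mortality_lag),
                        cfg.lifetime_mortality, cfg.incidence_sex_mult)
    for sex in ("male", "female"):
        surv = lt.survival(sex)[:-1]
        for lo, hi in RATE_BANDS:
            sl = slice(lo, hi)
            w = surv[sl]
            rows.append(("crc_incidence", sex, lo, hi,
                         1e5 * float(np.average(inc[sex][sl], weights=w))))
            rows.append(("crc_mortality", sex, lo, hi,
                         1e5 * float(np.average(mort[sex][sl], weights=w))))
    rows.append(("rectal_fraction", "all", 0, MAX_AGE + 1, cfg.rectal_fraction))
    bm = BenchmarkSet(pd.DataFrame(
        rows, columns=["metric", "sex", "age_lo", "age_hi", "value"]))
    # banding loses a little mass at the band edges: rescale so that the
    # life-table integration of the banded curves hits the targets exactly
    for metric, target in (("crc_incidence", cfg.lifetime_risk),
                           ("crc_mortality", cfg.lifetime_mortality)):
        got = lifetime_risk_of(bm, lt, metric)
        if got > 0:
            bm.table.loc[bm.table["metric"] == metric, "value"] *= target / got
    return bm


def lifetime_risk_of(benchmarks: BenchmarkSet, life_table: LifeTable,
                     metric: str = "crc_incidence") -> float:
    """Integrate banded benchmark rates against the life table (oracle for
    the lifetime-risk scaling)."""
    from .calibration import lifetime_integral
    return lifetime_integral(benchmarks, life_table, metric)


# ---------------------------------------------------------------------
# Ground truth for parameter-recovery experiments
# ---------------------------------------------------------------------

def make_ground_truth(seed: int = 0, n_sim: int = 30_000,
                      life_table: LifeTable | None = None):
    """Sample a valid parameter set and summarize a cohort simulated from
    it into a benchmark set; the pair supports calibration recovery tests."""
    from .demography import make_cohort

    rng = np.random.default_rng(seed)
    base = default_params()

    def jitter(sigma=0.2):
        return float(np.exp(rng.normal(0.0, sigma)))

    g = jitter()
    params = NHParams(
        adenoma_risk=base.adenoma_risk.scaled(g),
        serrated_risk=base.serrated_risk.scaled(jitter()),
        aggressive_fraction=min(0.9, base.aggressive_fraction * jitter()),
        p_early_to_advanced=base.p_early_to_advanced,
        p_advanced_to_preclinical=base.p_advanced_to_preclinical,
        p_early_to_advanced_indolent=min(
            0.5, base.p_early_to_advanced_indolent * jitter()),
        sojourn_mean=base.sojourn_mean,
        p_growth=base.p_growth,
        rectal_fraction=float(np.clip(base.rectal_fraction * jitter(0.1),
                                      0.05, 0.8)),
        stage_dist_symptomatic=base.stage_dist_symptomatic,
        stage_dist_screen=base.stage_dist_screen,
        survival_rate=tuple(r * jitter(0.15) for r in base.survival_rate),
    )
    lt = life_table or make_life_table()
    cohort = make_cohort(n_sim, 0.5, seed=seed + 1, life_table=lt)
    hist = simulate_cohort(cohort, params)
    summ = summarize_history(hist)
    summ = summ.rename(columns={"value": "value"})
    return params, BenchmarkSet(summ)
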