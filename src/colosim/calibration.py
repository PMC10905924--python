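"""Calibration of natural-history parameters to epidemiological benchmarks.

Targets are age/sex-specific early- and advanced-adenoma prevalence, CRC
incidence and mortality, and the rectal fraction of cancers.  A simulated
point *passes* when it lies within ±20% of its benchmark — the envelope
used to judge fit — and the search is a blockwise iterative proportional
fitting: each parameter block is nudged by (target/simulated)^damping
toward the benchmark it controls most directly.  This is robust with a
stochastic objective at moderate cohort sizes, where generic optimizers
struggle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .demography import MAX_AGE, LifeTable, make_cohort
from .natural_history import (NHParams, lifetime_rates, simulate_cohort,
                              summarize_history)

PASS_TOLERANCE = 0.20
KEY = ["metric", "sex", "age_lo", "age_hi"]


class CalibrationError(ValueError):
    pass


@dataclass
class BenchmarkSet:
    """Tidy benchmark table: (metric, sex, age_lo, age_hi, value).

    Metrics: early_adenoma_prevalence / advanced_adenoma_prevalence (%),
    crc_incidence / crc_mortality (per 100,000 person-years), and a single
    rectal_fraction row (proportion, sex="all").
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(KEY + ["value"]) - set(self.table.columns)
        if missing:
            raise CalibrationError(f"benchmark table missing columns {missing}")
        if (self.table["value"] < 0).any():
            raise CalibrationError("benchmark values must be non-negative")
        prev = self.table["metric"].str.contains("prevalence")
        if (self.table.loc[prev, "value"] > 100).any():
            raise CalibrationError("prevalence benchmarks must be <= 100%")

    def bands(self, metric: str):
        sub = self.table[self.table["metric"] == metric]
        return sorted({(int(lo), int(hi))
                       for lo, hi in zip(sub["age_lo"], sub["age_hi"])})

    @property
    def prevalence_bands(self):
        return self.bands("early_adenoma_prevalence")

    @property
    def rate_bands(self):
        return self.bands("crc_incidence")

    @property
    def rectal_fraction(self) -> float:
        sub = self.table[self.table["metric"] == "rectal_fraction"]
        return float(sub["value"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "BenchmarkSet":
        return cls(pd.read_csv(path, float_precision="round_trip"))


def score_fit(summaries: pd.DataFrame, benchmarks: BenchmarkSet,
              weights: dict | None = None, eps: float = 1e-6) -> float:
    """Weighted sum of squared log-ratios between simulated and target.

    Zero iff every simulated point equals its benchmark.  Raises when the
    age/sex grids do not line up, listing the missing cells.
    """
    merged = benchmarks.table.merge(
        summaries, on=KEY, how="left", suffixes=("_target", "_sim"))
    if merged["value_sim"].isna().any():
        missing = merged.loc[merged["value_sim"].isna(), KEY]
        raise CalibrationError(
            "summaries missing benchmark cells:\n" + missing.to_string(index=False))
    weights = weights or {}
    # floor each metric at a small fraction of its mean target so that
    # zero-valued cells contribute a bounded, not unbounded, penalty
    floors = merged.groupby("metric")["value_target"].mean() * 0.05
    total = 0.0
    for _, row in merged.iterrows():
        w = weights.get(row["metric"], 1.0)
        floor = max(float(floors[row["metric"]]), eps)
        t = max(row["value_target"], floor)
        s = max(row["value_sim"], floor)
        if row["value_target"] == row["value_sim"]:
            continue
        total += w * math.log(s / t) ** 2
    if not np.isfinite(total):
        raise CalibrationError("non-finite calibration score")
    return total


def make_report(summaries: pd.DataFrame, benchmarks: BenchmarkSet,
                iterations: int = 0) -> "CalibrationReport":
    merged = benchmarks.table.merge(summaries, on=KEY,
                                    suffixes=("_target", "_sim"))
    merged = merged.rename(columns={"value_target": "target",
                                    "value_sim": "simulated"})
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["ratio"] = merged["simulated"] / merged["target"]
    merged["passed"] = np.abs(merged["ratio"] - 1.0) <= PASS_TOLERANCE
    merged.loc[(merged["target"] == 0) & (merged["simulated"] == 0), "passed"] = True
    return CalibrationReport(points=merged, iterations=iterations)


@dataclass
class CalibrationReport:
    points: pd.DataFrame
    iterations: int

    @property
    def pass_fraction(self) -> float:
        return float(self.points["passed"].mean())

    @property
    def all_passed(self) -> bool:
        return bool(self.points["passed"].all())

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    def plot(self, path=None):
        """Calibration panel per metric/sex: simulated line, benchmark
        squares, pass/fail colouring (green inside the 20% envelope)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        metrics = [m for m in self.points["metric"].unique()
                   if m != "rectal_fraction"]
        fig, axes = plt.subplots(len(metrics), 2, figsize=(9, 2.6 * len(metrics)),
                                 squeeze=False)
        for i, metric in enumerate(metrics):
            for j, sex in enumerate(("male", "female")):
                ax = axes[i][j]
                sub = self.points[(self.points.metric == metric)
                                  & (self.points.sex == sex)]
                mid = (sub.age_lo + sub.age_hi) / 2.0
                ax.plot(mid, sub.simulated, "k-", lw=1, label="simulated")
                ax.plot(mid, sub.target, "s", color="tab:blue", ms=4,
                        label="benchmark")
                colors = np.where(sub.passed, "tab:green", "tab:red")
                ax.scatter(mid, sub.simulated, c=colors, s=18, zorder=3)
                ax.set_title(f"{metric} ({sex})", fontsize=8)
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def lifetime_integral(benchmarks: BenchmarkSet, life_table: LifeTable,
                      metric: str = "crc_incidence") -> float:
    """Life-table-weighted cumulative risk implied by a banded rate curve."""
    out = []
    for sex in ("male", "female"):
        surv = life_table.survival(sex)[:-1]
        rate = np.zeros(MAX_AGE + 1)
        sub = benchmarks.table[(benchmarks.table["metric"] == metric)
                               & (benchmarks.table["sex"] == sex)]
        for _, r in sub.iterrows():
            rate[int(r["age_lo"]):int(r["age_hi"])] = r["value"] / 1e5
        out.append(float(np.sum(surv * rate)))
    return 0.5 * (out[0] + out[1])


# ---------------------------------------------------------------------
# Blockwise proportional-fitting calibration
# ---------------------------------------------------------------------

def _cell_ratio(merged: pd.DataFrame, metric: str, sex: str,
                age: float | None = None) -> float:
    """target/simulated for the benchmark cell covering ``age`` (or pooled)."""
    sub = merged[(merged["metric"] == metric) & (merged["sex"] == sex)]
    if age is not None:
        hit = sub[(sub["age_lo"] <= age) & (age < sub["age_hi"])]
        if len(hit) == 0:  # outside the benchmark grid: use nearest band
            hit = sub.iloc[[int(np.argmin(np.abs(sub["age_lo"] - age)))]]
        sub = hit
    t, s = sub["target"].sum(), sub["simulated"].sum()
    if t <= 0:
        return 1.0
    return t / max(s, 0.05 * t)


def _mean_ratio(merged, metric) -> float:
    """Pooled target/simulated ratio.

    Rows are weighted by person-years when the caller attached a ``py``
    column, which turns the pooled rate ratio into an expected-count
    ratio — the quantity lifetime incidence and mortality respond to.
    """
    sub = merged[merged["metric"] == metric]
    w = sub["py"] if "py" in sub.columns else pd.Series(1.0, index=sub.index)
    w = w.fillna(1.0)
    t = float((sub["target"] * w).sum())
    s = float((sub["simulated"] * w).sum())
    if t <= 0:
        return 1.0
    return t / max(s, 0.05 * t)


def _damp(ratio: float, damping: float, cap: float = 4.0) -> float:
    return float(np.clip(ratio, 1.0 / cap, cap) ** damping)


def _update_params(params: NHParams, merged: pd.DataFrame,
                   damping: float) -> NHParams:
    """One proportional-fitting sweep over all parameter blocks."""
    # 1. adenoma genesis per sex and age band  <- early-adenoma prevalence
    risk = params.adenoma_risk
    new_vals = {"male": list(risk.male), "female": list(risk.female)}
    for s in ("male", "female"):
        for i, (lo, hi) in enumerate(zip(risk.edges[:-1], risk.edges[1:])):
            mid = (lo + hi) / 2.0
            r = _cell_ratio(merged, "early_adenoma_prevalence", s, mid)
            new_vals[s][i] = min(0.5, new_vals[s][i] * _damp(r, damping))
    new_risk = type(risk)(edges=list(risk.edges), male=new_vals["male"],
                          female=new_vals["female"])
    # 2. indolent advance probability  <- advanced-adenoma prevalence
    adv_factor = _damp(_mean_ratio(merged, "advanced_adenoma_prevalence"), damping)
    # 3. aggressive fraction and serrated rate  <- CRC incidence
    inc_factor = _damp(_mean_ratio(merged, "crc_incidence"), damping)
    # 4. stage-specific CRC death rates  <- CRC mortality (relative to incidence,
    #    so the survival block does not chase an incidence shortfall)
    # the death probability saturates in rate (advanced-stage cases die of
    # CRC almost regardless), so the rate step uses a stronger exponent
    inc_ratio = _mean_ratio(merged, "crc_incidence")
    mort_ratio = _mean_ratio(merged, "crc_mortality")
    surv_factor = _damp(mort_ratio / inc_ratio, min(1.0, 2.5 * damping))
    # 5. rectal fraction  <- set directly
    rect = merged.loc[merged["metric"] == "rectal_fraction", "target"]
    rectal = float(rect.iloc[0]) if len(rect) else params.rectal_fraction

    return replace(
        params,
        adenoma_risk=new_risk,
        p_early_to_advanced_indolent=min(
            0.5, params.p_early_to_advanced_indolent * adv_factor),
        aggressive_fraction=min(0.9, params.aggressive_fraction * inc_factor),
        serrated_risk=params.serrated_risk.scaled(inc_factor),
        survival_rate=tuple(min(r * surv_factor, 3.0)
                            for r in params.survival_rate),
        rectal_fraction=rectal,
    )


def calibrate(params0: NHParams, benchmarks: BenchmarkSet, budget: int = 8,
              n_sim: int = 100_000, seed: int = 0,
              life_table: LifeTable | None = None, damping: float = 0.5,
              weights: dict | None = None, polish: int = 4):
    """Tune natural-history parameters to the benchmark envelope.

    Runs up to ``budget`` simulate–compare–update sweeps on a fixed CRN
    cohort (so the objective is deterministic given ``seed``), then up to
    ``polish`` level-matching steps that adjust only the global incidence
    and survival scalars so the simulated lifetime CRC incidence and
    mortality equal the life-table integrals of the benchmark curves.
    Returns the resulting parameters with their report.  The life table
    is an input and is never modified.  Budget exhaustion returns the
    best parameters found rather than raising.
    """
    if budget < 1:
        raise CalibrationError("budget must be >= 1")
    if life_table is None:
        from .datasets import load_life_table
        life_table = load_life_table()
    cohort = make_cohort(n_sim, 0.5, seed, life_table)
    pb, rb = benchmarks.prevalence_bands, benchmarks.rate_bands

    # person-years per (sex, band) for expected-count pooling; the cohort,
    # hence the weights, are fixed across iterations
    death = cohort.other_cause_death_age
    py = {}
    for s in ("male", "female"):
        sel = cohort.sex == s
        for lo, hi in rb:
            py[(s, lo, hi)] = float(
                np.clip(np.minimum(death[sel], hi) - lo, 0.0, None).sum())

    def attach_py(points):
        points = points.copy()
        points["py"] = [py.get((r["sex"], r["age_lo"], r["age_hi"]), np.nan)
                        for _, r in points.iterrows()]
        return points

    def evaluate(params):
        hist = simulate_cohort(cohort, params)
        summ = summarize_history(hist, prevalence_bands=pb, rate_bands=rb)
        rep = make_report(summ, benchmarks)
        return score_fit(summ, benchmarks, weights=weights), rep, lifetime_rates(hist)

    params = params0
    score, report, rates = evaluate(params0)
    best = (params0, score, report, rates)
    accepted_scores = [score]
    iterations = 0
    for it in range(1, budget + 1):
        iterations = it
        if report.all_passed:
            best = (params, score, report, rates)
            break
        # always take the damped proportional step from the current iterate
        # (the objective is noisy cell-by-cell; the best iterate is kept)
        params = _update_params(params, attach_py(report.points), damping)
        score, report, rates = evaluate(params)
        if score < best[1]:
            best = (params, score, report, rates)
            accepted_scores.append(score)

    # level polish: pin the lifetime integrals with the global scalars
    params, score, report, rates = best
    polish_scores = []
    target_inc = 1000.0 * lifetime_integral(benchmarks, life_table, "crc_incidence")
    target_mort = 1000.0 * lifetime_integral(benchmarks, life_table, "crc_mortality")
    for _ in range(polish):
        r_inc = target_inc / max(rates["incidence_per_1000"], 1e-9)
        r_mort = target_mort / max(rates["mortality_per_1000"], 1e-9)
        if abs(r_inc - 1.0) < 0.02 and abs(r_mort - 1.0) < 0.02:
            break
        f_inc = _damp(r_inc, 1.0)
        # death probability saturates in the rate, hence the 1.5 exponent
        f_surv = _damp(r_mort / r_inc, 1.0) ** 1.5
        params = replace(
            params,
            aggressive_fraction=min(0.9, params.aggressive_fraction * f_inc),
            serrated_risk=params.serrated_risk.scaled(f_inc),
            survival_rate=tuple(min(r * f_surv, 3.0)
                                for r in params.survival_rate))
        score, report, rates = evaluate(params)
        polish_scores.append(score)

    report.iterations = iterations
    report.accepted_scores = accepted_scores
    report.polish_scores = polish_scores
    return params, report
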