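"""Paired scenario comparison: strategy versus no screening, per 1000.

Every strategy is replayed on the same natural-history realizations as
the no-screening scenario (common random numbers), so per-person
differences in death age, diagnosis, and colonoscopy use reflect the
intervention alone.  Benefits are life-years gained and reductions in
lifetime CRC incidence and mortality; burden is lifetime colonoscopies
(diagnostic + surveillance + symptomatic work-up) and non-colonoscopy
tests actually taken; harms are colonoscopy-complication deaths and the
life-years they cost.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .demography import Cohort
from .natural_history import NHParams, simulate_cohort
from .screening import (COLONOSCOPY, DEFAULT_SURVEILLANCE, P_COLONOSCOPY_DEATH,
                        StrategySpec, TestSpec, run_screening_program)


class OutcomesError(ValueError):
    pass


@dataclass
class OutcomeTable:
    """Per-1000 outcomes of one strategy against paired no screening."""

    strategy: str
    colonoscopies: float
    non_col_tests: float
    reduced_crc_cases: float
    reduced_crc_deaths: float
    lyg: float
    col_deaths: float
    years_lost_cols: float
    incidence_screen: float        # absolute lifetime, per 1000
    incidence_noscreen: float
    mortality_screen: float
    mortality_noscreen: float
    colonoscopies_noscreen: float  # symptomatic work-ups in the paired arm

    @property
    def incidence_reduction_pct(self) -> float:
        return 100.0 * self.reduced_crc_cases / self.incidence_noscreen \
            if self.incidence_noscreen else 0.0

    @property
    def mortality_reduction_pct(self) -> float:
        return 100.0 * self.reduced_crc_deaths / self.mortality_noscreen \
            if self.mortality_noscreen else 0.0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["incidence_reduction_pct"] = self.incidence_reduction_pct
        d["mortality_reduction_pct"] = self.mortality_reduction_pct
        return d


def _scenario_stats(histories, strategy, params, cohort_seed, colo,
                    surv_config, p_col_death, tables):
    """Aggregate one scenario over all persons."""
    n = len(histories)
    tot = {"cols": 0, "tests": 0, "cases": 0, "crc_deaths": 0,
           "col_deaths": 0, "years_lost": 0.0}
    death_ages = np.empty(n)
    for i, h in enumerate(histories):
        ledger, out = run_screening_program(
            h, strategy, params, cohort_seed, colo=colo,
            surv_config=surv_config, p_col_death=p_col_death, _tables=tables)
        death_ages[i] = out.death_age
        tot["cols"] += len(ledger.colonoscopies)
        tot["tests"] += len(ledger.tests_taken)
        tot["cases"] += out.dx_age is not None
        tot["crc_deaths"] += out.death_cause == "crc"
        if out.death_cause == "colonoscopy":
            tot["col_deaths"] += 1
            # counterfactual: same scenario with the complication suppressed
            _, cf = run_screening_program(
                h, strategy, params, cohort_seed, colo=colo,
                surv_config=surv_config, p_col_death=p_col_death,
                allow_complications=False, _tables=tables)
            tot["years_lost"] += cf.death_age - out.death_age
            death_ages[i] = out.death_age
    return tot, death_ages


def evaluate_strategy(cohort: Cohort, params: NHParams,
                      strategy: StrategySpec, histories=None,
                      colo: TestSpec = COLONOSCOPY,
                      surv_config=DEFAULT_SURVEILLANCE,
                      p_col_death: float = P_COLONOSCOPY_DEATH,
                      _baseline=None) -> OutcomeTable:
    """Run no-screening and the strategy on identical person streams."""
    if histories is None:
        histories = simulate_cohort(cohort, params)
    if len(histories) != cohort.size:
        raise OutcomesError("histories do not match the cohort")
    tables = params._tables()
    per1000 = 1000.0 / cohort.size
    if _baseline is None:
        _baseline = _scenario_stats(histories, None, params, cohort.seed,
                                    colo, surv_config, p_col_death, tables)
    ns, death_ns = _baseline
    sc, death_sc = _scenario_stats(histories, strategy, params, cohort.seed,
                                   colo, surv_config, p_col_death, tables)
    return OutcomeTable(
        strategy=strategy.label,
        colonoscopies=sc["cols"] * per1000,
        non_col_tests=sc["tests"] * per1000,
        reduced_crc_cases=(ns["cases"] - sc["cases"]) * per1000,
        reduced_crc_deaths=(ns["crc_deaths"] - sc["crc_deaths"]) * per1000,
        lyg=float(np.sum(death_sc - death_ns)) * per1000,
        col_deaths=sc["col_deaths"] * per1000,
        years_lost_cols=sc["years_lost"] * per1000,
        incidence_screen=sc["cases"] * per1000,
        incidence_noscreen=ns["cases"] * per1000,
        mortality_screen=sc["crc_deaths"] * per1000,
        mortality_noscreen=ns["crc_deaths"] * per1000,
        colonoscopies_noscreen=ns["cols"] * per1000,
    )


def no_screening_outcomes(cohort: Cohort, params: NHParams,
                          histories=None,
                          p_col_death: float = P_COLONOSCOPY_DEATH) -> dict:
    """Lifetime incidence, mortality, and symptomatic colonoscopies per 1000."""
    if histories is None:
        histories = simulate_cohort(cohort, params)
    tables = params._tables()
    ns, _ = _scenario_stats(histories, None, params, cohort.seed, COLONOSCOPY,
                            DEFAULT_SURVEILLANCE, p_col_death, tables)
    per1000 = 1000.0 / cohort.size
    return {"incidence_per_1000": ns["cases"] * per1000,
            "mortality_per_1000": ns["crc_deaths"] * per1000,
            "colonoscopies_per_1000": ns["cols"] * per1000}


def run_grid(cohort: Cohort, params: NHParams, grid, histories=None,
             progress=False, **kw) -> pd.DataFrame:
    """Evaluate a strategy grid on one CRN cohort; one row per strategy."""
    if not grid:
        raise OutcomesError("strategy grid is empty")
    labels = [s.label for s in grid]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise OutcomesError(f"duplicate strategy labels: {dupes}")
    if histories is None:
        histories = simulate_cohort(cohort, params)
    baseline = _scenario_stats(
        histories, None, params, cohort.seed,
        kw.get("colo", COLONOSCOPY), kw.get("surv_config", DEFAULT_SURVEILLANCE),
        kw.get("p_col_death", P_COLONOSCOPY_DEATH), params._tables())
    rows = []
    for i, strat in enumerate(grid):
        if progress:
            print(f"[{i + 1}/{len(grid)}] {strat.label}", flush=True)
        rows.append(evaluate_strategy(cohort, params, strat,
                                      histories=histories, _baseline=baseline,
                                      **kw).as_dict())
    return pd.DataFrame(rows)


def pretty_table(df: pd.DataFrame) -> pd.DataFrame:
    """Rounded presentation view (per-1000 integers, harms to 2 dp)."""
    out = df.copy()
    for c in ("colonoscopies", "non_col_tests", "reduced_crc_cases",
              "reduced_crc_deaths", "lyg"):
        out[c] = out[c].round().astype(int)
    for c in ("col_deaths", "years_lost_cols"):
        out[c] = out[c].round(2)
    return out
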