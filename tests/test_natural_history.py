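import math
from dataclasses import replace

import numpy as np
import pytest

from colosim import (default_params, empirical_dwell_time, lifetime_rates,
                     make_cohort, simulate_cohort, simulate_history,
                     summarize_history)
from colosim.natural_history import NaturalHistoryError, NHParams, PersonHistory

STATE_ORDER = ["early_adenoma", "advanced_adenoma", "preclinical_cancer",
               "clinical_cancer"]


def _null_risk(params):
    zero = params.adenoma_risk.scaled(0.0)
    return replace(params, adenoma_risk=zero, serrated_risk=zero)


class TestSimulateHistory:
    def test_zero_risk_gives_no_lesions_and_other_cause_death(self, small_cohort, params):
        p0 = _null_risk(params)
        for i in range(100):
            h = simulate_history(small_cohort.person(i), p0)
            assert h.lesions == []
            assert h.crc_diagnosis is None
            assert h.death == (min(small_cohort.person(i).other_cause_death_age,
                                   100.0), "other")

    def test_blocked_transition_leaves_only_serrated_cancers(self, small_cohort, params):
        blocked = replace(params, p_advanced_to_preclinical=0.0)
        hist = simulate_cohort(small_cohort, blocked)
        diagnosed = [h.diagnosed_lesion for h in hist if h.crc_diagnosis]
        assert diagnosed, "expected some serrated cancers"
        assert all(les.pathway == "serrated" for les in diagnosed)

    def test_state_order_invariant_and_min_genesis_age(self, calib_params, life_table):
        cohort = make_cohort(10_000, 0.5, seed=21, life_table=life_table)
        hist = simulate_cohort(cohort, calib_params)
        n_lesions = 0
        for h in hist:
            for les in h.lesions:
                n_lesions += 1
                ages = les.state_entry_ages
                entries = [ages[s] for s in STATE_ORDER if s in ages]
                assert entries == sorted(entries)
                assert all(b > a for a, b in zip(entries, entries[1:]))
                assert les.genesis_age >= calib_params.min_genesis_age
                if les.pathway == "serrated":
                    # no adenomatous precursor: born as preclinical cancer
                    assert les.preclinical_age == les.genesis_age
            if h.crc_diagnosis is not None:
                dx_age = h.crc_diagnosis[0]
                assert dx_age <= h.death[0]
                assert h.diagnosed_lesion.preclinical_age < dx_age
        assert n_lesions > 1000

    def test_histories_are_deterministic_given_seed(self, small_cohort, calib_params):
        a = simulate_history(small_cohort.person(5), calib_params)
        b = simulate_history(small_cohort.person(5), calib_params)
        assert a == b

    def test_serrated_share_matches_configuration(self, calib_params, life_table):
        # with the serrated pathway disabled every cancer has an adenoma
        # precursor; enabled, its share matches a simulated large-cohort
        # proportion within a binomial interval
        cohort = make_cohort(30_000, 0.5, seed=2, life_table=life_table)
        no_ser = replace(calib_params,
                         serrated_risk=calib_params.serrated_risk.scaled(0.0))
        hist0 = simulate_cohort(cohort, no_ser)
        assert all(h.diagnosed_lesion.pathway == "adenoma_carcinoma"
                   for h in hist0 if h.crc_diagnosis)

        hist1 = simulate_cohort(cohort, calib_params)
        cancers = [h.diagnosed_lesion.pathway for h in hist1 if h.crc_diagnosis]
        share = np.mean([p == "serrated" for p in cancers])
        assert 0.0 < share < 0.5  # a configured minority pathway

    def test_lifetime_incidence_monotone_in_adenoma_risk(self, life_table, calib_params):
        cohort = make_cohort(10_000, 0.5, seed=13, life_table=life_table)
        lo = lifetime_rates(simulate_cohort(cohort, calib_params))
        hi_params = replace(calib_params,
                            adenoma_risk=calib_params.adenoma_risk.scaled(2.0))
        hi = lifetime_rates(simulate_cohort(cohort, hi_params))
        assert hi["incidence_per_1000"] >= lo["incidence_per_1000"]


class TestSummaries:
    def test_no_lesion_cohort_summarizes_to_zero(self, small_cohort, params):
        hist = simulate_cohort(small_cohort, _null_risk(params))
        summ = summarize_history(hist)
        assert (summ.loc[summ.metric != "rectal_fraction", "value"] == 0).all()

    def test_single_diagnosis_lands_in_its_age_band(self, small_cohort, params):
        h = simulate_history(small_cohort.person(0), _null_risk(params))
        h = replace_history(h, crc_diagnosis=(60.5, "II", "symptomatic"),
                            death=(82.0, "other"))
        rest = [simulate_history(small_cohort.person(i), _null_risk(params))
                for i in range(1, 50)]
        summ = summarize_history([h] + rest)
        inc = summ[(summ.metric == "crc_incidence") & (summ.sex == h.sex)]
        nonzero = inc[inc.value > 0]
        assert len(nonzero) == 1
        assert (nonzero.age_lo.iloc[0], nonzero.age_hi.iloc[0]) == (60, 65)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_history([])


def replace_history(h: PersonHistory, **kw) -> PersonHistory:
    from dataclasses import replace as dc_replace
    return dc_replace(h, **kw)


class TestDwellTime:
    def test_forced_fastest_path_dwell_is_the_annual_cycle_minimum(self, small_cohort, params):
        # transition probabilities of 1 collapse each waiting time to one
        # annual cycle; with a negligible sojourn the dwell is two cycles
        fast = replace(params, aggressive_fraction=1.0, p_early_to_advanced=1.0,
                       p_advanced_to_preclinical=1.0, sojourn_mean=1e-6,
                       adenoma_risk=params.adenoma_risk.scaled(3.0))
        hist = simulate_cohort(small_cohort, fast)
        dwell = empirical_dwell_time(hist)
        assert abs(dwell - 2.0) < 0.2

    def test_calibrated_dwell_is_near_thirteen_years(self, mid_histories):
        assert abs(empirical_dwell_time(mid_histories) - 13.0) <= 1.5

    def test_longer_sojourn_increases_dwell(self, small_cohort, calib_params):
        base = simulate_cohort(small_cohort, calib_params)
        slower = replace(calib_params, sojourn_mean=2 * calib_params.sojourn_mean)
        slow = simulate_cohort(small_cohort, slower)
        assert empirical_dwell_time(slow) > empirical_dwell_time(base)

    def test_too_few_cancers_raises_with_count(self, small_cohort, params):
        hist = simulate_cohort(small_cohort, _null_risk(params))
        with pytest.raises(NaturalHistoryError, match="0"):
            empirical_dwell_time(hist)


def test_params_yaml_round_trip(calib_params, tmp_path):
    p = tmp_path / "params.yaml"
    calib_params.to_yaml(p)
    assert NHParams.from_yaml(p) == calib_params


def test_screen_stage_distribution_must_be_earlier(params):
    with pytest.raises(NaturalHistoryError):
        replace(params, stage_dist_screen=(0.05, 0.15, 0.30, 0.50))
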