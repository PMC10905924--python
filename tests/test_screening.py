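from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from colosim import simulate_history
from colosim.screening import (COLONOSCOPY, DEFAULT_SURVEILLANCE, NCPCSInputs,
                               ScreeningError, StrategySpec, TestSpec,
                               apply_initial_test, colonoscopy_exam,
                               default_grid, get_test_spec, ncpcs_score,
                               parse_strategy, run_screening_program,
                               surveillance_schedule)

NULL_TEST = TestSpec("null", 0, 0, 0, 0, 1.0, 1.0, 1.0)


class TestNCPCSScore:
    @pytest.mark.parametrize("inputs,expected", [
        # all-zero row: young female with previous negative colonoscopy
        (NCPCSInputs(sex="female", age=30, pnc=True), (0, False)),
        # every risk factor present
        (NCPCSInputs(sex="male", age=65, bmi_class=">=24",
                     smoking="current/past", drinking="current", diabetes=True,
                     fdr_crc=True, pnc=False), (28, True)),
        # boundary: 2 + 9 + 1 + 3 = 15, exactly positive
        (NCPCSInputs(sex="male", age=47, bmi_class=">=24", pnc=False),
         (15, True)),
        (NCPCSInputs(sex="female", age=47, bmi_class=">=24", pnc=False),
         (13, False)),
    ])
    def test_published_score_sheet(self, inputs, expected):
        assert ncpcs_score(inputs) == expected


class TestSpecsAndStrategies:
    def test_table_values_for_rs_dominate_its_components(self):
        fit, ncpcs, rs = (get_test_spec(n) for n in ("FIT", "NCPCS", "RS"))
        # a disjunction of two tests cannot be less sensitive than either
        assert rs.sens_crc >= max(fit.sens_crc, ncpcs.sens_crc)
        assert rs.sens_medium >= fit.sens_medium
        assert rs.sens_large >= fit.sens_large
        assert rs.specificity <= min(fit.specificity, ncpcs.specificity)

    def test_unknown_test_name_raises(self):
        with pytest.raises(ScreeningError):
            get_test_spec("gFOBT")

    def test_composed_rs_dominates_components_and_loses_specificity(self):
        from colosim.screening import composed_rs_spec
        rs = composed_rs_spec()
        fit, ncpcs = get_test_spec("FIT"), get_test_spec("NCPCS")
        assert rs.sens_crc >= max(fit.sens_crc, ncpcs.sens_crc)
        assert rs.specificity == pytest.approx(fit.specificity
                                               * ncpcs.specificity)

    def test_strategy_label_round_trip(self):
        s = parse_strategy("FIT:50-70:3")
        assert (s.test, s.start_age, s.stop_age, s.interval) == ("FIT", 50, 70, 3)
        assert s.label == "FIT:50-70:3"
        assert s.offer_ages() == [50, 53, 56, 59, 62, 65, 68]

    def test_default_grid_is_81_strategies(self):
        grid = default_grid()
        assert len(grid) == 81
        assert len({s.label for s in grid}) == 81

    def test_invalid_strategies_rejected(self):
        with pytest.raises(ScreeningError):
            StrategySpec(test="FIT", start_age=70, stop_age=50, interval=3)
        with pytest.raises(ScreeningError):
            parse_strategy("FIT:50:70:3")


class TestInitialTest:
    def test_null_test_is_always_negative(self, small_cohort, calib_params):
        rng = np.random.default_rng(0)
        for i in range(200):
            h = simulate_history(small_cohort.person(i), calib_params)
            r = apply_initial_test(h, 60.0, NULL_TEST, rng)
            assert r == "negative"

    def test_fit_detects_preclinical_cancer_at_table_sensitivity(
            self, mid_histories):
        fit = get_test_spec("FIT")
        spec = replace(fit, participation=1.0)
        rng = np.random.default_rng(1)
        hits = trials = 0
        for h in mid_histories:
            carrier_age = next(
                (les.preclinical_age + 0.5 for les in h.lesions
                 if les.preclinical_age + 0.5 < min(les.clinical_age, 100.0)),
                None)
            if carrier_age is None:
                continue
            others = [l for l in h.lesions
                      if l.state(carrier_age) in ("early_adenoma",
                                                  "advanced_adenoma")]
            if others:
                continue  # isolate the cancer-sensitivity channel
            trials += 1
            hits += apply_initial_test(h, carrier_age, spec, rng) == "true_positive"
        assert trials > 200
        lo, hi = stats.binom.interval(0.999, trials, fit.sens_crc)
        assert lo <= hits <= hi

    def test_lesion_free_rs_false_positive_rate_is_one_minus_specificity(
            self, small_cohort, calib_params):
        rs = replace(get_test_spec("RS"), participation=1.0)
        rng = np.random.default_rng(2)
        zero = calib_params.adenoma_risk.scaled(0.0)
        p0 = replace(calib_params, adenoma_risk=zero, serrated_risk=zero)
        n = 5000
        fps = sum(
            apply_initial_test(simulate_history(small_cohort.person(i % 2000), p0),
                               55.0, rs, rng) == "false_positive"
            for i in range(n))
        lo, hi = stats.binom.interval(0.999, n, 1.0 - rs.specificity)
        assert lo <= fps <= hi

    def test_participation_accounting(self, mid_cohort, calib_params, mid_histories):
        # taken/offered converges to the participation rate
        strat = parse_strategy("FIT:50-70:3")
        spec = get_test_spec("FIT")
        offers = taken = 0
        for h in mid_histories[:8000]:
            ledger, _ = run_screening_program(h, strat, calib_params,
                                              mid_cohort.seed)
            offers += len(ledger.offers)
            taken += len(ledger.tests_taken)
        assert offers > 10_000
        lo, hi = stats.binom.interval(0.999, offers, spec.participation)
        assert lo <= taken <= hi


class TestColonoscopy:
    def test_no_lesions_nothing_detected(self, small_cohort, calib_params):
        zero = calib_params.adenoma_risk.scaled(0.0)
        p0 = replace(calib_params, adenoma_risk=zero, serrated_risk=zero)
        h = simulate_history(small_cohort.person(0), p0)
        detected, removed, cancer = colonoscopy_exam(
            h.lesions, 60.0, COLONOSCOPY, np.random.default_rng(0))
        assert detected == [] and removed == [] and cancer is None

    def test_large_adenoma_detection_rate(self, mid_histories):
        rng = np.random.default_rng(3)
        hits = trials = 0
        for h in mid_histories:
            for les in h.lesions:
                a = les.advanced_age + 0.5
                if les.state(a) != "advanced_adenoma" or a > 100:
                    continue
                trials += 1
                _, removed, _ = colonoscopy_exam([les], a, COLONOSCOPY, rng)
                hits += les in removed
                break
        assert trials > 500
        lo, hi = stats.binom.interval(0.999, trials, COLONOSCOPY.sens_large)
        assert lo <= hits <= hi

    def test_midpoint_sensitivities_sit_inside_published_ranges(self):
        assert 0.65 <= COLONOSCOPY.sens_small <= 0.75
        assert 0.81 <= COLONOSCOPY.sens_medium <= 0.87
        assert COLONOSCOPY.sens_large == 0.95
        assert 0.95 <= COLONOSCOPY.sens_crc <= 1.0
        assert COLONOSCOPY.specificity == 1.0


class TestSurveillance:
    def test_advanced_adenoma_goes_to_three_years(self):
        nxt = surveillance_schedule({"n_adenomas": 1, "advanced": True}, 60.0)
        assert nxt == 63.0

    def test_one_or_two_small_adenomas_go_to_five_years(self):
        assert surveillance_schedule({"n_adenomas": 2}, 60.0) == 65.0
        assert surveillance_schedule({"n_adenomas": 3}, 60.0) == 63.0

    def test_clean_diagnostic_exam_releases(self):
        assert surveillance_schedule({"n_adenomas": 0}, 60.0) is None

    def test_clean_surveillance_exam_gets_one_ten_year_recall_then_release(self):
        first = surveillance_schedule({"surveillance_exam": True,
                                       "consecutive_clean": 0}, 60.0)
        assert first == 70.0
        again = surveillance_schedule({"surveillance_exam": True,
                                       "consecutive_clean": 1}, 70.0)
        assert again is None

    def test_disabled_surveillance_always_none(self):
        assert surveillance_schedule({"n_adenomas": 5, "advanced": True},
                                     60.0, enabled=False) is None

    def test_never_scheduled_past_age_eighty(self):
        assert surveillance_schedule({"advanced": True}, 79.0) is None


class TestProgramReplay:
    def test_person_dead_before_start_age_has_empty_ledger(
            self, small_cohort, calib_params):
        idx = int(np.argmin(small_cohort.other_cause_death_age))
        assert small_cohort.other_cause_death_age[idx] < 40
        h = simulate_history(small_cohort.person(idx), calib_params)
        ledger, out = run_screening_program(
            h, parse_strategy("FIT:40-80:1"), calib_params, small_cohort.seed)
        assert ledger.offers == [] and ledger.colonoscopies == []
        assert out.death_age == h.death[0]

    def test_null_test_reproduces_no_screening_bit_for_bit(
            self, mid_cohort, calib_params, mid_histories):
        import colosim.screening as scr
        scr.PROFILES["trial"]["null"] = NULL_TEST
        strat = StrategySpec(test="null", start_age=40, stop_age=80, interval=1)
        try:
            for h in mid_histories[:3000]:
                _, null_out = run_screening_program(h, strat, calib_params,
                                                    mid_cohort.seed)
                _, ns_out = run_screening_program(h, None, calib_params,
                                                  mid_cohort.seed)
                assert null_out == ns_out
        finally:
            del scr.PROFILES["trial"]["null"]

    def test_false_positive_lockout_skips_to_first_grid_age_after_five_years(
            self, mid_cohort, calib_params, mid_histories):
        strat = parse_strategy("FIT:50-70:1")
        checked = 0
        for h in mid_histories[:6000]:
            ledger, _ = run_screening_program(h, strat, calib_params,
                                              mid_cohort.seed)
            diag = [a for a, ind in ledger.colonoscopies if ind == "diagnostic"]
            if ledger.false_positives and diag and ledger.lockout_until > 0:
                col_age = ledger.lockout_until - 5.0
                later = [a for a in ledger.tests_taken if a > col_age]
                assert all(a >= col_age + 5.0 for a in later)
                checked += 1
        assert checked > 20

    def test_no_surveillance_mode_needs_fewer_colonoscopies(
            self, mid_cohort, calib_params, mid_histories):
        for label in ("FIT:50-70:3", "NCPCS:50-70:2"):
            with_s = parse_strategy(label)
            without = parse_strategy(label, surveillance_enabled=False)
            n_with = n_without = 0
            for h in mid_histories[:6000]:
                lw, _ = run_screening_program(h, with_s, calib_params,
                                              mid_cohort.seed)
                lo, _ = run_screening_program(h, without, calib_params,
                                              mid_cohort.seed)
                n_with += len(lw.colonoscopies)
                n_without += len(lo.colonoscopies)
            assert n_without <= n_with

    def test_ledger_colonoscopy_indications_are_complete(
            self, mid_cohort, calib_params, mid_histories):
        strat = parse_strategy("RS:50-70:2")
        for h in mid_histories[:3000]:
            ledger, out = run_screening_program(h, strat, calib_params,
                                                mid_cohort.seed)
            kinds = {ind for _, ind in ledger.colonoscopies}
            assert kinds <= {"diagnostic", "surveillance", "symptomatic"}
            assert ledger.n_colonoscopies() == sum(
                ledger.n_colonoscopies(k)
                for k in ("diagnostic", "surveillance", "symptomatic"))
            if ledger.false_positives:
                assert get_test_spec("RS").specificity < 1.0
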