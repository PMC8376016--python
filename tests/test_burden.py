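import pytest
from hypothesis import given, settings, strategies as st

from conflictburden import (
    Care,
    DurationUnit,
    InjuryPattern,
    Outcome,
    classify,
    compute_direct,
    compute_yld_incidence,
    compute_yld_prevalence,
    compute_yll,
    load_standard_life_table,
    make_flat_life_table,
    parse_duration,
)
from conflictburden.burden import allocate_person_years, disability_span_years
from tests.conftest import make_record


class TestParseDuration:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (6, DurationUnit.MONTHS, 0.5),
            (26, DurationUnit.WEEKS, 0.5),
            (365, DurationUnit.DAYS, 1.0),
            (2, DurationUnit.YEARS, 2.0),
            (0, DurationUnit.DAYS, 0.0),
        ],
    )
    def test_unit_conversion(self, value, unit, expected):
        assert parse_duration(value, unit) == pytest.approx(expected)

    def test_negative_value_raises(self):
        with pytest.raises(ValueError):
            parse_duration(-1, DurationUnit.DAYS)

    def test_continuing_raises(self):
        with pytest.raises(ValueError):
            parse_duration(1, DurationUnit.CONTINUING)


class TestClassify:
    def test_definitive_death(self):
        rec = make_record(outcome=Outcome.DEATH_RELATED, age_at_death=30,
                          disability_flag=False, duration_value=None, duration_unit=None)
        assert classify(rec) is InjuryPattern.DEATH

    def test_six_months_hospital_is_short_term(self):
        rec = make_record(duration_value=6, duration_unit=DurationUnit.MONTHS)
        assert classify(rec) is InjuryPattern.SHORT_TERM

    def test_continuing_without_care_is_permanent_untreated(self):
        rec = make_record(care=Care.NONE, duration_value=None,
                          duration_unit=DurationUnit.CONTINUING, dw_code="lt_amputation")
        assert classify(rec) is InjuryPattern.PERMANENT_UNTREATED

    def test_continuing_with_care_is_permanent_treated(self):
        rec = make_record(care=Care.CLINIC, duration_value=None,
                          duration_unit=DurationUnit.CONTINUING, dw_code="lt_amputation")
        assert classify(rec) is InjuryPattern.PERMANENT_TREATED

    @pytest.mark.parametrize(
        "care,expected",
        [
            (Care.HOSPITAL, InjuryPattern.LONG_TERM_RECOVERED_TREATED),
            (Care.WORKPLACE, InjuryPattern.LONG_TERM_RECOVERED_TREATED),
            (Care.NONE, InjuryPattern.LONG_TERM_RECOVERED_UNTREATED),
        ],
    )
    def test_year_or_more_is_long_term(self, care, expected):
        rec = make_record(care=care, duration_value=2, duration_unit=DurationUnit.YEARS,
                          dw_code="lt_amputation")
        assert classify(rec) is expected

    def test_exactly_one_year_is_long_term(self):
        rec = make_record(duration_value=12, duration_unit=DurationUnit.MONTHS)
        assert classify(rec) is InjuryPattern.LONG_TERM_RECOVERED_TREATED

    def test_nondefinitive_death_uses_disability_fields(self):
        rec = make_record(outcome=Outcome.DEATH_POSSIBLY_RELATED, age_at_death=40)
        assert classify(rec) is InjuryPattern.SHORT_TERM


class TestYLL:
    def test_death_at_twenty_standard_table(self, standard_table):
        rec = make_record(outcome=Outcome.DEATH_RELATED, age_at_death=20,
                          disability_flag=False, duration_value=None, duration_unit=None)
        assert compute_yll(rec, standard_table) == pytest.approx(67.0, abs=1.0)

    def test_death_past_table_end(self, standard_table):
        rec = make_record(outcome=Outcome.DEATH_RELATED, age_at_death=115,
                          disability_flag=False, duration_value=None, duration_unit=None)
        yll = compute_yll(rec, standard_table)
        assert yll == pytest.approx(standard_table.remaining[-1])
        assert yll >= 0

    def test_survivor_rejected(self, standard_table):
        with pytest.raises(ValueError, match="death_related"):
            compute_yll(make_record(), standard_table)

    def test_possibly_related_death_rejected(self, standard_table):
        rec = make_record(outcome=Outcome.DEATH_POSSIBLY_RELATED, age_at_death=40)
        with pytest.raises(ValueError):
            compute_yll(rec, standard_table)

    def test_missing_age_at_death_rejected(self, standard_table):
        rec = make_record(outcome=Outcome.DEATH_RELATED, age_at_death=None,
                          disability_flag=False, duration_value=None, duration_unit=None)
        with pytest.raises(ValueError):
            compute_yll(rec, standard_table)


def permanent_record(age=20, care=Care.HOSPITAL):
    return make_record(age_at_injury=age, care=care, duration_value=None,
                       duration_unit=DurationUnit.CONTINUING, dw_code="lt_spinal_cord")


class TestYLDIncidence:
    def test_permanent_at_twenty_dw_point_two(self, standard_table):
        # worked example: DW 0.2 x remaining LE at 20 (~67 y) ~ 13.4 YLDs
        rec = permanent_record(age=20)
        yld = compute_yld_incidence(rec, InjuryPattern.PERMANENT_TREATED, 0.2, standard_table)
        assert yld == pytest.approx(13.4, abs=0.15)

    def test_zero_dw_gives_zero(self, standard_table):
        rec = permanent_record()
        assert compute_yld_incidence(rec, InjuryPattern.PERMANENT_TREATED, 0.0, standard_table) == 0.0

    def test_long_term_is_dw_times_duration(self):
        rec = make_record(duration_value=2, duration_unit=DurationUnit.YEARS)
        yld = compute_yld_incidence(rec, InjuryPattern.LONG_TERM_RECOVERED_TREATED, 0.3)
        assert yld == pytest.approx(0.6)

    def test_dw_outside_unit_interval_rejected(self, standard_table):
        with pytest.raises(ValueError):
            compute_yld_incidence(make_record(), InjuryPattern.SHORT_TERM, 1.2)

    def test_permanent_without_age_rejected(self, standard_table):
        rec = make_record(age_at_injury=None, duration_value=None,
                          duration_unit=DurationUnit.CONTINUING, dw_code="lt_spinal_cord")
        with pytest.raises(ValueError):
            compute_yld_incidence(rec, InjuryPattern.PERMANENT_TREATED, 0.2, standard_table)

    @given(dw=st.floats(min_value=0, max_value=1), years=st.floats(min_value=0, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_dw_and_duration(self, dw, years):
        rec = make_record(duration_value=years, duration_unit=DurationUnit.YEARS)
        pattern = InjuryPattern.LONG_TERM_RECOVERED_TREATED
        base = compute_yld_incidence(rec, pattern, dw)
        assert compute_yld_incidence(rec, pattern, min(1.0, dw + 0.1)) >= base
        longer = make_record(duration_value=years + 1, duration_unit=DurationUnit.YEARS)
        assert compute_yld_incidence(longer, pattern, dw) >= base


class TestYLDPrevalence:
    def test_window_allocation_spec_example(self):
        # permanent disability, DW 0.2, three whole years inside the window
        rec = permanent_record(age=20)
        table = load_standard_life_table()
        year = rec.injury_year
        alloc = compute_yld_prevalence(
            rec, InjuryPattern.PERMANENT_TREATED, 0.2,
            study_end=year + 3.0, table=table, injury_time_offset=0.0,
        )
        assert alloc == {year: pytest.approx(0.2), year + 1: pytest.approx(0.2),
                         year + 2: pytest.approx(0.2)}
        assert sum(alloc.values()) == pytest.approx(0.6)

    def test_midyear_offset_default_prorates_first_year(self, standard_table):
        rec = permanent_record(age=20)
        year = rec.injury_year
        alloc = compute_yld_prevalence(
            rec, InjuryPattern.PERMANENT_TREATED, 0.2,
            study_end=year + 3.0, table=standard_table,
        )
        assert alloc[year] == pytest.approx(0.1)
        assert sum(alloc.values()) == pytest.approx(0.5)

    def test_short_term_confined_to_injury_year(self):
        rec = make_record(duration_value=4, duration_unit=DurationUnit.MONTHS)
        alloc = compute_yld_prevalence(rec, InjuryPattern.SHORT_TERM, 0.3, study_end=None)
        assert set(alloc) == {rec.injury_year}
        assert sum(alloc.values()) == pytest.approx(
            compute_yld_incidence(rec, InjuryPattern.SHORT_TERM, 0.3)
        )

    def test_unbounded_horizon_matches_incidence(self, standard_table):
        # worked example: both methods total ~13.4 YLDs
        rec = permanent_record(age=20)
        alloc = compute_yld_prevalence(
            rec, InjuryPattern.PERMANENT_TREATED, 0.2, study_end=None, table=standard_table
        )
        incidence = compute_yld_incidence(rec, InjuryPattern.PERMANENT_TREATED, 0.2, standard_table)
        assert abs(sum(alloc.values()) - incidence) < 1e-9

    def test_study_end_before_injury_gives_empty_allocation(self, standard_table):
        rec = permanent_record(age=20)
        alloc = compute_yld_prevalence(
            rec, InjuryPattern.PERMANENT_TREATED, 0.2,
            study_end=rec.injury_year - 1.0, table=standard_table,
        )
        assert alloc == {}

    @given(
        start=st.floats(min_value=2003, max_value=2014.99),
        span=st.floats(min_value=0, max_value=80),
        rate=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, deadline=None)
    def test_allocation_conserves_mass(self, start, span, rate):
        alloc = allocate_person_years(start, start + span, rate)
        assert sum(alloc.values()) == pytest.approx(rate * span, abs=1e-9)
        assert all(0 <= v <= rate + 1e-12 for v in alloc.values())


class TestEquivalenceOnSyntheticCohort:
    def test_prevalence_equals_incidence_unbounded(self, small_survey, registry_draws,
                                                   standard_table):
        _, records, _ = small_survey
        burdens = compute_direct(records, registry_draws, standard_table, study_end=None)
        for pb in burdens:
            assert abs(sum(pb.yld_prevalence_by_year.values()) - pb.yld_incidence) < 1e-9

    def test_daly_is_yll_plus_yld_exactly(self, small_survey, registry_draws, standard_table):
        _, records, _ = small_survey
        burdens = compute_direct(records, registry_draws, standard_table)
        total_daly = sum(pb.daly for pb in burdens)
        total_yll = sum(pb.yll for pb in burdens)
        total_yld = sum(pb.yld_incidence for pb in burdens)
        assert total_daly == pytest.approx(total_yll + total_yld, rel=1e-12)

    def test_record_contributes_to_exactly_one_of_yll_yld(self, small_survey,
                                                          registry_draws, standard_table):
        _, records, _ = small_survey
        for pb in compute_direct(records, registry_draws, standard_table):
            assert not (pb.yll > 0 and pb.yld_incidence > 0)

    def test_untreated_yld_at_least_treated(self, registry, standard_table):
        # same record valued under both care routes
        for code in registry.long_term_codes():
            treated = make_record(care=Care.HOSPITAL, duration_value=4,
                                  duration_unit=DurationUnit.YEARS, dw_code=code)
            untreated = make_record(care=Care.NONE, duration_value=4,
                                    duration_unit=DurationUnit.YEARS, dw_code=code)
            from conflictburden import match_dw
            yld_t = compute_yld_incidence(
                treated, classify(treated),
                match_dw(treated, classify(treated), registry).mean, standard_table)
            yld_u = compute_yld_incidence(
                untreated, classify(untreated),
                match_dw(untreated, classify(untreated), registry).mean, standard_table)
            assert yld_u >= yld_t


class TestFlatVsStandardYLL:
    def test_flat_yll_below_standard_on_synthetic_deaths(self, small_survey, standard_table):
        _, records, _ = small_survey
        flat = make_flat_life_table(69.4)
        deaths = [r for r in records if r.outcome is Outcome.DEATH_RELATED
                  and r.age_at_death is not None]
        assert deaths
        for rec in deaths:
            assert compute_yll(rec, flat) <= compute_yll(rec, standard_table) + 1e-9


class TestDisabilitySpan:
    def test_permanent_span_is_remaining_le(self, standard_table):
        rec = permanent_record(age=20)
        span = disability_span_years(rec, InjuryPattern.PERMANENT_TREATED, standard_table)
        assert span == pytest.approx(standard_table.remaining_life_expectancy(20))

    def test_death_has_no_span(self, standard_table):
        rec = make_record(outcome=Outcome.DEATH_RELATED, age_at_death=20,
                          disability_flag=False, duration_value=None, duration_unit=None)
        with pytest.raises(ValueError):
            disability_span_years(rec, InjuryPattern.DEATH, standard_table)
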