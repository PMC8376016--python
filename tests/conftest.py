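import pytest

from conflictburden import (
    Care,
    DurationUnit,
    InjuryRecord,
    Mechanism,
    Outcome,
    SyntheticSurveyConfig,
    generate_draws,
    generate_survey,
    load_dw_registry,
    load_standard_life_table,
)


@pytest.fixture(scope="session")
def standard_table():
    return load_standard_life_table()


@pytest.fixture(scope="session")
def registry():
    return load_dw_registry()


@pytest.fixture(scope="session")
def registry_draws(registry):
    return generate_draws(registry, n_draws=1000, seed=123)


@pytest.fixture(scope="session")
def small_survey():
    """A fast synthetic survey with no missingness (module-wide reuse)."""
    config = SyntheticSurveyConfig(n_households=250, missingness=0.0, seed=42)
    records, truth = generate_survey(config)
    return config, records, truth


@pytest.fixture(scope="session")
def default_survey():
    """Synthetic survey at default (paper-like) scale."""
    config = SyntheticSurveyConfig(seed=7)
    records, truth = generate_survey(config)
    return config, records, truth


def make_record(**kwargs) -> InjuryRecord:
    defaults = dict(
        person_id="p1",
        injury_year=2008,
        mechanism=Mechanism.GUNSHOT,
        outcome=Outcome.SURVIVED,
        age_at_injury=30,
        care=Care.HOSPITAL,
        disability_flag=True,
        duration_value=6.0,
        duration_unit=DurationUnit.MONTHS,
        dw_code="st_moderate",
    )
    defaults.update(kwargs)
    return InjuryRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record
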