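import pytest

from htngap import CountryRecord


@pytest.fixture
def make_record():
    """Factory for a valid CountryRecord with overridable fields."""

    def _make(**overrides) -> CountryRecord:
        base = dict(
            iso3="NPL",
            name="Nepal",
            population_total=30_000_000.0,
            population_eligible=18_000_000.0,
            income_group="LMIC",
            density_physician=7.3,
            density_nurse=20.0,
            density_pharmacist=1.5,
            density_chw=3.0,
            prevalence=0.375,
            prevalence_lo=0.309,
            prevalence_hi=0.441,
        )
        base.update(overrides)
        return CountryRecord(**base)

    return _make
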