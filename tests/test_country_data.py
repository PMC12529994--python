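"""Domain types, file readers, income classification and dataset assembly."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htngap import (
    AssemblyError,
    CountryRecord,
    Dataset,
    IncomeThresholds,
    InputError,
    ValidationError,
    assemble_dataset,
    classify_income,
    read_dataset,
    read_density_table,
    read_prevalence_table,
    write_dataset,
)
from htngap.synthetic import default_config, generate_dataset


# ---------------------------------------------------------------- types

class TestCountryRecord:
    def test_valid_record_constructs(self, make_record):
        record = make_record()
        assert record.iso3 == "NPL"
        assert record.density("chw") == 3.0

    @pytest.mark.parametrize(
        "overrides",
        [
            {"iso3": "NP"},
            {"iso3": "NPL1"},
            {"population_total": 0.0},
            {"population_eligible": 40_000_000.0},  # above total
            {"income_group": "MIC"},
            {"density_physician": -1.0},
            {"density_nurse": -0.1},
            {"prevalence_lo": 0.5},  # above point
            {"prevalence_hi": 0.30},  # below point
            {"prevalence_hi": 1.5},
        ],
    )
    def test_invariant_violations_raise(self, make_record, overrides):
        with pytest.raises(ValidationError):
            make_record(**overrides)

    def test_optional_densities_may_be_missing(self, make_record):
        record = make_record(density_nurse=None, density_pharmacist=None,
                             density_chw=None)
        assert record.density("nurse") is None

    def test_unknown_provider_type_rejected(self, make_record):
        with pytest.raises(ValidationError):
            make_record().density("dentist")


class TestDataset:
    def test_duplicate_iso3_rejected(self, make_record):
        with pytest.raises(ValidationError, match="duplicate"):
            Dataset(records=(make_record(), make_record()))

    def test_chw_coverage_counts_nonmissing(self, make_record):
        ds = Dataset(records=(
            make_record(iso3="AAA"),
            make_record(iso3="BBB", density_chw=None),
            make_record(iso3="CCC"),
        ))
        assert ds.chw_coverage == 2


# ------------------------------------------------------- classification

class TestClassifyIncome:
    @pytest.mark.parametrize(
        "gni,expected",
        [
            (500, "LIC"),
            (1085, "LIC"),       # boundary is upper-inclusive
            (1086, "LMIC"),
            (4255, "LMIC"),
            (4256, "UMIC"),
            (13845, "UMIC"),
            (13846, "HIC"),
            (50_000, "HIC"),
        ],
    )
    def test_threshold_boundaries(self, gni, expected):
        assert classify_income(gni) == expected

    def test_non_positive_gni_rejected(self):
        with pytest.raises(ValidationError):
            classify_income(0)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValidationError):
            IncomeThresholds(lic_max=5000, lmic_max=4255, umic_max=13845)

    @settings(max_examples=200, derandomize=True)
    @given(
        gni_a=st.floats(min_value=1.0, max_value=1e6),
        gni_b=st.floats(min_value=1.0, max_value=1e6),
    )
    def test_monotone_step_function(self, gni_a, gni_b):
        """Raising GNI never moves a country to a lower income group."""
        order = {"LIC": 0, "LMIC": 1, "UMIC": 2, "HIC": 3}
        lo, hi = sorted((gni_a, gni_b))
        assert order[classify_income(lo)] <= order[classify_income(hi)]


# --------------------------------------------------------------- readers

class TestReadDensityTable:
    def test_long_layout_latest_nonmissing(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text(
            "country,code,year,value\n"
            "India,IND,2019,7.3\n"
            "India,IND,2021,\n"
            "Nepal,NPL,2018,\n"
        )
        assert read_density_table(path) == {"IND": (7.3, 2019)}

    def test_wide_layout_latest_year_wins(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text(
            "country,code,2018,2020\n"
            "India,IND,7.0,7.3\n"
            "Nepal,NPL,6.0,\n"
        )
        assert read_density_table(path) == {"IND": (7.3, 2020),
                                            "NPL": (6.0, 2018)}

    def test_negative_density_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("country,code,year,value\nIndia,IND,2019,-1\n")
        with pytest.raises(ValidationError, match="IND"):
            read_density_table(path, indicator_name="physicians")

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            read_density_table(tmp_path / "absent.csv")

    def test_world_bank_metadata_preamble_skipped(self, tmp_path):
        path = tmp_path / "wb.csv"
        path.write_text(
            '"Data Source","World Development Indicators"\n'
            '"Last Updated Date","2023-01-01"\n'
            "\n"
            "\n"
            "country,code,2020,2021\n"
            "India,IND,7.0,7.3\n"
        )
        assert read_density_table(path) == {"IND": (7.3, 2021)}


class TestReadPrevalenceTable:
    def test_percent_scale_normalised(self, tmp_path):
        path = tmp_path / "prev.csv"
        path.write_text("code,prevalence,lower,upper\nNPL,37.5,30.9,44.1\n")
        point, lo, hi = read_prevalence_table(path)["NPL"]
        assert (point, lo, hi) == (0.375, 0.309, 0.441)

    def test_proportion_scale_unchanged(self, tmp_path):
        path = tmp_path / "prev.csv"
        path.write_text("code,prevalence,lower,upper\nXAA,0.375,0.309,0.441\n")
        assert read_prevalence_table(path)["XAA"] == (0.375, 0.309, 0.441)

    def test_lower_above_point_rejected(self, tmp_path):
        path = tmp_path / "prev.csv"
        path.write_text("code,prevalence,lower,upper\nNPL,37.5,40.0,44.1\n")
        with pytest.raises(ValidationError):
            read_prevalence_table(path)

    def test_values_above_100_rejected(self, tmp_path):
        path = tmp_path / "prev.csv"
        path.write_text("code,prevalence,lower,upper\nNPL,375,309,441\n")
        with pytest.raises(ValidationError):
            read_prevalence_table(path)


# -------------------------------------------------------------- assembly

class TestAssembleDataset:
    @staticmethod
    def _inputs():
        densities = {
            "physician": {"AAA": (10.0, 2021), "BBB": (5.0, 2021)},
            "nurse": {"AAA": (20.0, 2021), "BBB": (15.0, 2021), "CCC": (9.0, 2021)},
            "chw": {"AAA": (2.0, 2021)},
        }
        prevalence = {c: (0.35, 0.30, 0.40) for c in ("AAA", "BBB", "CCC")}
        population = {c: 1e6 for c in ("AAA", "BBB", "CCC")}
        income = {"AAA": "LIC", "BBB": "HIC", "CCC": "UMIC"}
        return densities, prevalence, population, income

    def test_inclusion_rule_drops_countries_without_physicians(self, caplog):
        densities, prevalence, population, income = self._inputs()
        with caplog.at_level("WARNING"):
            ds = assemble_dataset(densities, prevalence, population, income)
        assert sorted(r.iso3 for r in ds) == ["AAA", "BBB"]
        assert any("CCC" in m and "physician" in m for m in caplog.messages)

    def test_chw_coverage_reflects_missingness(self):
        ds = assemble_dataset(*self._inputs())
        assert ds.chw_coverage == 1
        by = {r.iso3: r for r in ds}
        assert by["AAA"].density_chw == 2.0
        assert by["BBB"].density_chw is None

    def test_eligible_population_defaults_to_adult_fraction(self):
        ds = assemble_dataset(*self._inputs(), adult_fraction=0.6)
        assert all(r.population_eligible == pytest.approx(0.6 * r.population_total)
                   for r in ds)

    def test_explicit_eligible_mapping_wins(self):
        densities, prevalence, population, income = self._inputs()
        ds = assemble_dataset(densities, prevalence, population, income,
                              eligible={"AAA": 123_456.0, "BBB": 200_000.0})
        assert {r.iso3: r.population_eligible for r in ds} == {
            "AAA": 123_456.0, "BBB": 200_000.0}

    def test_zero_survivors_is_assembly_error(self):
        with pytest.raises(AssemblyError):
            assemble_dataset({"physician": {}}, {"AAA": (0.3, 0.2, 0.4)},
                             {"AAA": 1e6}, {"AAA": "LIC"})

    def test_unknown_provider_type_rejected(self):
        with pytest.raises(ValidationError):
            assemble_dataset({"dentist": {"AAA": (1.0, 2021)}}, {}, {}, {})


# -------------------------------------------------------------- round trip

def test_dataset_csv_round_trip_is_exact(tmp_path):
    """Writing the canonical CSV and re-reading reproduces every field."""
    ds = generate_dataset(default_config(seed=7))
    path = tmp_path / "dataset.csv"
    write_dataset(ds, path)
    again = read_dataset(path)
    assert again.records == ds.records
    assert again.chw_coverage == ds.chw_coverage


def test_read_dataset_rejects_foreign_csv(tmp_path):
    path = tmp_path / "other.csv"
    path.write_text("a,b\n1,2\n")
    with pytest.raises(InputError):
        read_dataset(path)
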