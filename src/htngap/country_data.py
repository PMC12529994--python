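"""Domain types and ingestion for country-level workforce and prevalence data.

The analysis joins four country-level inputs on ISO3 codes:

* provider densities (physicians, nurses, pharmacists, community health
  workers) per 10 000 total population, in World Bank indicator CSV layouts
  (long: one row per country-year, or wide: one column per year);
* hypertension prevalence with a 95% CI, NCD-RisC style (country, point,
  lower, upper; percent or proportion scale);
* total population;
* World Bank income group, derived from GNI per capita thresholds.

Countries without a physician density are excluded from the assembled
dataset; all other provider densities are optional (community-health-worker
data in particular exist for only about half of countries).
"""
from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

log = logging.getLogger(__name__)

INCOME_GROUPS = ("LIC", "LMIC", "UMIC", "HIC")
#: provider cadres tracked by the model, in canonical order
PROVIDER_TYPES = ("physician", "nurse", "pharmacist", "chw")

#: canonical column order of the internal exchange CSV
DATASET_COLUMNS = (
    "iso3",
    "name",
    "population_total",
    "population_eligible",
    "income_group",
    "density_physician",
    "density_nurse",
    "density_pharmacist",
    "density_chw",
    "prevalence",
    "prevalence_lo",
    "prevalence_hi",
)

#: share of the total population forming the denominator for patient counts.
#: Prevalence estimates cover adults (30+), so applying them to the full
#: population would overstate patient numbers; 0.6 reconciles a ~37% adult
#: prevalence with the headline patient totals the inputs imply.
DEFAULT_ADULT_FRACTION = 0.6


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class InputError(OSError):
    """An input file is missing or unreadable."""


class AssemblyError(ValidationError):
    """Dataset assembly produced no usable countries."""


@dataclass(frozen=True)
class IncomeThresholds:
    """World Bank GNI-per-capita cut points (US$), upper-inclusive.

    LIC: gni <= lic_max; LMIC: lic_max < gni <= lmic_max;
    UMIC: lmic_max < gni <= umic_max; HIC above.
    """

    lic_max: float = 1085.0
    lmic_max: float = 4255.0
    umic_max: float = 13845.0

    def __post_init__(self) -> None:
        if not (self.lic_max < self.lmic_max < self.umic_max):
            raise ValidationError(
                f"income thresholds must be strictly increasing, got "
                f"{self.lic_max}, {self.lmic_max}, {self.umic_max}"
            )


@dataclass(frozen=True)
class CountryRecord:
    """One country's population, income group, densities and prevalence.

    Densities are providers per 10 000 *total* population.  Prevalence is a
    proportion in [0, 1] with its 95% CI, applying to the eligible (adult)
    population ``population_eligible``.
    """

    iso3: str
    name: str
    population_total: float
    population_eligible: float
    income_group: str
    density_physician: float
    prevalence: float
    prevalence_lo: float
    prevalence_hi: float
    density_nurse: Optional[float] = None
    density_pharmacist: Optional[float] = None
    density_chw: Optional[float] = None

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Za-z]{3}", self.iso3):
            raise ValidationError(f"iso3 must be a 3-letter code, got {self.iso3!r}")
        if not self.population_total > 0:
            raise ValidationError(f"{self.iso3}: population_total must be > 0")
        if not 0 < self.population_eligible <= self.population_total:
            raise ValidationError(
                f"{self.iso3}: population_eligible must be in (0, population_total]"
            )
        if self.income_group not in INCOME_GROUPS:
            raise ValidationError(
                f"{self.iso3}: income_group must be one of {INCOME_GROUPS}, "
                f"got {self.income_group!r}"
            )
        if self.density_physician is None or not self.density_physician >= 0:
            raise ValidationError(f"{self.iso3}: density_physician must be >= 0")
        for cadre in ("nurse", "pharmacist", "chw"):
            value = getattr(self, f"density_{cadre}")
            if value is not None and not value >= 0:
                raise ValidationError(f"{self.iso3}: density_{cadre} must be >= 0")
        if not (0 <= self.prevalence_lo <= self.prevalence <= self.prevalence_hi <= 1):
            raise ValidationError(
                f"{self.iso3}: prevalence CI must satisfy "
                f"0 <= lo <= point <= hi <= 1, got "
                f"({self.prevalence_lo}, {self.prevalence}, {self.prevalence_hi})"
            )

    def density(self, provider_type: str) -> Optional[float]:
        """Density for one cadre, ``None`` when not reported."""
        if provider_type not in PROVIDER_TYPES:
            raise ValidationError(f"unknown provider type {provider_type!r}")
        return getattr(self, f"density_{provider_type}")


@dataclass(frozen=True)
class Dataset:
    """An ordered, iso3-unique collection of country records."""

    records: tuple[CountryRecord, ...]

    def __post_init__(self) -> None:
        codes = [r.iso3 for r in self.records]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValidationError(f"duplicate iso3 codes: {dupes}")

    @property
    def chw_coverage(self) -> int:
        """Number of countries reporting a community-health-worker density."""
        return sum(1 for r in self.records if r.density_chw is not None)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_group(self) -> dict[str, tuple[CountryRecord, ...]]:
        return {
            g: tuple(r for r in self.records if r.income_group == g)
            for g in INCOME_GROUPS
        }


def classify_income(
    gni_per_capita: float, thresholds: IncomeThresholds = IncomeThresholds()
) -> str:
    """Map GNI per capita (US$) to an income group label.

    Intervals are upper-inclusive, so every positive GNI maps to exactly
    one group.
    """
    if not gni_per_capita > 0:
        raise ValidationError(f"gni_per_capita must be > 0, got {gni_per_capita}")
    if gni_per_capita <= thresholds.lic_max:
        return "LIC"
    if gni_per_capita <= thresholds.lmic_max:
        return "LMIC"
    if gni_per_capita <= thresholds.umic_max:
        return "UMIC"
    return "HIC"


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    # World Bank downloads carry a 4-line metadata preamble before the
    # header, which can also break tokenisation; retry skipping it
    frames: list[pd.DataFrame] = []
    errors: list[Exception] = []
    for skiprows in (0, 4):
        try:
            frame = pd.read_csv(path, skiprows=skiprows, skipinitialspace=True)
        except Exception as exc:
            errors.append(exc)
            continue
        if _find_code_column(frame):
            return frame
        frames.append(frame)
    if frames:
        return frames[0]
    raise InputError(f"could not parse {path}: {errors[0]}") from errors[0]


def _find_code_column(frame: pd.DataFrame) -> Optional[str]:
    for col in frame.columns:
        if str(col).strip().lower() in {"code", "iso3", "country code", "country_code"}:
            return col
    return None


_YEAR_RE = re.compile(r"^(\d{4})(\s*\[.*\])?$")


def read_density_table(path: str | Path, indicator_name: str = "") -> dict[str, tuple[float, int]]:
    """Read a World Bank style indicator table of provider densities.

    Accepts the long layout (country, code, year, value) or the wide layout
    (country, code, one column per year).  For each country the most recent
    non-missing value is kept; countries with no value in any year are
    absent from the result.

    Returns a mapping iso3 -> (density per 10 000, year).
    """
    frame = _read_csv(path)
    code_col = _find_code_column(frame)
    if code_col is None:
        raise InputError(f"{path}: no country-code column found")

    lower = {str(c).strip().lower(): c for c in frame.columns}
    label = indicator_name or Path(path).name
    out: dict[str, tuple[float, int]] = {}

    if "year" in lower and "value" in lower:  # long layout
        for idx, row in frame.iterrows():
            value = row[lower["value"]]
            if pd.isna(value):
                continue
            value = float(value)
            if value < 0:
                raise ValidationError(
                    f"{label}: negative density {value} at row {idx} "
                    f"({row[code_col]})"
                )
            iso3 = str(row[code_col]).strip()
            year = int(row[lower["year"]])
            if iso3 not in out or year > out[iso3][1]:
                out[iso3] = (value, year)
        return out

    year_cols = [
        (int(_YEAR_RE.match(str(c).strip()).group(1)), c)
        for c in frame.columns
        if _YEAR_RE.match(str(c).strip())
    ]
    if not year_cols:
        raise InputError(f"{path}: neither long (year/value) nor wide (year columns) layout")
    year_cols.sort()
    for idx, row in frame.iterrows():
        iso3 = str(row[code_col]).strip()
        for year, col in year_cols:  # ascending: later years overwrite
            value = row[col]
            if pd.isna(value):
                continue
            value = float(value)
            if value < 0:
                raise ValidationError(
                    f"{label}: negative density {value} at row {idx}, "
                    f"year {year} ({iso3})"
                )
            out[iso3] = (value, year)
    return out


def read_prevalence_table(path: str | Path) -> dict[str, tuple[float, float, float]]:
    """Read an NCD-RisC style prevalence table with 95% CI bounds.

    Values may arrive on the percent or the proportion scale; rows whose
    point estimate exceeds 1 are treated as percent and divided by 100.
    Returns a mapping iso3 -> (prevalence, lo, hi) as proportions.
    """
    frame = _read_csv(path)
    code_col = _find_code_column(frame)
    if code_col is None:
        raise InputError(f"{path}: no country-code column found")
    lower = {str(c).strip().lower(): c for c in frame.columns}

    def pick(*names: str) -> Optional[str]:
        for n in names:
            if n in lower:
                return lower[n]
        return None

    point_col = pick("prevalence", "point", "estimate", "mean", "value")
    lo_col = pick("lower", "lo", "ci_lower", "prevalence_lo", "lower_95")
    hi_col = pick("upper", "hi", "ci_upper", "prevalence_hi", "upper_95")
    if point_col is None or lo_col is None or hi_col is None:
        # fall back to the first three numeric columns after the code column
        numeric = [c for c in frame.columns if c != code_col and pd.api.types.is_numeric_dtype(frame[c])]
        if len(numeric) < 3:
            raise InputError(f"{path}: could not locate point/lower/upper columns")
        point_col, lo_col, hi_col = numeric[:3]

    out: dict[str, tuple[float, float, float]] = {}
    for idx, row in frame.iterrows():
        if pd.isna(row[point_col]):
            continue
        point, lo, hi = float(row[point_col]), float(row[lo_col]), float(row[hi_col])
        if max(point, lo, hi) > 100:
            raise ValidationError(f"{path}: prevalence above 100 at row {idx}")
        if point > 1:
            point, lo, hi = point / 100, lo / 100, hi / 100
        if not (0 <= lo <= point <= hi <= 1):
            raise ValidationError(
                f"{path}: prevalence CI out of order at row {idx}: "
                f"({lo}, {point}, {hi})"
            )
        out[str(row[code_col]).strip()] = (point, lo, hi)
    return out


def assemble_dataset(
    densities: Mapping[str, Mapping[str, tuple[float, int]]],
    prevalence: Mapping[str, tuple[float, float, float]],
    population: Mapping[str, float],
    income: Mapping[str, str],
    names: Optional[Mapping[str, str]] = None,
    eligible: Optional[Mapping[str, float]] = None,
    adult_fraction: float = DEFAULT_ADULT_FRACTION,
) -> Dataset:
    """Join the per-source mappings into a Dataset.

    ``densities`` is keyed by provider type ("physician", "nurse",
    "pharmacist", "chw"), each mapping iso3 -> (density, year).  A country
    enters the dataset only if it has a physician density, a prevalence
    estimate, a population and an income group; countries failing the rule
    are dropped with a logged reason.  ``population_eligible`` comes from
    ``eligible`` when supplied, else ``population_total * adult_fraction``.
    """
    unknown = set(densities) - set(PROVIDER_TYPES)
    if unknown:
        raise ValidationError(f"unknown provider types {sorted(unknown)}")
    if not 0 < adult_fraction <= 1:
        raise ValidationError(f"adult_fraction must be in (0, 1], got {adult_fraction}")

    physicians = densities.get("physician", {})
    candidates = sorted(
        set(physicians) | set(prevalence) | set(population) | set(income)
    )
    records = []
    for iso3 in candidates:
        missing = [
            label
            for label, present in (
                ("physician density", iso3 in physicians),
                ("prevalence", iso3 in prevalence),
                ("population", iso3 in population),
                ("income group", iso3 in income),
            )
            if not present
        ]
        if missing:
            log.warning("dropping %s: missing %s", iso3, ", ".join(missing))
            continue
        point, lo, hi = prevalence[iso3]
        pop = float(population[iso3])
        optional = {
            f"density_{cadre}": densities[cadre][iso3][0]
            for cadre in ("nurse", "pharmacist", "chw")
            if cadre in densities and iso3 in densities[cadre]
        }
        records.append(
            CountryRecord(
                iso3=iso3,
                name=(names or {}).get(iso3, iso3),
                population_total=pop,
                population_eligible=float(eligible[iso3]) if eligible and iso3 in eligible
                else pop * adult_fraction,
                income_group=income[iso3],
                density_physician=physicians[iso3][0],
                prevalence=point,
                prevalence_lo=lo,
                prevalence_hi=hi,
                **optional,
            )
        )
    if not records:
        raise AssemblyError("no country has all four required fields")
    return Dataset(records=tuple(records))


def _format(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the canonical dataset CSV (missing optional fields as empty cells)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(DATASET_COLUMNS)
        for r in dataset:
            writer.writerow([_format(getattr(r, col)) for col in DATASET_COLUMNS])


def read_dataset(path: str | Path) -> Dataset:
    """Read the canonical dataset CSV written by :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"dataset file not found: {path}")
    records = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or set(DATASET_COLUMNS) - set(reader.fieldnames):
            raise InputError(f"{path}: not a canonical dataset CSV")
        for row in reader:
            kwargs: dict = {"iso3": row["iso3"], "name": row["name"],
                            "income_group": row["income_group"]}
            for col in DATASET_COLUMNS:
                if col in kwargs:
                    continue
                cell = row[col]
                kwargs[col] = None if cell == "" else float(cell)
            records.append(CountryRecord(**kwargs))
    return Dataset(records=tuple(records))
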