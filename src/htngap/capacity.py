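"""Visit demand and provider capacity arithmetic.

Demand side: the number of adults with hypertension in a country is
``prevalence x population_eligible``; annual visit demand multiplies that by
an assumed visit frequency (12, 6, 3 or 1 visits per patient per year).
The 95% CI on demand propagates linearly from the prevalence CI.

Supply side: a provider delivers ``patients_per_day x workdays_per_year``
visit slots annually (4000 at the base throughput of 20 patients/day over
200 workdays; 2000 at the low throughput of 10/day), of which a fixed
fraction (10% by default) is available for hypertension care.  Provider
counts come from cadre densities per 10 000 total population.  Three care
models allocate cadres: physician-only, nonphysician-only (nurses +
pharmacists + community health workers) and team-based (all combined).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .country_data import CountryRecord, ValidationError

VISIT_FREQUENCIES = (12, 6, 3, 1)  # high/base, intermediate, low, minimal
THROUGHPUTS = (20, 10)  # base, low capacity (patients per provider-day)
CARE_MODELS = ("physician_only", "nonphysician_only", "team")

VISIT_LABELS = {12: "high", 6: "intermediate", 3: "low", 1: "minimal"}
THROUGHPUT_LABELS = {20: "base", 10: "low"}


@dataclass(frozen=True)
class CapacityParams:
    """Provider throughput assumptions.

    workdays_per_year: clinic days per provider per year.
    patients_per_day: visit slots per provider per workday.
    hypertension_time_fraction: share of slots spent on hypertension care.
    """

    workdays_per_year: float = 200.0
    patients_per_day: float = 20.0
    hypertension_time_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.workdays_per_year > 0:
            raise ValidationError("workdays_per_year must be > 0")
        if not self.patients_per_day > 0:
            raise ValidationError("patients_per_day must be > 0")
        if not 0 < self.hypertension_time_fraction <= 1:
            raise ValidationError("hypertension_time_fraction must be in (0, 1]")

    @property
    def annual_slots_per_provider(self) -> float:
        """Total visit slots a provider offers per year (all conditions)."""
        return self.patients_per_day * self.workdays_per_year

    @property
    def hypertension_slots_per_provider(self) -> float:
        """Visit slots per provider-year available for hypertension."""
        return self.annual_slots_per_provider * self.hypertension_time_fraction


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the visit-frequency x throughput x care-model grid."""

    visits_per_year: int
    patients_per_day: int
    care_model: str

    def __post_init__(self) -> None:
        if self.visits_per_year not in VISIT_FREQUENCIES:
            raise ValidationError(
                f"visits_per_year must be one of {VISIT_FREQUENCIES}"
            )
        if self.patients_per_day not in THROUGHPUTS:
            raise ValidationError(f"patients_per_day must be one of {THROUGHPUTS}")
        if self.care_model not in CARE_MODELS:
            raise ValidationError(f"care_model must be one of {CARE_MODELS}")

    @property
    def label(self) -> str:
        """Diff-friendly scenario tag, e.g. ``v12_c20_team``."""
        return f"v{self.visits_per_year}_c{self.patients_per_day}_{self.care_model}"

    @classmethod
    def from_label(cls, label: str) -> "ScenarioSpec":
        try:
            v, c, model = label.split("_", 2)
            return cls(int(v[1:]), int(c[1:]), model)
        except (ValueError, IndexError) as exc:
            raise ValidationError(f"bad scenario label {label!r}") from exc


def full_grid() -> tuple[ScenarioSpec, ...]:
    """All 24 scenario cells in canonical order."""
    return tuple(
        ScenarioSpec(v, c, m)
        for v, c, m in product(VISIT_FREQUENCIES, THROUGHPUTS, CARE_MODELS)
    )


@dataclass(frozen=True)
class DemandEstimate:
    """Annual visit demand with CI bounds and the underlying patient count."""

    visits: float
    visits_lo: float
    visits_hi: float
    patients: float

    def __post_init__(self) -> None:
        if not 0 <= self.visits_lo <= self.visits <= self.visits_hi:
            raise ValidationError(
                f"demand CI out of order: ({self.visits_lo}, {self.visits}, "
                f"{self.visits_hi})"
            )


def patients_with_hypertension(record: CountryRecord) -> tuple[float, float, float]:
    """Point and CI patient counts: prevalence x eligible population."""
    n = record.population_eligible
    return (record.prevalence * n, record.prevalence_lo * n, record.prevalence_hi * n)


def annual_demand(
    patients: tuple[float, float, float], visits_per_year: float
) -> DemandEstimate:
    """Annual clinic visits demanded by a patient count at a visit frequency."""
    if not visits_per_year > 0:
        raise ValidationError(f"visits_per_year must be > 0, got {visits_per_year}")
    point, lo, hi = patients
    return DemandEstimate(
        visits=visits_per_year * point,
        visits_lo=visits_per_year * lo,
        visits_hi=visits_per_year * hi,
        patients=point,
    )


def provider_capacity(
    density: float, population_total: float, params: CapacityParams
) -> float:
    """Annual hypertension visits deliverable by one cadre.

    ``density`` is providers per 10 000 total population; capacity is the
    provider count times the per-provider hypertension slots.
    """
    if not density >= 0:
        raise ValidationError(f"density must be >= 0, got {density}")
    providers = density / 10_000 * population_total
    return providers * params.hypertension_slots_per_provider


def care_model_capacity(
    record: CountryRecord, care_model: str, params: CapacityParams
) -> float:
    """Annual hypertension visit supply for a country under one care model.

    Missing nonphysician densities contribute zero capacity rather than
    excluding the country, so team capacity is exactly the sum of the
    physician-only and nonphysician-only capacities.
    """
    if care_model not in CARE_MODELS:
        raise ValidationError(f"unknown care model {care_model!r}")
    nonphys_density = sum(
        record.density(c) or 0.0 for c in ("nurse", "pharmacist", "chw")
    )
    if care_model == "physician_only":
        return provider_capacity(
            record.density_physician, record.population_total, params
        )
    if care_model == "nonphysician_only":
        return provider_capacity(nonphys_density, record.population_total, params)
    # team capacity is defined as the exact sum of the two components
    return provider_capacity(
        record.density_physician, record.population_total, params
    ) + provider_capacity(nonphys_density, record.population_total, params)
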