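"""Per-country visit gaps, income-group aggregation and extreme rankings.

The gap for a country-scenario is ``demand - supply`` in visits per year:
positive means deficit (need exceeds capacity), negative means surplus.
Supply carries no uncertainty, so the gap CI is the demand CI shifted by
the supply.  Aggregates sum member-country gaps exactly (point and both
bounds independently) and report unweighted country-level means of
prevalence and densities with sample SDs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .capacity import (
    CapacityParams,
    ScenarioSpec,
    annual_demand,
    care_model_capacity,
    patients_with_hypertension,
)
from .country_data import (
    INCOME_GROUPS,
    PROVIDER_TYPES,
    CountryRecord,
    Dataset,
    ValidationError,
)

GLOBAL = "GLOBAL"


class ConsistencyError(ValidationError):
    """Results reference unknown or duplicated countries."""


@dataclass(frozen=True)
class GapResult:
    """Demand, supply and gap (visits/year) for one country-scenario."""

    iso3: str
    scenario: ScenarioSpec
    demand: float
    demand_lo: float
    demand_hi: float
    supply: float
    gap: float
    gap_lo: float
    gap_hi: float
    gap_pct: Optional[float]  # None when supply is zero (undefined)
    is_surplus: bool

    def __post_init__(self) -> None:
        if not self.gap_lo <= self.gap <= self.gap_hi:
            raise ValidationError(
                f"{self.iso3}: gap CI out of order "
                f"({self.gap_lo}, {self.gap}, {self.gap_hi})"
            )


@dataclass(frozen=True)
class GroupSummary:
    """Cumulative gap and descriptive statistics for one income group.

    ``cumulative_gap`` and its bounds are raw visits/year (exact sums over
    member countries); reporting in millions is a presentation concern.
    ``mean_density``/``sd_density`` cover countries reporting that cadre;
    SDs are sample SDs and absent for singleton groups.
    """

    income_group: str  # one of INCOME_GROUPS or GLOBAL
    scenario: ScenarioSpec
    cumulative_gap: float
    cumulative_gap_lo: float
    cumulative_gap_hi: float
    n_countries: int
    n_surplus: int
    mean_prevalence: float  # percent
    sd_prevalence: Optional[float]
    mean_density: dict[str, Optional[float]]
    sd_density: dict[str, Optional[float]]


def compute_gap(
    record: CountryRecord,
    scenario: ScenarioSpec,
    params: CapacityParams = CapacityParams(),
) -> GapResult:
    """Gap for one country under one scenario cell.

    The scenario's throughput overrides ``params.patients_per_day``; the
    workdays and time-fraction assumptions come from ``params``.
    """
    effective = replace(params, patients_per_day=scenario.patients_per_day)
    demand = annual_demand(
        patients_with_hypertension(record), scenario.visits_per_year
    )
    supply = care_model_capacity(record, scenario.care_model, effective)
    gap = demand.visits - supply
    return GapResult(
        iso3=record.iso3,
        scenario=scenario,
        demand=demand.visits,
        demand_lo=demand.visits_lo,
        demand_hi=demand.visits_hi,
        supply=supply,
        gap=gap,
        gap_lo=demand.visits_lo - supply,
        gap_hi=demand.visits_hi - supply,
        gap_pct=gap_percentage(demand.visits, supply),
        is_surplus=gap < 0,
    )


def gap_percentage(demand: float, supply: float) -> Optional[float]:
    """Gap as a percentage of supply: ``100 * (demand - supply) / supply``.

    Values above 100 mean demand exceeds twice the supply; negative values
    mean surplus.  With zero supply the percentage is undefined and ``None``
    is returned rather than a number.
    """
    if supply == 0:
        return None
    return 100.0 * (demand - supply) / supply


def _check_one_per_country(gaps: Sequence[GapResult]) -> None:
    codes = [g.iso3 for g in gaps]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ConsistencyError(f"duplicate countries in gap collection: {dupes}")


def _mean_sd(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    mean = sum(values) / len(values)
    if len(values) < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return mean, math.sqrt(var)


def _descriptives(
    members: Sequence[tuple[CountryRecord, GapResult]],
) -> tuple[float, Optional[float], dict, dict]:
    mean_prev, sd_prev = _mean_sd([100.0 * r.prevalence for r, _ in members])
    mean_density: dict[str, Optional[float]] = {}
    sd_density: dict[str, Optional[float]] = {}
    for cadre in PROVIDER_TYPES:
        values = [r.density(cadre) for r, _ in members if r.density(cadre) is not None]
        mean_density[cadre], sd_density[cadre] = _mean_sd(values)
    return (
        mean_prev if mean_prev is not None else float("nan"),
        sd_prev, mean_density, sd_density,
    )


def _summarize(
    label: str,
    scenario: ScenarioSpec,
    members: Sequence[tuple[CountryRecord, GapResult]],
) -> GroupSummary:
    mean_prev, sd_prev, mean_density, sd_density = _descriptives(members)
    return GroupSummary(
        income_group=label,
        scenario=scenario,
        cumulative_gap=sum(g.gap for _, g in members),
        cumulative_gap_lo=sum(g.gap_lo for _, g in members),
        cumulative_gap_hi=sum(g.gap_hi for _, g in members),
        n_countries=len(members),
        n_surplus=sum(1 for _, g in members if g.is_surplus),
        mean_prevalence=mean_prev,
        sd_prevalence=sd_prev,
        mean_density=mean_density,
        sd_density=sd_density,
    )


def aggregate(
    gaps: Sequence[GapResult], dataset: Dataset, scenario: ScenarioSpec
) -> list[GroupSummary]:
    """Income-group summaries plus a GLOBAL row, for one scenario cell.

    The GLOBAL cumulative gap is defined as the sum of the group
    cumulatives (each an exact sum of its member-country gaps), so
    partition conservation holds exactly.
    """
    _check_one_per_country(gaps)
    by_iso3 = {r.iso3: r for r in dataset}
    unknown = [g.iso3 for g in gaps if g.iso3 not in by_iso3]
    if unknown:
        raise ConsistencyError(f"gaps reference unknown countries: {sorted(unknown)}")
    members: dict[str, list[tuple[CountryRecord, GapResult]]] = {
        g: [] for g in INCOME_GROUPS
    }
    for gap in gaps:
        record = by_iso3[gap.iso3]
        members[record.income_group].append((record, gap))
    summaries = [
        _summarize(group, scenario, members[group])
        for group in INCOME_GROUPS
        if members[group]
    ]
    # GLOBAL cumulatives are sums of the group cumulatives, so partition
    # conservation holds exactly rather than up to summation order
    everyone = [pair for group in INCOME_GROUPS for pair in members[group]]
    mean_prev, sd_prev, mean_density, sd_density = _descriptives(everyone)
    summaries.append(
        GroupSummary(
            income_group=GLOBAL,
            scenario=scenario,
            cumulative_gap=sum(s.cumulative_gap for s in summaries),
            cumulative_gap_lo=sum(s.cumulative_gap_lo for s in summaries),
            cumulative_gap_hi=sum(s.cumulative_gap_hi for s in summaries),
            n_countries=sum(s.n_countries for s in summaries),
            n_surplus=sum(s.n_surplus for s in summaries),
            mean_prevalence=mean_prev,
            sd_prevalence=sd_prev,
            mean_density=mean_density,
            sd_density=sd_density,
        )
    )
    return summaries


def count_surplus_countries(gaps: Sequence[GapResult]) -> int:
    """Number of countries whose capacity strictly exceeds demand (gap < 0)."""
    _check_one_per_country(gaps)
    return sum(1 for g in gaps if g.gap < 0)


def rank_extremes(
    gaps: Sequence[GapResult],
) -> tuple[Optional[tuple[str, float]], Optional[tuple[str, float]]]:
    """Largest deficit and largest surplus, ties broken by iso3 order.

    Returns ``(largest_deficit, largest_surplus)``; either is ``None`` when
    no country is in deficit (resp. surplus).
    """
    if not gaps:
        raise ValidationError("rank_extremes requires a non-empty collection")
    _check_one_per_country(gaps)
    deficits = [g for g in gaps if g.gap > 0]
    surpluses = [g for g in gaps if g.gap < 0]
    largest_deficit = None
    if deficits:
        best = min(deficits, key=lambda g: (-g.gap, g.iso3))
        largest_deficit = (best.iso3, best.gap)
    largest_surplus = None
    if surpluses:
        best = min(surpluses, key=lambda g: (g.gap, g.iso3))
        largest_surplus = (best.iso3, best.gap)
    return largest_deficit, largest_surplus
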