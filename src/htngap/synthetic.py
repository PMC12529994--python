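"""Synthetic country-level datasets with the structure of the real inputs.

The generator emulates a 199-country world split 61/64/49/25 across
HIC/UMIC/LMIC/LIC, with income-group-conditional provider densities
(zero-truncated normals), prevalence around 36-40% with 95% CI bounds, a
heavy-tailed (log-uniform) population-size distribution, and
community-health-worker densities missing for roughly half the countries.
Group-level density and prevalence means default to the observed
income-group profiles of the real World Bank / NCD-RisC extracts.

Everything is deterministic given the seed, so downstream stages are
testable without any download.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml
from scipy.stats import truncnorm

from .country_data import (
    INCOME_GROUPS,
    CountryRecord,
    Dataset,
    ValidationError,
)

#: hard cap on generated CHW densities (per 10 000); the observed country
#: maximum in the real data, used to keep the heavy right tail realistic
CHW_DENSITY_CAP = 44.9

#: group counts of the 199-country reference world
DEFAULT_GROUP_COUNTS = {"HIC": 61, "UMIC": 64, "LMIC": 49, "LIC": 25}

# Group-level density means (per 10 000) follow the real income-group
# profile; SDs apply the pooled coefficient of variation of each cadre
# (0.91 physicians, 1.14 nurses, 1.21 pharmacists) to the group mean.
# CHW densities use the pooled (mean, sd) for every group: the real data
# show no clean income gradient for that cadre.
DEFAULT_DENSITY_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "LIC": {"physician": (1.9, 1.7), "nurse": (14.8, 16.9),
            "pharmacist": (0.6, 0.7), "chw": (3.4, 7.3)},
    "LMIC": {"physician": (7.8, 7.1), "nurse": (20.8, 23.8),
             "pharmacist": (1.7, 2.0), "chw": (3.4, 7.3)},
    "UMIC": {"physician": (20.7, 18.8), "nurse": (40.8, 46.7),
             "pharmacist": (3.1, 3.7), "chw": (3.4, 7.3)},
    "HIC": {"physician": (33.8, 30.6), "nurse": (88.7, 101.5),
            "pharmacist": (8.0, 9.7), "chw": (3.4, 7.3)},
}

#: per group: (mean %, sd %, CI half-width in percentage points)
DEFAULT_PREVALENCE_PARAMS: dict[str, tuple[float, float, float]] = {
    "LIC": (36.7, 4.8, 6.0),
    "LMIC": (36.1, 5.7, 6.0),
    "UMIC": (40.3, 6.7, 6.0),
    "HIC": (36.2, 7.0, 6.0),
}

#: CHW data exist for 96 of 199 countries in the real extract
DEFAULT_CHW_MISSING_PROB = 103 / 199

#: prevalence draws are clipped to this percent band before use
PREVALENCE_CLIP = (5.0, 80.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic world."""

    n_countries_by_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS)
    )
    density_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            g: dict(v) for g, v in DEFAULT_DENSITY_PARAMS.items()
        }
    )
    prevalence_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_PARAMS)
    )
    chw_missing_prob: float = DEFAULT_CHW_MISSING_PROB
    population_range: tuple[float, float] = (1e4, 1.4e9)
    adult_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for group, n in self.n_countries_by_group.items():
            if group not in INCOME_GROUPS:
                raise ValidationError(f"unknown income group {group!r}")
            if n < 0 or n != int(n):
                raise ValidationError(f"{group}: country count must be a non-negative integer")
        if sum(self.n_countries_by_group.values()) == 0:
            raise ValidationError("at least one country is required")
        for group, cadres in self.density_params.items():
            for cadre, (mean, sd) in cadres.items():
                if mean < 0 or sd < 0:
                    raise ValidationError(
                        f"{group}/{cadre}: density mean and sd must be >= 0"
                    )
        for group, (mean, sd, hw) in self.prevalence_params.items():
            if mean < 0 or sd < 0 or hw < 0:
                raise ValidationError(f"{group}: prevalence params must be >= 0")
        if not 0 <= self.chw_missing_prob <= 1:
            raise ValidationError("chw_missing_prob must be in [0, 1]")
        lo, hi = self.population_range
        if not 0 < lo <= hi:
            raise ValidationError("population_range must satisfy 0 < min <= max")
        if not 0 < self.adult_fraction <= 1:
            raise ValidationError("adult_fraction must be in (0, 1]")


def default_config(seed: int = 0) -> GeneratorConfig:
    """The 199-country reference configuration."""
    return GeneratorConfig(seed=seed)


def config_from_dict(data: Mapping, seed: Optional[int] = None) -> GeneratorConfig:
    """Build a config from a partial mapping; omitted fields keep defaults."""
    base = default_config()
    kwargs: dict = {}
    if "n_countries_by_group" in data:
        kwargs["n_countries_by_group"] = dict(data["n_countries_by_group"])
    if "density_params" in data:
        merged = {g: dict(v) for g, v in base.density_params.items()}
        for group, cadres in data["density_params"].items():
            merged.setdefault(group, {}).update(
                {c: tuple(p) for c, p in cadres.items()}
            )
        kwargs["density_params"] = merged
    if "prevalence_params" in data:
        merged_p = dict(base.prevalence_params)
        merged_p.update({g: tuple(p) for g, p in data["prevalence_params"].items()})
        kwargs["prevalence_params"] = merged_p
    for key in ("chw_missing_prob", "adult_fraction"):
        if key in data:
            kwargs[key] = float(data[key])
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "population_range" in data:
        # YAML 1.1 reads floats like 1.0e5 as strings; coerce explicitly
        kwargs["population_range"] = tuple(float(x) for x in data["population_range"])
    if seed is not None:
        kwargs["seed"] = seed
    return GeneratorConfig(**kwargs)


def load_config(path: str | Path, seed: Optional[int] = None) -> GeneratorConfig:
    """Read a YAML or JSON config file; every field is optional."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path}: config must be a mapping")
    return config_from_dict(data, seed=seed)


def _code(index: int) -> str:
    """Deterministic synthetic 3-letter code for country number ``index``."""
    a, rem = divmod(index, 26 * 26)
    b, c = divmod(rem, 26)
    return "".join(chr(ord("A") + x) for x in (a, b, c))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draws from a normal(mean, sd) truncated to [0, inf)."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Draw one synthetic Dataset; identical seeds give identical datasets."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.population_range
    records: list[CountryRecord] = []
    index = 0
    for group in INCOME_GROUPS:  # fixed order => reproducible streams
        n = int(config.n_countries_by_group.get(group, 0))
        if n == 0:
            continue
        population = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
        cadres = config.density_params[group]
        density = {
            cadre: _truncated_normal(rng, *cadres[cadre], n)
            for cadre in ("physician", "nurse", "pharmacist")
        }
        chw = np.minimum(_truncated_normal(rng, *cadres["chw"], n), CHW_DENSITY_CAP)
        chw_missing = rng.random(n) < config.chw_missing_prob
        mean, sd, half_width = config.prevalence_params[group]
        prevalence = np.clip(rng.normal(mean, sd, n), *PREVALENCE_CLIP) / 100.0
        hw = half_width / 100.0
        for i in range(n):
            records.append(
                CountryRecord(
                    iso3=_code(index),
                    name=f"Synthetic {_code(index)}",
                    population_total=float(population[i]),
                    population_eligible=float(population[i]) * config.adult_fraction,
                    income_group=group,
                    density_physician=float(density["physician"][i]),
                    density_nurse=float(density["nurse"][i]),
                    density_pharmacist=float(density["pharmacist"][i]),
                    density_chw=None if chw_missing[i] else float(chw[i]),
                    prevalence=float(prevalence[i]),
                    prevalence_lo=float(max(0.0, prevalence[i] - hw)),
                    prevalence_hi=float(min(1.0, prevalence[i] + hw)),
                )
            )
            index += 1
    return Dataset(records=tuple(records))
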