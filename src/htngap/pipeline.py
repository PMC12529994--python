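"""End-to-end run orchestration: dataset -> scenario grid -> CSV artifacts.

A run takes one dataset (a canonical CSV, or a freshly generated synthetic
world when no input is given), evaluates every requested scenario cell for
every country, and writes three artifacts to the output directory:

* ``per_country.csv``  - one row per country-scenario with demand, supply,
  gap, CI bounds, gap percentage and surplus flag;
* ``group_summary.csv`` - one row per scenario x (income group + GLOBAL);
* ``manifest.json``    - input checksum, parameter values and tool version.

Outputs are a pure function of (inputs, config, seed): re-running an
identical invocation reproduces every byte.
"""
from __future__ import annotations

import csv
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .capacity import CapacityParams, ScenarioSpec, full_grid
from .country_data import (
    Dataset,
    InputError,
    PROVIDER_TYPES,
    ValidationError,
    read_dataset,
)
from .gaps import GapResult, GroupSummary, aggregate, compute_gap
from .synthetic import default_config, generate_dataset

log = logging.getLogger(__name__)

PER_COUNTRY_CSV = "per_country.csv"
GROUP_SUMMARY_CSV = "group_summary.csv"
MANIFEST_JSON = "manifest.json"

PER_COUNTRY_COLUMNS = (
    "iso3",
    "income_group",
    "scenario",
    "visits_per_year",
    "patients_per_day",
    "care_model",
    "demand",
    "demand_lo",
    "demand_hi",
    "supply",
    "gap",
    "gap_lo",
    "gap_hi",
    "gap_pct",
    "is_surplus",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: Path
    input: Optional[Path] = None  # canonical dataset CSV; None => synthetic
    scenarios: tuple[ScenarioSpec, ...] = field(default_factory=full_grid)
    params: CapacityParams = field(default_factory=CapacityParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValidationError("scenario subset must be non-empty")


@dataclass(frozen=True)
class RunArtifacts:
    """Paths and in-memory results of a completed run."""

    outdir: Path
    dataset: Dataset
    gaps: dict[str, tuple[GapResult, ...]]  # scenario label -> per-country gaps
    summaries: dict[str, tuple[GroupSummary, ...]]

    @property
    def per_country_path(self) -> Path:
        return self.outdir / PER_COUNTRY_CSV

    @property
    def group_summary_path(self) -> Path:
        return self.outdir / GROUP_SUMMARY_CSV

    @property
    def manifest_path(self) -> Path:
        return self.outdir / MANIFEST_JSON


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _dataset_checksum(dataset: Dataset) -> str:
    buffer = io.StringIO()
    for r in dataset:
        buffer.write(repr(r))
        buffer.write("\n")
    return hashlib.sha256(buffer.getvalue().encode()).hexdigest()


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Execute the full grid and write all artifacts atomically-in-spirit.

    All gaps and aggregates are computed before any file is opened, so a
    failing scenario cell aborts the run with no partial outputs.
    """
    if config.input is not None:
        if not Path(config.input).exists():
            raise InputError(f"input dataset not found: {config.input}")
        dataset = read_dataset(config.input)
        source = str(config.input)
        checksum = hashlib.sha256(Path(config.input).read_bytes()).hexdigest()
    else:
        dataset = generate_dataset(default_config(seed=config.seed))
        source = f"synthetic(seed={config.seed})"
        checksum = _dataset_checksum(dataset)
    log.info("running %d scenario cells over %d countries",
             len(config.scenarios), len(dataset))

    gaps: dict[str, tuple[GapResult, ...]] = {}
    summaries: dict[str, tuple[GroupSummary, ...]] = {}
    for scenario in config.scenarios:
        cell = tuple(compute_gap(r, scenario, config.params) for r in dataset)
        gaps[scenario.label] = cell
        summaries[scenario.label] = tuple(aggregate(cell, dataset, scenario))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    group_of = {r.iso3: r.income_group for r in dataset}

    with open(outdir / PER_COUNTRY_CSV, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(PER_COUNTRY_COLUMNS)
        for scenario in config.scenarios:
            for g in gaps[scenario.label]:
                writer.writerow([
                    g.iso3, group_of[g.iso3], scenario.label,
                    scenario.visits_per_year, scenario.patients_per_day,
                    scenario.care_model,
                    _fmt(g.demand), _fmt(g.demand_lo), _fmt(g.demand_hi),
                    _fmt(g.supply), _fmt(g.gap), _fmt(g.gap_lo), _fmt(g.gap_hi),
                    _fmt(g.gap_pct), _fmt(g.is_surplus),
                ])

    with open(outdir / GROUP_SUMMARY_CSV, "w", newline="") as handle:
        writer = csv.writer(handle)
        header = [
            "scenario", "income_group", "n_countries", "n_surplus",
            "cumulative_gap", "cumulative_gap_lo", "cumulative_gap_hi",
            "mean_prevalence_pct", "sd_prevalence_pct",
        ]
        for cadre in PROVIDER_TYPES:
            header += [f"mean_density_{cadre}", f"sd_density_{cadre}"]
        writer.writerow(header)
        for scenario in config.scenarios:
            for s in summaries[scenario.label]:
                row = [
                    scenario.label, s.income_group, s.n_countries, s.n_surplus,
                    _fmt(s.cumulative_gap), _fmt(s.cumulative_gap_lo),
                    _fmt(s.cumulative_gap_hi),
                    _fmt(s.mean_prevalence), _fmt(s.sd_prevalence),
                ]
                for cadre in PROVIDER_TYPES:
                    row += [_fmt(s.mean_density[cadre]), _fmt(s.sd_density[cadre])]
                writer.writerow(row)

    manifest = {
        "tool": "htngap",
        "version": __version__,
        "input": source,
        "input_sha256": checksum,
        "seed": config.seed,
        "n_countries": len(dataset),
        "chw_coverage": dataset.chw_coverage,
        "params": {
            "workdays_per_year": config.params.workdays_per_year,
            "hypertension_time_fraction": config.params.hypertension_time_fraction,
        },
        "scenarios": [s.label for s in config.scenarios],
        "outputs": [PER_COUNTRY_CSV, GROUP_SUMMARY_CSV],
    }
    with open(outdir / MANIFEST_JSON, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")

    return RunArtifacts(outdir=outdir, dataset=dataset, gaps=gaps,
                        summaries=summaries)


def _read_per_country(indir: Path) -> list[dict]:
    path = Path(indir) / PER_COUNTRY_CSV
    if not path.exists():
        raise InputError(f"run artifact not found: {path}")
    rows = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or set(PER_COUNTRY_COLUMNS) - set(reader.fieldnames):
            raise InputError(f"{path}: malformed per-country artifact")
        for row in reader:
            try:
                for col in ("demand", "demand_lo", "demand_hi", "supply",
                            "gap", "gap_lo", "gap_hi"):
                    row[col] = float(row[col])
                row["gap_pct"] = float(row["gap_pct"]) if row["gap_pct"] else None
                row["is_surplus"] = row["is_surplus"] == "True"
            except ValueError as exc:
                raise InputError(f"{path}: malformed row {row['iso3']}") from exc
            rows.append(row)
    return rows


def _millions(visits: float) -> str:
    return f"{visits / 1e6:,.1f}"


def summarize_run(indir: str | Path, sign: int = 1) -> str:
    """Human-readable summary recomputed from the per-country artifact.

    Per scenario: global cumulative gap with CI (millions of visits/year),
    per-group cumulative gaps, surplus-country count, and the extreme
    countries.  ``sign=+1`` reports deficits as positive numbers;
    ``sign=-1`` flips the presentation (surpluses positive).
    """
    if sign not in (1, -1):
        raise ValidationError("sign must be +1 or -1")
    rows = _read_per_country(Path(indir))
    scenarios: dict[str, list[dict]] = {}
    for row in rows:
        scenarios.setdefault(row["scenario"], []).append(row)

    convention = "deficit" if sign == 1 else "surplus"
    lines = [
        f"htngap run summary ({len(scenarios)} scenario cells, "
        f"positive = {convention})",
    ]
    for label, cell in scenarios.items():
        total = sum(r["gap"] for r in cell)
        lo = sum(r["gap_lo"] for r in cell)
        hi = sum(r["gap_hi"] for r in cell)
        if sign == -1:
            total, lo, hi = -total, -hi, -lo
        n_surplus = sum(1 for r in cell if r["gap"] < 0)
        lines.append("")
        lines.append(f"scenario {label}: {len(cell)} countries")
        lines.append(
            f"  global cumulative gap: {_millions(total)} million visits/yr "
            f"(95% CI {_millions(lo)} to {_millions(hi)})"
        )
        by_group: dict[str, float] = {}
        for r in cell:
            by_group[r["income_group"]] = by_group.get(r["income_group"], 0.0) + r["gap"]
        for group in sorted(by_group):
            lines.append(
                f"  {group}: {_millions(sign * by_group[group])} million visits/yr"
            )
        lines.append(f"  countries in surplus: {n_surplus}")
        deficits = [r for r in cell if r["gap"] > 0]
        surpluses = [r for r in cell if r["gap"] < 0]
        if deficits:
            worst = min(deficits, key=lambda r: (-r["gap"], r["iso3"]))
            lines.append(
                f"  largest deficit: {worst['iso3']} "
                f"({_millions(worst['gap'])} million visits/yr)"
            )
        if surpluses:
            best = min(surpluses, key=lambda r: (r["gap"], r["iso3"]))
            lines.append(
                f"  largest surplus: {best['iso3']} "
                f"({_millions(-best['gap'])} million visits/yr)"
            )
    return "\n".join(lines) + "\n"


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML run config; keyword overrides win over file values."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: run config must be a mapping")
    kwargs: dict = {}
    if "input" in data and data["input"] is not None:
        kwargs["input"] = Path(data["input"])
    if "outdir" in data:
        kwargs["outdir"] = Path(data["outdir"])
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "scenarios" in data and data["scenarios"] is not None:
        kwargs["scenarios"] = tuple(
            ScenarioSpec.from_label(s) for s in data["scenarios"]
        )
    params_data = data.get("params", {})
    if params_data:
        kwargs["params"] = CapacityParams(
            workdays_per_year=params_data.get("workdays_per_year", 200.0),
            patients_per_day=params_data.get("patients_per_day", 20.0),
            hypertension_time_fraction=params_data.get(
                "hypertension_time_fraction", 0.10
            ),
        )
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    if "outdir" not in kwargs:
        raise ValidationError("run config must set an output directory")
    return RunConfig(**kwargs)
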