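# htngap

Country-level supply–demand gap modelling for hypertension care.

More than a billion adults live with hypertension, and long-term blood
pressure control hinges on regular clinic follow-up — which many health
systems cannot staff if care relies on physicians alone. `htngap` is for
health-workforce and NCD-policy analysts who want to quantify that
mismatch: for each country it computes the annual clinic visits the
hypertensive population needs, the visits the workforce can deliver, and
the gap between the two, across a grid of assumptions and care models.

## Model

For a country with eligible population *N*ₑ, prevalence *p* (95% CI
[*p*ₗₒ, *p*ₕᵢ]), total population *N* and provider density *ρ* per 10 000:

- **demand**  D = v · p · Nₑ, with visit frequency v ∈ {12, 6, 3, 1}
  visits/patient/year;
- **supply**  S = (ρ / 10 000) · N · c · w · f, with throughput
  c ∈ {20, 10} patients/day, w = 200 workdays/year and f = 0.10 of
  provider time on hypertension (so 400 or 200 hypertension visit slots
  per provider-year);
- **gap**  G = D − S (positive = deficit), with a CI propagated linearly
  from the prevalence CI.

Three care models choose ρ: physician-only, nonphysician-only (nurses +
pharmacists + community health workers) and team-based (all cadres). The
full grid is 4 × 2 × 3 = 24 scenario cells; results aggregate to World
Bank income groups (LIC/LMIC/UMIC/HIC, GNI/capita ≤1085 / ≤4255 / ≤13845 /
above US$) and globally. A bundled synthetic-data generator reproduces the
statistical structure of the real World Bank / NCD-RisC inputs (199
countries, income-group density and prevalence profiles, half-missing
community-health-worker data) so everything runs offline; see
`docs/methods.md` for the full model account.

## Worked example

```sh
htngap generate --seed 1 --out world.csv
htngap run --input world.csv --outdir run \
    --scenarios v12_c20_physician_only,v12_c20_team
htngap report --indir run
```

prints (synthetic world, seed 1):

```
scenario v12_c20_physician_only: 199 countries
  global cumulative gap: 49,400.5 million visits/yr (95% CI 38,401.3 to 60,399.7)
  HIC: 8,987.6 million visits/yr
  LIC: 10,373.7 million visits/yr
  LMIC: 13,735.2 million visits/yr
  UMIC: 16,304.1 million visits/yr
  countries in surplus: 12
  largest deficit: ADM (4,271.2 million visits/yr)
  largest surplus: AFO (264.4 million visits/yr)

scenario v12_c20_team: 199 countries
  global cumulative gap: -24,247.2 million visits/yr (95% CI -35,246.4 to -13,248.0)
  ...
  countries in surplus: 110
```

Reading: under monthly visits delivered by physicians alone
(`v12_c20_physician_only`), every income group shows a cumulative deficit
— a global shortfall of ~49.4 billion visits/year against physician
capacity, with only 12 (high-density) countries in surplus. Switching the
same demand to team-based care (`v12_c20_team`) turns the global balance
into a net surplus and puts 110 countries in surplus, though LIC and LMIC
remain in deficit — the capacity case for task-sharing. Per-country and
per-group numbers land in `run/per_country.csv` and
`run/group_summary.csv`; `run/manifest.json` records input checksums and
parameters, and identical invocations reproduce identical bytes.

The same machinery is available as a library:

```python
from htngap import ScenarioSpec, compute_gap, default_config, generate_dataset

world = generate_dataset(default_config(seed=1))
gap = compute_gap(world.records[0], ScenarioSpec(12, 20, "team"))
print(gap.gap, gap.is_surplus)
```

Real World Bank indicator CSVs (long or wide layout) and NCD-RisC-style
prevalence tables are ingested with `read_density_table`,
`read_prevalence_table`, `classify_income` and `assemble_dataset`.

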