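# Methods

## Model

htngap compares, country by country, the annual number of hypertension
clinic visits a population needs with the number its health workforce can
deliver.

**Demand.** For a country with eligible (adult) population `N_e` and
hypertension prevalence `p` (with 95% CI `[p_lo, p_hi]`), the patient count
is `H = p · N_e` and the annual visit demand under a visit-frequency
scenario `v` is

    D = v · H = v · p · N_e,   v ∈ {12, 6, 3, 1} visits/patient/year.

The four frequencies span monthly follow-up (common where visits double as
medication refills), quarterly/biannual schedules, and a minimal one visit
per year. The demand CI is obtained by substituting `p_lo` and `p_hi`
for `p`; since the map is linear in `p` this propagation is exact.

**Supply.** A provider offers `c · w` visit slots per year (`c` patients
per workday, `w` workdays), of which a fraction `f` goes to hypertension
care:

    S = (ρ / 10 000) · N · c · w · f,

where `ρ` is the relevant provider density per 10 000 *total* population
`N`. Defaults are `w = 200` workdays, `f = 0.10`, and `c ∈ {20, 10}`
(base and low throughput), giving 4 000 or 2 000 annual slots per provider
and 400 or 200 hypertension-effective slots. Three care models choose `ρ`:
physician-only, nonphysician-only (nurses + pharmacists + community health
workers, missing cadres contributing zero), and team-based (all cadres).
Team supply is computed as the exact sum of the physician-only and
nonphysician-only supplies, so additivity holds bitwise.

**Gap.** `G = D − S`, positive = deficit, negative = surplus (a zero gap is
balanced, counted in neither). Supply carries no uncertainty, so
`[G_lo, G_hi] = [D_lo − S, D_hi − S]`. The percentage gap is
`100 · (D − S) / S`, undefined (reported as empty, not a number) when
`S = 0`. The full grid is 4 visit frequencies × 2 throughputs × 3 care
models = 24 cells per country.

## Assumptions and their consequences

- All prevalent patients generate demand, not only diagnosed or treated
  ones; the estimates are therefore need-based ceilings.
- The 10% time fraction applies identically to every cadre. It is a crude
  stand-in for case-mix and likely optimistic for physicians in
  high-burden settings.
- Provider densities refer to total population while patient counts use the
  eligible population; the eligible share is an explicit, configurable
  field (`adult_fraction`, default 0.6) because prevalence sources cover
  adults (30+) while workforce densities do not.
- No visit-duration, referral, comorbidity or urban/rural structure is
  modelled; the analysis is deliberately country-level arithmetic.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `visits_per_year` | visits/patient/yr | grid {12,6,3,1} | follow-up schedule scenarios |
| `patients_per_day` | visits/provider/day | 20 (base), 10 (low) | throughput scenarios |
| `workdays_per_year` | days | 200 | working year net of leave/admin |
| `hypertension_time_fraction` | proportion | 0.10 | share of clinic time on hypertension |
| `adult_fraction` | proportion | 0.6 | eligible share of total population |
| income thresholds | US$ GNI/capita | ≤1085 / ≤4255 / ≤13845 | World Bank 2023 classification, upper-inclusive |

## Synthetic data generator

The generator produces worlds with the statistical structure of the real
country-level inputs so the pipeline is testable offline:

- 199 countries split 61/64/49/25 across HIC/UMIC/LMIC/LIC (configurable);
- provider densities drawn per income group from zero-truncated normals.
  Group means follow the observed income gradient (physicians
  1.9/7.8/20.7/33.8 per 10 000 from LIC to HIC, nurses 14.8/20.8/40.8/88.7,
  pharmacists 0.6/1.7/3.1/8.0). Group-level SDs are not published anywhere
  we know of, so each cadre's pooled coefficient of variation (≈0.91
  physicians, 1.14 nurses, 1.21 pharmacists) is applied to the group mean.
  Truncation at zero is mandatory — nurse SDs exceed their means — and
  shifts the realised mean upward; tests correct for this with an
  independent Monte-Carlo oracle rather than adjusting the generator;
- community-health-worker densities use the pooled mean ± SD (3.4 ± 7.3)
  in every group, capped at 44.9 per 10 000 (the observed country maximum),
  and are set missing with probability 103/199 so expected coverage
  matches the 96-of-199 coverage of the real extract;
- prevalence is drawn per group on the percent scale (means
  36.7/36.1/40.3/36.2, SDs 4.8/5.7/6.7/7.0 from LIC to HIC), clipped to
  [5, 80]% and converted to a proportion; the 95% CI is point ± a fixed
  6-percentage-point half-width (configurable) clipped to [0, 1], as CI
  widths are not published;
- population is log-uniform over [10⁴, 1.4·10⁹] to mimic the heavy-tailed
  country-size distribution.

What the generator does **not** emulate: correlations between indicators
(GNI–density, density–prevalence), the real total world population (the
log-uniform draw sums to ~25bn rather than 8bn, so absolute visit totals
are not comparable to real-data runs), country identities, and temporal
structure. Passing tests on synthetic data therefore validate the
arithmetic, orderings and uncertainty propagation — not the real-world
magnitudes, which require the real World Bank / NCD-RisC inputs.

## Numerical choices

- All internal quantities are unrounded doubles; rounding (millions, one
  decimal) happens only in the text report.
- Cumulative gaps are plain ordered sums of member-country gaps; the GLOBAL
  row is defined as the sum of the four income-group cumulatives, making
  partition conservation exact by construction rather than up to
  float-summation order.
- Surplus is strict (`gap < 0`); extreme-country ties break on the
  lexicographically smaller ISO3 code.
- Demand/supply formulas are evaluated in a fixed association order so
  independent scalar recomputation reproduces them bit-for-bit (exercised
  over 100 seeded small worlds in the test suite).
- The canonical dataset CSV writes floats via `repr`, so a write/read
  round-trip reproduces every field exactly.
- Degenerate inputs: zero prevalence gives zero demand (every country in
  surplus wherever any provider exists); zero densities give zero supply
  and an undefined percentage gap; a zero-width prevalence CI collapses the
  gap CI to a point.

## Design choices where the design was open

- **Sign convention.** Gap = demand − supply with positive = deficit; the
  report subcommand offers `--sign surplus-positive` for the opposite
  presentation, but the data model keeps one fixed convention so
  monotonicity invariants are unambiguous.
- **Latest-year density selection.** World Bank indicator tables carry many
  years with gaps; the reader keeps each country's most recent non-missing
  value and its year.
- **Percent-vs-proportion detection.** Prevalence rows with a point
  estimate above 1 are treated as percentages; NCD-RisC-style files ship
  percent, internal fixtures use proportions.
- **Group descriptives.** Mean prevalence and densities per income group
  are unweighted country-level means with sample SD (density means cover
  only countries reporting that cadre), matching how such tables are
  usually summarised; population weighting would be dominated by a handful
  of large countries.
- **Missing nonphysician data.** Treated as zero capacity rather than
  dropping the country, keeping all countries in team-based results at the
  cost of understating nonphysician supply where data are merely absent.

## Test problem sizes

The default suite runs entirely on generated data: the 199-country
reference world for end-to-end checks, 100 seeded 10-country worlds for the
bit-exact oracle sweep, 500 countries per income group (2 000 total) for
parameter recovery with 10⁶-draw Monte-Carlo reference moments, and a few
hundred property-based examples per invariant. The whole suite completes in
a few seconds on one CPU.

## Known limitations

- Real-data replication needs the upstream World Bank / NCD-RisC files;
  the readers accept their layouts but no download is performed.
- The generator's independence assumptions understate between-indicator
  structure; group-level contrasts are faithful, joint distributions are
  not.
- The uncertainty interval reflects prevalence uncertainty only; workforce
  densities and the throughput constants enter as fixed scenario values.
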