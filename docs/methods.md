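# Methods

## Model

The package implements a human-capital costing of premature mortality.
Every death before age 80 in the reference year is assigned a
counterfactual life course by matching it, uniformly at random and with
replacement, to a person in a dynamic-microsimulation population panel
who is alive in the matching year and shares the decedent's matching
cell: 5-year age band (0–4 … 75–79), sex, and SES quintile. The matched
trajectory supplies, per decedent:

- years of life lost, `YLL = min(cf_death_year, horizon) − death_year`,
  where `cf_death_year` is the first year the match's alive flag is
  false; a match surviving past the horizon contributes
  `horizon − death_year`;
- FTE working years, `Σ weekly_hours × 52 / 1976` over the in-scope
  years;
- a present value of lifetime income,
  `PVLI = Σ_t y_t ((1+g)/(1+r))^(t−base)`, with growth applied to the
  real stream and discounting to the grown stream (the conventional
  composition; with `g = r` the PVLI is the plain sum), then multiplied
  by a scalar CPI factor for reporting-year dollars.

The random matching is replicated (default R = 100) with seeds
`base_seed XOR r`; statistics are replicate means and 95% percentile
confidence intervals, computed per stratum by summing within each
replicate first and then taking the mean and the 2.5th/97.5th
percentiles across replicates (NumPy's linear-interpolation percentile).

## Parameters

| parameter | default | meaning |
|---|---|---|
| wage growth `g` | 0.01 /yr | real income growth above inflation |
| discount rate `r` | 0.03 /yr | annual discounting of future income |
| base year / horizon | 2003 / 2030 | valuation origin and truncation |
| standard working year | 1976 h | 38 h/week × 52 weeks; FTE denominator |
| CPI factor | 1.0 | base-year → reporting-year dollars; user-supplied for real CPI series |
| premature-age cut-off | 80 | deaths at 80+ are out of scope |
| replicates R | 100 | matching-uncertainty resampling |

Conventions that the source material leaves open, fixed here and
configurable where numeric:

- The death year itself counts as a full year of potential work and
  income (matching at the start of the year); the matched person's own
  death year counts as zero (death at the start of that year). These are
  the conservative ends of the within-year ambiguity.
- The standard working year (1976 h) and weeks per year (52) are
  repository defaults, echoed into every output header.
- Matching is with replacement because a decedent cohort can exceed a
  cell's candidate count in a 1% population sample.
- When a cell is empty the relaxation ladder is: (1) merge adjacent SES
  quintiles, (2) additionally widen the age band by ±5 years, (3) drop
  SES. Age and sex, the strongest predictors of labour-market outcomes,
  are preserved longest; every relaxed match is logged with its level.
- Display rounding is round-half-up (so 81.5% renders as 82%) and is
  display-only; all shares are computed from unrounded internals.

## Site grouping

Cancer deaths are underlying-cause ICD-10 codes C00–C97; subcodes
classify by their three-character category. The default site map groups
the categories into 26 named sites plus "Other malignant neoplasms"
using standard WHO groupings, forming an exact partition of C00–C97
(verified exhaustively in the tests). Two caveats: the liver-cancer
label excludes hepatitis-related cases in name only — the exclusion is
not derivable from the cause code, so the map uses plain C22; and C97
(independent multiple primaries) goes to the catch-all. A user-supplied
CSV (site_label, code_start, code_end) overrides the default map.

## Synthetic data

The generator stands in for two confidential inputs.

*Mortality dataset*: cell membership is multinomial on the published
(age band × sex) death counts; age is uniform over the band's integer
ages (only banded counts are published); the site is drawn from the
published per-site death counts and the ICD-10 code uniformly from the
site's categories; SES is uniform over quintiles (the published tables
do not stratify deaths by SES).

*Population panel*: initial ages uniform 0–89, sexes balanced, SES
uniform. Employment is a persistent per-person draw against sex- and
age-specific participation (71.3% men / 55.8% women at ages 15–64, zero
outside — the 2003 rates); part-time status is a per-person draw (15%
of working men, 44% of working women — chosen to be realistic for 2003
Australia) between 19 and 38 weekly hours. A working person's income is
a sex×SES full-time base wage (stylised five-point gradients with a 15%
gender gap), scaled by relative hours and a person-level lognormal
factor (σ = 0.3, mean-one; the income-dispersion family is a free
parameter, not an inferred quantity), growing at 1% per year in real
terms. Survival follows Gompertz-shaped annual hazards in 10-year age
bands with ~40% male excess; hours and income are zero from the death
year onward.

What the panel does **not** emulate: labour-force entry/exit dynamics
(employment is persistent, not transitional), retirement behaviour
beyond the participation age cut-off, household structure, migration,
cohort trends in female participation, and income autocorrelation beyond
the persistent person effect. Passing tests therefore demonstrate the
correctness of the costing arithmetic, matching and aggregation under a
structurally faithful panel — not the empirical accuracy of any absolute
dollar total, which depends on the real registry and microsimulation.

## Numerical choices

- Accumulation is vectorised as (person × year) contribution matrices
  with prefix sums; the per-trajectory functions define the reference
  semantics and the two paths are cross-checked in the tests, alongside
  an independent brute-force per-person-year enumeration.
- Percentile CIs use linear interpolation between order statistics; a
  single replicate yields a degenerate interval equal to the mean.
- Matching iterates decedents in id order so an assignment is a pure
  function of (deaths, cells, seed).
- Degenerate inputs: an empty cohort produces empty outputs and zeroed
  report tables (with a logged warning); a decedent with no candidate
  after the full relaxation ladder raises a hard error naming them.

## Problem sizes

Unit and acceptance tests use a 2,000-person panel with cohorts of a few
hundred deaths, and 100 replicates where the replication contract itself
is under test; the acceptance script runs the published cohort size
(25,733 deaths, 20,000-person panel, 100 replicates), which completes in
well under a minute on one CPU. These sizes give multinomial/binomial
tolerances (3 SE) and chi-square uniformity checks (α = 0.001) ample
power while keeping runs quick.

## Known limitations

- Morbidity and carer productivity costs are out of scope; only
  mortality is costed.
- Unpaid/household labour is not valued.
- The truncation at 2030 makes totals conservative; at `r = 3%` a
  payment 29 years out is discounted by more than 57% of face value.
- Correlations between cause of death and other mortality risks (e.g.
  smoking) are captured only insofar as age/sex/SES carry them, which
  may overstate counterfactual survival for some sites.
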