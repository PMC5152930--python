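"""Run the full costing: match, accumulate, value, aggregate.

Each decedent is matched at random to a panel person in the same
(5-year age band, sex, SES quintile) cell; the match's simulated life
supplies the counterfactual years of life, FTE working years and income
stream, valued with 1% real wage growth and a 3% discount rate to 2030.
Matching is replicated 20 times; results are replicate means with 95%
percentile confidence intervals.
"""

from mortcost import (
    EconomicParams,
    MortalitySpec,
    PanelSpec,
    aggregate,
    generate_mortality_dataset,
    generate_population_panel,
    run_pipeline,
)

deaths = generate_mortality_dataset(MortalitySpec(n_deaths=2000, seed=11))
panel = generate_population_panel(PanelSpec(n_persons=10_000, seed=12))
result = run_pipeline(deaths, panel, n_replicates=20, base_seed=13, params=EconomicParams())

totals = aggregate(result.outcomes)
print(totals.to_string(index=False))
print("\nPer-site PVLI (top 5, $):")
by_site = aggregate(result.outcomes, ["site"], values=("pvli",))
print(by_site.nlargest(5, "mean").to_string(index=False))
# yll is total years of life lost to 2030 across the cohort; working_years
# the FTE years of market work forgone; pvli the present value (2003) of
# the income those years would have produced.
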