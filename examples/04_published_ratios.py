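"""Recompute the ratio arithmetic of the published summary tables.

The published tables are inputs here; the shares, per-death costs and
scenario savings are recomputed through the reporting operations.
"""

from mortcost import per_death_cost, published, round_half_up, scenario_savings, share_of_total

t1 = published.deaths_yll_by_age_sex()
t3 = published.site_burden().set_index("site")
pvli_all = published.PVLI_TOTALS_M["All"]

male = t1[t1["sex"] == "M"]
print(f"male share of deaths: {round_half_up(share_of_total(male['deaths'].sum(), t1['deaths'].sum())):.0f}%")
print(f"male share of YLL:    {round_half_up(share_of_total(male['yll'].sum(), t1['yll'].sum())):.0f}%")
print(f"male share of PVLI:   {round_half_up(share_of_total(published.PVLI_TOTALS_M['M'], pvli_all)):.0f}%")

lung = float(t3.loc['Lung cancer', 'pvli_m'])
print(f"\nlung share of PVLI: {round_half_up(share_of_total(lung, pvli_all)):.0f}%")
print(f"cost per death, all cancers: ${per_death_cost(pvli_all * 1000.0, t1['deaths'].sum()):.0f}k")
print(f"cost per death, lung:        ${per_death_cost(lung * 1000.0, int(t3.loc['Lung cancer', 'deaths'])):.0f}k")

annual, ten = scenario_savings(lung, reduction=0.02, horizon_years=10)
print(f"\nsustained 2% lung-mortality reduction: ${annual:.1f}M per annum, "
      f"${ten:.1f}M cumulative over 10 years")
# A sustained reduction adds a new persisting annual stream each year, so
# the 10-year cumulative figure is annual x 10(10+1)/2.
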