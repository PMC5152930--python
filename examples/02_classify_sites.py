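"""Classify ICD-10 underlying-cause codes into reported cancer sites.

Any three-character category in C00-C97 is a cancer death; the default
map groups those categories into 26 named sites plus a catch-all, and
subcode digits (C34.1 vs C34) never change the classification.
"""

from mortcost import classify_site, default_site_map, is_cancer_death

for code in ["C34.1", "C61", "C18", "C97", "I21"]:
    if is_cancer_death(code):
        print(f"{code:>6} -> {classify_site(code)}")
    else:
        print(f"{code:>6} -> not a cancer death")

site_map = default_site_map()
print(f"\n{len(site_map.labels)} site labels; every category C00-C97 maps to exactly one:")
counts = {}
for num in range(98):
    counts[site_map.lookup(num)] = counts.get(site_map.lookup(num), 0) + 1
print(f"  named-site categories: {98 - counts[site_map.catch_all]}, "
      f"catch-all categories: {counts[site_map.catch_all]}")
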