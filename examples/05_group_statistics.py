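"""Compare severity groups statistically on cohort features.

Pairwise Mann-Whitney U tests (exact for small samples, normal approximation
otherwise), one-way ANOVA across the three groups, and Tukey HSD post-hoc
comparisons, here on the mean lumen area and red-percentage features.
"""
from itertools import combinations

import pandas as pd

from octfib import anova_oneway, class_presets, generate_cohort, mann_whitney_u, tukey_hsd
from octfib.pipeline import extract_features

cohort = generate_cohort(class_presets(), n_per_class=6, seed=5)
rows = []
for pair, _truth, _label in cohort:
    r, _qc = extract_features(pair)
    rows.extend(r)
features = pd.DataFrame(rows)

for column in ("area_mean", "percent_red"):
    groups = {lab: features.loc[features["label"] == lab, column].to_numpy()
              for lab in ("advanced", "mild", "normal")}
    print(f"\n=== {column} ===")
    for lab, vals in groups.items():
        print(f"  {lab:>8}: mean={vals.mean():.2f} (n={len(vals)})")

    for a, b in combinations(groups, 2):
        gc = mann_whitney_u(groups[a], groups[b])
        print(f"  MWU {a} vs {b}: U={gc.statistic:.1f}, p={gc.p_value:.2e}")

    gc = anova_oneway(list(groups.values()))
    print(f"  ANOVA: F={gc.statistic:.2f}, p={gc.p_value:.2e}")

    for pair_cmp in tukey_hsd(list(groups.values()), labels=list(groups)):
        mark = "*" if pair_cmp.significant else " "
        print(f"  Tukey {pair_cmp.groups[0]} vs {pair_cmp.groups[1]}: p={pair_cmp.p_value:.2e} {mark}")
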