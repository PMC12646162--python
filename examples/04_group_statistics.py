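"""Compare rupture forces across species and trichome location.

Generates the grouped dataset at the observed structure (cultivar leaf
5±2 n=16, cultivar stem 9±3 n=24, wild leaf 6±3 n=29, wild stem 4±2 n=10,
plus 5 planted extreme values), screens outliers by the 1.5·IQR rule, and
runs a two-way ANOVA with post-hoc Tukey HSD letters at α = 0.02.
"""

from trichomech import synthio, analyze_groups

df = synthio.gen_group_dataset(seed=1)
res = analyze_groups(df[["species", "location", "value"]], alpha=0.02)

print(f"outliers removed: {res['n_outliers']} of {len(df)}")
print("\nper-group summary (uN):")
print(res["summary"][["species", "location", "mean", "sd", "n"]]
      .to_string(index=False))
print("\nANOVA (Type II):")
print(res["anova"][["sum_sq", "df", "F", "PR(>F)"]].round(4).to_string())
print("\nTukey letters (alpha = 0.02):", res["letters"])
print()
print("Groups sharing no letter differ significantly: the cultivar stem")
print("trichomes typically need markedly more force to rupture than any")
print("other species/location pair.")
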