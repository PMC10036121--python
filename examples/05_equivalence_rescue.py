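"""Practical-equivalence testing and reverted/restored rescue classification.

Baseline DEGs (Wald q < 0.1) are classified under treatment: *reverted* when
significantly changed in the opposite direction, *restored* when practically
equivalent to no change (TOST against a +/-1.5-fold region, BH q < 0.05
within the DEG set), otherwise not rescued.
"""

from nutrichrom import SimConfig, classify_rescue, simulate_de_table

cfg = SimConfig(seed=3)
baseline, treatment, truth = simulate_de_table(cfg)
result = classify_rescue(baseline, treatment)

print(f"baseline DEGs: {result.n_degs}")
print(result.table["label"].value_counts().to_string())
print(f"rescued fraction: {result.rescued_fraction:.2f}")

t = truth.de_truth.set_index("gene_id")
merged = result.table.set_index("gene_id").join(t["label"].rename("true"))
mapped = merged["true"].replace({"still_changed": "not_rescued", "unchanged": "not_rescued"})
print(f"label agreement with planted truth: {(merged['label'] == mapped).mean():.2f}")
# The generator plants 30% reverted / 30% restored / 40% still-changed among
# true DE genes, so the rescued fraction should land near 0.60.
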