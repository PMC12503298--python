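"""Y-linked duplicate (ampliconic) gene-family expression across stages."""

from mscix import (
    SimConfig,
    count_expressed_families,
    family_expression,
    pseudobulk,
    simulate_counts,
)

m, ann, _ = simulate_counts(SimConfig(seed=4))
ft = family_expression(pseudobulk(m), ann)
print(f"{len(ft.per_stage)} duplicate families "
      f"({ft.n_paralogs.min()}-{ft.n_paralogs.max()} copies each)")
print("\nfamilies expressed per stage (summed count >= 1):")
print(count_expressed_families(ft).to_string())
print("\ntop families by meiotic aggregate (normalised by library size):")
print(ft.per_stage.nlargest(5, "meiotic").round(5).to_string())
# Family expression is the library-size-normalised sum over all paralogs.
# In a testis without meiotic silencing, many Y families peak in meiosis
# rather than being restricted to post-meiotic stages.
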