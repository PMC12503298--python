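"""Faster-X contrasts: dN/dS of sex-linked gene classes vs autosomes."""

from mscix import (
    SimConfig,
    classify_induced,
    dnds_prepare,
    faster_x_contrast,
    pseudobulk,
    simulate_counts,
    simulate_dnds,
)

config = SimConfig(seed=5)
m, ann, _ = simulate_counts(config)
dnds = dnds_prepare(simulate_dnds(config))
induced = classify_induced(pseudobulk(m))
print(f"{len(dnds)} genes with a dN/dS estimate; "
      f"{int((induced != 'none').sum())} induced in a spermatogenesis stage")

fx = faster_x_contrast(dnds, ann, induced)
print("\nrank-sum contrasts vs autosomes:")
print(fx.pairwise[["subset", "gene_class", "n", "statistic", "p"]]
      .to_string(index=False))
# Expected structure: Y-hemizygous genes above autosomes (coding
# degeneration), X+Y gametologs below (slower-X purifying selection), and
# X-hemizygous genes elevated mainly in the induced subset — the
# testis-restricted faster-X effect.
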