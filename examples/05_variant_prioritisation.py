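"""Filter an annotated variant table to rare, splice-disrupting, recessively
segregating candidates, flag splice-outlier proximity, and assign gene
tiers. The simulated table holds one causal deep-intronic variant among
decoys that each violate exactly one filter."""

from asorescue import assign_tiers, outlier_proximity, prioritise_variants
from asorescue.simulate import simulate_variant_table

variants, outliers, pedigree, truth = simulate_variant_table(n_decoys=8, seed=0)
print(f"input: {len(variants)} variants "
      f"(1 causal + {len(variants) - 1} designed decoys)")

variants = assign_tiers(variants, ["CDK5RAP3", "DMD", "TTN"], [], [])
kept = prioritise_variants(variants, pedigree, "recessive_hom",
                           maf_max=0.01, delta_min=0.10)
kept = outlier_proximity(kept, outliers, window=250)

cols = ["chrom", "pos", "gene", "maf", "max_delta", "tier", "segregation",
        "outlier_distance", "outlier_proximal"]
print(kept[cols].to_string(index=False))

# Only the causal variant survives: MAF below 0.01, maximum SpliceAI delta
# 0.42 (>= 0.10), homozygous in the affected child with heterozygous
# parents, and 3 bp from a splice-outlier interval (within the 250-bp
# scrutiny window).
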