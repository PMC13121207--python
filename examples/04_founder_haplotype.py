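"""Recover a shared founder segment: per-proband ROH around the focal
variant, the minimal cross-family shared region, the GQ-filtered haplotype
matrix, and the relatedness screen."""

from asorescue import detect_roh, haplotype_matrix, minimal_shared_region, relatedness
from asorescue.simulate import simulate_pedigrees

gm, pedigree, truth = simulate_pedigrees(seed=0)
focal = truth.params["focal_pos"]

segments = [detect_roh(gm, proband, focal)
            for proband in ("A_proband", "B_proband")]
for seg in segments:
    print(f"{seg.individual}: ROH {seg.chrom}:{seg.start}-{seg.end} "
          f"({seg.n_markers} markers)")
chrom, start, end = minimal_shared_region(segments)
print(f"minimal shared region: {chrom}:{start}-{end}")
print(f"planted segment:       {chrom}:{truth.params['segment_start']}-"
      f"{truth.params['segment_end']}")

hm = haplotype_matrix(gm, (chrom, start, end), list(gm.individuals), focal,
                      ["A_proband", "B_proband"])
print(f"haplotype matrix funnel: {hm.funnel}")
print(f"probands concordant across {hm.concordant[0]}-{hm.concordant[1]}")

for pair in (("A_father", "A_mother"), ("B_father", "B_mother"),
             ("A_father", "B_father")):
    score = relatedness(gm, *pair)
    print(f"relatedness {pair[0]} vs {pair[1]}: {score:+.4f} "
          f"({'unrelated' if score < 0.05 else 'related'}, cutoff 0.05)")

# Both probands are homozygous across the planted founder segment, so the
# intersection of their ROHs recovers it exactly; the parents carry a single
# shared haplotype copy, which leaves them below the relatedness cutoff on a
# genome-wide marker panel.
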