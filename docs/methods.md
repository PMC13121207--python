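# Methods

`asorescue` implements the computational core of a gene-discovery workflow
for a recessive splice-disrupting variant treated with a splice-blocking
antisense oligonucleotide (ASO): differential (phospho)proteomics and
rescue-set classification, pathway/kinase summaries, founder-haplotype
genetics, splice-variant prioritisation, and relative qPCR quantification.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Differential statistics

Input is a features × samples matrix of log2 intensities with a sample
design (genotype ∈ {proband, control} × treatment ∈ {ASO_S, ASO_T,
untreated} × replicate). For a contrast the per-feature statistics are

* log2FC = mean(test) − mean(reference) on the log2 scale,
* a Welch two-sample t (pooled-variance optional), two-sided p from the t
  reference distribution with Welch–Satterthwaite degrees of freedom,
* Benjamini–Hochberg q across all features of the dataset for that
  contrast (proteome and phosphoproteome adjusted separately),
* significance = |log2FC| ≥ `lfc_min` (default 0.2) and q ≤ `q_max`
  (default 0.05).

Missing values are handled complete-case per feature and contrast; a
feature with fewer than two values in an arm gets missing statistics and is
excluded from the BH family. No imputation and no variance moderation are
performed: imputation fabricates signal, and an empirical-Bayes moderated
test is a possible extension rather than a default, because the choice
materially changes power at n = 4 per arm and should be explicit. Welch
rather than pooled is the default because equal arm variances cannot be
checked at this replication level.

Degenerate inputs: zero variance in both arms with equal means → t = 0,
p = 1; zero variance with unequal means → p at the smallest positive float
(never silently zero); constant features in the z-matrix → all-zero row,
flagged.

Per-feature z-scores standardise each feature across *all* samples (sample
sd, ddof = 1); they feed the restoration geometry below.

## Rescue-set classification

A feature enters the ASO-T rescue set iff all four hold:

1. **Disease-altered** — significant in ASO-S proband vs ASO-S control *or*
   ASO-S proband vs ASO-T control at the primary thresholds.
2. **Treatment-responsive** — significant in ASO-T proband vs ASO-S proband
   at the rescue thresholds (a separately configurable, typically more
   permissive fold-change cutoff, to keep partially restored features).
3. **Shift toward control** — with per-arm means of the z-scores m_PS,
   m_PT, m_CS, m_CT, the restoration fraction toward control arm c is
   r_c = (m_PT − m_PS) / (m_c − m_PS), defined when |m_c − m_PS| > 1e-9;
   the criterion is r_c > 0 for at least one control arm (any positive
   shift counts; no magnitude threshold is imposed). The reported r comes
   from the control arm with the larger |m_c − m_PS|, i.e. the
   better-resolved gap.
4. **Not off-target** — not flagged as altered between ASO-T and ASO-S
   control cells.

Labels are a package convention with configurable cutoffs: r > 1.2
overshoot, r ≥ 0.8 full, r ≥ 0.05 partial; degrees of restoration are not
formalised in the source procedure.

Two deliberate multiplicity choices, both configurable:

* **Sequential BH family.** The responsiveness test (criterion 2) is only
  ever applied to disease-altered candidates, so by default its BH family
  is that candidate list (`responsive_family="disease_altered"`), not the
  whole matrix. With the full-matrix family, an effect of 1.0 log2 units at
  σ = 0.25 and n = 4 (t ≈ 5.7 but only ~6 df, p ≈ 1.3e-3) frequently fails
  q ≤ 0.05 when only a few percent of features carry signal — the procedure
  would discard most genuinely restored features on multiplicity grounds
  alone. `responsive_family="all"` restores the flat design.
* **Off-target exclusion on raw p.** Criterion 4 is an exclusion screen:
  failing to exclude is the anti-conservative direction for the final set.
  An FDR-adjusted exclusion test has near-zero power against moderate
  off-target effects at this replication level, which would make the
  criterion vacuous, so the default flags |log2FC| ≥ `lfc_min` with
  unadjusted p ≤ 0.05 (`off_target_rule="raw_p"`; `"bh"` available).

A consequence worth knowing: with the exclusion screen and sequential
family in play, tightening q_max is *not* globally monotone (a tighter
q_max also weakens the exclusion). Monotonicity holds when the off-target
thresholds are pinned and the flat family is used, and the test suite
checks it in exactly that configuration.

## Enrichment and kinase activity

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) for a selection of n features from a universe of N against each
term of size K (after intersecting terms with the universe), reporting
InTerm = k, RichFactor = k/K, and BH q across tested terms. No multi-database
retrieval or term-redundancy collapsing is attempted; terms come from
user-supplied GMT files.

Inferred kinase activity is the KSEA z statistic on substrate phosphosite
log2 fold-changes,

    z_k = (mean_{s∈S_k} lfc_s − mean lfc) · √m_k / sd(lfc),

with a two-sided permutation p from `n_perm` (default 10⁴) random
same-size site draws, add-one corrected: p = (b + 1)/(n_perm + 1). Kinases
with fewer than `m_min = 3` quantified substrates are skipped; unquantified
substrate sites are dropped with a warning. This is an approximation to
dedicated kinase-activity tools and is labelled as such; the permutation
null is the shared site pool, so co-regulation among substrates of other
kinases inflates neither size nor power systematically but can correlate
scores between kinases with overlapping substrates.

## Founder-haplotype genetics

* **ROH.** No single field definition exists; here an ROH around a focal
  variant is the maximal run of consecutive homozygous calls containing it,
  extending greedily both directions and consuming at most `max_het`
  heterozygous calls (default 0 — exome marker density is low and
  boundaries are refined with denser data downstream). The het budget split
  between directions is chosen to maximise the marker count (ties to the
  left); boundaries are the outermost homozygous markers; missing or
  low-GQ calls end the extension; a het or missing focal call is an error.
* **Minimal shared region** is the intersection of per-individual segments
  (equivalently bounded by the smallest ROH), all of which contain the
  focal position by construction.
* **Haplotype matrix.** Markers inside the shared region are kept only if
  called in all individuals with GQ strictly greater than 35 in all of
  them (strict ">", per the source filtering wording); the funnel (total,
  dropped-by-call, dropped-by-GQ, kept) is logged and sum-consistent. The
  concordant sub-interval extends from the focal marker while all
  homozygous carriers agree on the allele count.
* **Relatedness.** A Somalier-style statistic on jointly called markers:
  (N_both_het − 2·N_opposite_hom) / min(N_het_i, N_het_j), cutoff 0.05 for
  "unrelated". Its sampling sd is ≈ √(3/M) for unrelated pairs regardless
  of allele frequencies, so resolving a 0.05 cutoff needs several thousand
  markers — hence the simulator's default genome-wide panel of 5000 (the
  real screen runs on ~17k sites). At least 200 overlapping markers are
  required at all.
* **Variant prioritisation.** Retain variants with population MAF
  strictly < 0.01, maximum SpliceAI delta (acceptor/donor gain/loss)
  ≥ 0.10 (inclusive), and segregation consistent with the chosen mode
  (`recessive_hom`: affected hom-alt, unaffected parents het, unaffected
  sibs 0/1; `comp_het`: ≥ 2 retained variants in a gene, one inherited from
  each parent; `de_novo`). A missing parental genotype degrades to
  segregation "unknown" and the variant is *kept* — a discovery pipeline
  must not drop candidates silently. Splice-outlier proximity flags
  variants within 250 bp (inclusive) of an outlier interval, with distance
  to a 1-based inclusive interval defined as max(start − p, p − end, 0).
  Gene tiers 1–3 come from user gene lists (first match wins,
  case-insensitive); tier 4 is everything else. SpliceAI scores are
  consumed pre-computed; the model itself is never run.

## qPCR

Normalised quantity NQ_s = E^(mean_r Ct_r,s − Ct_target,s) against the
geometric mean of the reference genes (E = 2 by default; E ≤ 1 rejected),
technical replicates averaged on the Ct scale first (spread > 0.5 cycles
warns). Percent of control = 100 · NQ_s / mean(NQ over controls), making
the control-group mean exactly 100. Biological replicates are normalised
per sample and summarised afterwards. A global per-sample Ct offset
(pipetting) cancels exactly in NQ.

## Synthetic data: what it emulates, what it does not

`simulate_omics` reproduces the study's arm structure (2 genotypes × 2 ASO
treatments × 4 replicates) with Gaussian noise σ = 0.25 on the log2 scale,
baseline N(20, 2), and planted categories: 1780 null, 100 fully rescued
(disease effect δ = 1.0 in proband-ASO-S only), 50 partially rescued
(residual (1 − r)·δ under ASO-T, r = 0.5), 50 disease-altered-not-rescued,
and 20 ASO-T off-target features (effect 0.6 in *both* ASO-T arms, so the
exclusion criterion rather than the genotype is what must remove them).
Signs are random per feature. A t₅ noise option exists for robustness
checks. Not emulated: TMT batch/channel structure, intensity-dependent
missingness, protein–site dependence. Passing recovery tests therefore
demonstrates the classifier logic under clean noise, not robustness to the
full messiness of real TMT data.

`simulate_phospho` adds site identifiers (GENE_S123 style), groups sites
into proteins, assigns random kinase substrate sets, and plants one
activated kinase whose substrates share a common shift.

`simulate_pedigrees` builds two trios whose four founders each carry one
copy of a shared ancestral haplotype across a segment (default 21 markers)
centred on the focal variant; both probands inherit it from both parents
(hom across the segment, hom-alt at the focal marker; all parents het).
The markers immediately flanking the segment are forced heterozygous in
the probands so the planted segment has exact boundaries at marker
resolution. Background genotypes are independent Hardy–Weinberg draws —
no linkage disequilibrium and no recombination model, which is adequate
for genotype-level concordance logic but not for coalescent-accurate
haplotype statistics.

`simulate_ct` generates Ct values consistent with the ddCt model (default:
three controls at 100% and one proband at 4.4% residual expression,
σ_Ct = 0.05 cycles, 3 technical replicates, per-sample pipetting offsets).
`simulate_variant_table` plants one causal deep-intronic variant (MAF 0,
donor-gain delta 0.42, recessive trio genotypes, 3 bp from a
splice-outlier interval) among decoys that each violate exactly one
retention filter.

All generators are byte-deterministic given their seed and emit truth
objects keyed to the generated identifiers.

## Numerical choices and conventions

Coordinates are 1-based, intervals inclusive on both ends (VCF
convention). Boundary conventions follow the filtering wording: MAF
strictly <, SpliceAI delta ≥, GQ strictly >, proximity ≤. Restoration
denominators below 1e-9 are treated as degenerate (flag false, r
undefined). Result TSVs are written byte-stably (sorted rows, 6
significant digits). BH is delegated to statsmodels (`fdr_bh`) with NaN
masking; the hypergeometric tail to scipy — both are cross-checked against
brute-force oracles in the tests.

## Known limitations

* n = 4 per arm yields ~6 df per test; FDR-significance at |log2FC| ≥ 0.2
  is power-limited, and the rescue classifier's recall on simulated data
  reflects that (reported by `scripts/acceptance.py`, not asserted here).
* The kinase statistic is a generic KSEA approximation, not the original
  tool behind the published figures.
* The relatedness screen is a point statistic without an IBD probability
  model; it classifies, it does not estimate kinship segments.
* The supplementary-table XLSX reader requires an explicit column mapping
  because third-party workbook layouts vary.
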