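"""Synthetic-data generators with planted, machine-readable ground truth.

Every pipeline input can be generated here: four-arm (phospho)proteomic
abundance matrices with planted rescue categories, site-level phospho data
with a planted activated kinase, two-trio genotype matrices sharing an IBD
founder segment around a focal variant, qPCR Ct tables, and annotated
variant tables with designed decoys. Each generator returns its inputs plus
a truth object keyed to the generated identifiers, and is byte-deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    AbundanceTable,
    CtTable,
    GenotypeMatrix,
    OutlierInterval,
    PedigreeSpec,
    SampleDesign,
)

ARMS = (("proband", "ASO_S"), ("proband", "ASO_T"),
        ("control", "ASO_S"), ("control", "ASO_T"))
ARM_CODES = {("proband", "ASO_S"): "PS", ("proband", "ASO_T"): "PT",
             ("control", "ASO_S"): "CS", ("control", "ASO_T"): "CT"}

CATEGORIES = ("null", "rescued_full", "rescued_partial", "rescued_not", "off_target")


# ---------------------------------------------------------------------------
# omics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmicsSimConfig:
    """Study conditions for the four-arm rescue experiment.

    Defaults mirror the amniocyte experiment scale: 2 genotypes x 2 ASO
    treatments x 4 replicates, a 1.0 log2-unit disease effect, measurement
    noise sigma = 0.25 on the log2 scale, and 2000 features of which 220 are
    non-null (100 fully rescued, 50 partially rescued at restoration
    fraction 0.5, 50 disease-altered but not rescued, 20 ASO off-target).
    """

    n_null: int = 1780
    n_rescued_full: int = 100
    n_rescued_partial: int = 50
    n_rescued_not: int = 50
    n_off_target: int = 20
    delta: float = 1.0
    partial_r: float = 0.5
    off_target_effect: float = 0.6
    n_rep: int = 4
    sigma: float = 0.25
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    noise: str = "gaussian"  # or "t5" for heavier tails
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_null, self.n_rescued_full, self.n_rescued_partial,
                  self.n_rescued_not, self.n_off_target)
        if any(c < 0 for c in counts):
            raise ValueError("category counts must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.partial_r < 1):
            raise ValueError("partial restoration fraction must be in (0, 1)")
        n_effect = sum(counts[1:])
        if self.delta == 0 and n_effect > 0:
            raise ValueError("delta = 0 with non-null categories planted")
        if self.n_rep < 2:
            raise ValueError("need at least 2 replicates per arm")
        if self.noise not in ("gaussian", "t5"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def n_features(self) -> int:
        return (self.n_null + self.n_rescued_full + self.n_rescued_partial
                + self.n_rescued_not + self.n_off_target)


@dataclass
class SimTruth:
    """Planted ground truth; ``data`` keys match the generated identifiers."""

    data: pd.DataFrame
    params: dict = field(default_factory=dict)


def _four_arm_design(n_rep: int) -> SampleDesign:
    rows = []
    for arm in ARMS:
        code = ARM_CODES[arm]
        for r in range(1, n_rep + 1):
            rows.append(dict(sample=f"{code}{r}", genotype=arm[0],
                             treatment=arm[1], replicate=r))
    return SampleDesign(pd.DataFrame(rows).set_index("sample"))


def _arm_effects(category: str, sign: float, cfg: OmicsSimConfig) -> dict[str, float]:
    """Mean shift added per arm for one feature of the given category."""
    d, r, o = cfg.delta, cfg.partial_r, cfg.off_target_effect
    if category == "null":
        return {}
    if category == "rescued_full":
        return {"PS": d * sign}
    if category == "rescued_partial":
        return {"PS": d * sign, "PT": (1 - r) * d * sign}
    if category == "rescued_not":
        return {"PS": d * sign, "PT": d * sign}
    if category == "off_target":
        # off-target ASO-T effect hits both ASO-T arms so that the exclusion
        # criterion, not the genotype, is what removes these features
        return {"CT": o * sign, "PT": o * sign}
    raise ValueError(category)


def simulate_omics(cfg: OmicsSimConfig = OmicsSimConfig()) -> tuple[
    AbundanceTable, SampleDesign, SimTruth
]:
    """Four-arm log2 abundance matrix with planted rescue categories."""
    rng = np.random.default_rng(cfg.seed)
    design = _four_arm_design(cfg.n_rep)
    categories = np.repeat(
        CATEGORIES,
        [cfg.n_null, cfg.n_rescued_full, cfg.n_rescued_partial,
         cfg.n_rescued_not, cfg.n_off_target],
    )
    n = cfg.n_features
    width = len(str(n))
    features = [f"PROT{str(i + 1).zfill(width)}" for i in range(n)]
    signs = rng.choice([-1.0, 1.0], size=n)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)

    samples = design.sample_ids
    arm_code = [ARM_CODES[(design.table.at[s, "genotype"],
                           design.table.at[s, "treatment"])] for s in samples]
    means = np.tile(baseline[:, None], (1, len(samples)))
    for i, (cat, sign) in enumerate(zip(categories, signs)):
        eff = _arm_effects(cat, sign, cfg)
        for j, code in enumerate(arm_code):
            means[i, j] += eff.get(code, 0.0)
    if cfg.noise == "gaussian":
        noise = rng.normal(0.0, cfg.sigma, size=means.shape)
    else:  # t with 5 df, scaled to the same sd
        noise = rng.standard_t(5, size=means.shape) * cfg.sigma / np.sqrt(5 / 3)
    values = pd.DataFrame(means + noise, index=features, columns=samples)
    truth = SimTruth(
        pd.DataFrame({"category": categories, "sign": signs,
                      "delta": np.where(categories == "null", 0.0, cfg.delta)},
                     index=pd.Index(features, name="feature")),
        params=asdict(cfg),
    )
    return AbundanceTable(values), design, truth


# ---------------------------------------------------------------------------
# phospho sites + kinases
# ---------------------------------------------------------------------------


def simulate_phospho(
    cfg: OmicsSimConfig = OmicsSimConfig(),
    *,
    sites_per_protein: int = 2,
    n_kinases: int = 20,
    substrates_per_kinase: int = 10,
    kinase_shift: float = 1.0,
    plant_kinase: bool = True,
) -> tuple[AbundanceTable, SampleDesign, dict[str, tuple[str, ...]], SimTruth]:
    """Site-level phospho matrix, a kinase-substrate map, and planted truth.

    Built on :func:`simulate_omics`; sites are grouped into proteins
    (``sites_per_protein`` each) and kinases claim random substrate sites.
    When ``plant_kinase`` is true the first kinase's substrates receive an
    extra common shift in the ASO-S-treated proband arm, so it should rank
    first in a KSEA of the proband-vs-control contrast.
    """
    table, design, truth = simulate_omics(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_features
    site_ids = []
    residues = ("S", "T", "Y")
    for i in range(n):
        protein = f"GENE{str(i // sites_per_protein + 1).zfill(4)}"
        res = residues[i % 3]
        pos = 10 + 17 * i % 900
        site_ids.append(f"{protein}_{res}{pos}")
    values = table.values.copy()
    values.index = pd.Index(site_ids, name="site")
    truth.data.index = pd.Index(site_ids, name="site")

    kinase_map: dict[str, tuple[str, ...]] = {}
    for k in range(n_kinases):
        picks = rng.choice(n, size=substrates_per_kinase, replace=False)
        kinase_map[f"KIN{str(k + 1).zfill(2)}"] = tuple(site_ids[i] for i in picks)
    planted = None
    if plant_kinase and n_kinases > 0:
        planted = "KIN01"
        ps_samples = design.arm_samples("proband", "ASO_S")
        rows = [site_ids.index(s) for s in kinase_map[planted]]
        values.iloc[rows, [values.columns.get_loc(s) for s in ps_samples]] += kinase_shift
    truth.data["kinase"] = ""
    if planted:
        truth.data.loc[list(kinase_map[planted]), "kinase"] = planted
    truth.params.update(dict(planted_kinase=planted, kinase_shift=kinase_shift,
                             n_kinases=n_kinases,
                             substrates_per_kinase=substrates_per_kinase))
    return AbundanceTable(values), design, kinase_map, truth


# ---------------------------------------------------------------------------
# pedigrees with a shared founder segment
# ---------------------------------------------------------------------------

INDIVIDUALS = ("A_father", "A_mother", "A_proband",
               "B_father", "B_mother", "B_proband")
FOCAL_POS = 47_974_691  # anchor position for the focal deep-intronic variant
MARKER_STEP = 1000


def simulate_pedigrees(
    n_markers: int = 5000,
    segment_span: int = 21,
    *,
    allele_freq_range: tuple[float, float] = (0.1, 0.9),
    low_gq_fraction: float = 0.05,
    gq_range: tuple[float, float] = (36.0, 99.0),
    low_gq_range: tuple[float, float] = (5.0, 35.0),
    chrom: str = "chr17",
    seed: int = 0,
) -> tuple[GenotypeMatrix, PedigreeSpec, SimTruth]:
    """Two unrelated trios sharing one ancestral haplotype around a focal
    variant.

    All four parents carry a single copy of the founder haplotype across a
    ``segment_span``-marker segment centred on the focal marker; both
    probands inherit it from both parents and are therefore homozygous across
    the segment, hom-alt at the focal variant, with all parents heterozygous
    there. The markers immediately flanking the segment are forced
    heterozygous in the probands so the planted segment has exact boundaries
    at marker resolution. Background genotypes are independent
    Hardy-Weinberg draws, which keeps cross-family founders unrelated; the
    default panel of 5000 markers makes the planted segment a small fraction
    of the sites, as a founder segment is in a genome-wide panel, so the
    relatedness statistic can resolve the 0.05 cutoff.
    """
    if segment_span < 1 or segment_span >= n_markers - 2:
        raise ValueError("segment_span must be >= 1 and leave flanking markers")
    rng = np.random.default_rng(seed)
    centre = n_markers // 2
    half = segment_span // 2
    seg_lo, seg_hi = centre - half, centre - half + segment_span - 1
    if seg_lo < 1 or seg_hi > n_markers - 2:
        raise ValueError("segment does not fit inside the marker panel")
    positions = FOCAL_POS + MARKER_STEP * (np.arange(n_markers) - centre)
    freqs = rng.uniform(*allele_freq_range, size=n_markers)

    founder = (rng.random(n_markers) < freqs).astype(np.int8)
    founder[centre] = 1  # focal alt allele rides on the founder haplotype

    def random_hap() -> np.ndarray:
        return (rng.random(n_markers) < freqs).astype(np.int8)

    seg = slice(seg_lo, seg_hi + 1)
    geno = {}
    for fam in ("A", "B"):
        gametes = {}
        for role in ("father", "mother"):
            hap_f = random_hap()
            hap_f[seg] = founder[seg]  # founder copy
            hap_o = random_hap()
            hap_o[centre] = 0  # parents are carriers (het) at the focal variant
            geno[f"{fam}_{role}"] = hap_f + hap_o
            pick = rng.integers(0, 2, size=n_markers)
            gamete = np.where(pick == 0, hap_f, hap_o)
            gamete[seg] = founder[seg]  # proband inherits the founder segment
            gametes[role] = gamete
        child = gametes["father"] + gametes["mother"]
        child[seg_lo - 1] = 1  # exact segment boundaries at marker resolution
        child[seg_hi + 1] = 1
        geno[f"{fam}_proband"] = child

    g = np.column_stack([geno[i] for i in INDIVIDUALS]).astype(np.int8)
    gq = rng.uniform(*gq_range, size=g.shape)
    low = rng.random(g.shape) < low_gq_fraction
    gq[low] = rng.uniform(*low_gq_range, size=int(low.sum()))
    gq[centre, :] = 60.0  # the focal call itself is high quality everywhere

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_markers)]
    alt_shift = rng.integers(1, 4, size=n_markers)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
    ref[centre], alt[centre] = "G", "A"
    markers = pd.DataFrame(dict(chrom=chrom, pos=positions, ref=ref, alt=alt))
    gm = GenotypeMatrix(markers, list(INDIVIDUALS), g, gq)

    ped = PedigreeSpec(pd.DataFrame(
        {
            "father": [None, None, "A_father", None, None, "B_father"],
            "mother": [None, None, "A_mother", None, None, "B_mother"],
            "sex": ["male", "female", "female", "male", "female", "male"],
            "affected": ["no", "no", "yes", "no", "no", "yes"],
        },
        index=pd.Index(INDIVIDUALS, name="id"),
    ))
    truth_df = pd.DataFrame(
        {
            "role": ["founder_segment"] * 2 + ["focal"],
            "chrom": chrom,
            "pos": [int(positions[seg_lo]), int(positions[seg_hi]), FOCAL_POS],
        },
        index=pd.Index(["segment_start", "segment_end", "focal"], name="key"),
    )
    truth = SimTruth(truth_df, params=dict(
        chrom=chrom, segment_start=int(positions[seg_lo]),
        segment_end=int(positions[seg_hi]),
        segment_marker_indices=(seg_lo, seg_hi), focal_pos=FOCAL_POS,
        n_markers=n_markers, seed=seed,
    ))
    return gm, ped, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

REFERENCE_CT = {"GAPDH": 20.0, "HPRT1": 24.0, "RPLP0": 22.0}
TARGET_ASSAY = "CDK5RAP3"
BASE_LOG2_NQ = -4.0  # control-level target quantity relative to references


def simulate_ct(
    true_fractions: Mapping[str, float] | None = None,
    sigma_ct: float = 0.05,
    n_tech: int = 3,
    seed: int = 0,
    *,
    groups: Mapping[str, str] | None = None,
) -> tuple[CtTable, SimTruth]:
    """Ct table consistent with the ddCt model and a known expression profile.

    ``true_fractions`` maps sample -> expression as a fraction of the control
    level (default: three controls at 1.0 and one proband at 0.044, the
    residual canonical splicing measured in proband muscle). A per-sample
    global Ct offset emulates pipetting differences; per-well noise is
    Normal(0, ``sigma_ct``) cycles on ``n_tech`` technical replicates.
    """
    if true_fractions is None:
        true_fractions = {"C1": 1.0, "C2": 1.0, "C3": 1.0, "P1": 0.044}
    if groups is None:
        groups = {s: ("control" if f == 1.0 else "proband")
                  for s, f in true_fractions.items()}
    if sigma_ct < 0 or n_tech < 1:
        raise ValueError("sigma_ct must be >= 0 and n_tech >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fraction in true_fractions.items():
        if fraction <= 0:
            raise ValueError(f"true fraction for {sample!r} must be > 0")
        offset = rng.normal(0.0, 0.3)  # global pipetting shift for the sample
        base = {assay: ct + offset for assay, ct in REFERENCE_CT.items()}
        ref_mean = np.mean(list(base.values()))
        base[TARGET_ASSAY] = ref_mean - (BASE_LOG2_NQ + np.log2(fraction))
        for assay, ct in base.items():
            role = "reference" if assay in REFERENCE_CT else "target"
            for rep in range(1, n_tech + 1):
                rows.append(dict(sample=sample, assay=assay, role=role,
                                 rep=rep, ct=ct + rng.normal(0.0, sigma_ct)))
    table = CtTable(pd.DataFrame(rows), dict(groups))
    fr = pd.Series(true_fractions, name="true_fraction")
    ctrl = [s for s, g in groups.items() if g == "control"]
    truth_df = pd.DataFrame({
        "true_fraction": fr,
        "true_percent": 100.0 * fr / fr[ctrl].mean(),
        "group": pd.Series(dict(groups)),
    })
    truth_df.index.name = "sample"
    truth = SimTruth(truth_df, params=dict(sigma_ct=sigma_ct, n_tech=n_tech,
                                           seed=seed))
    return table, truth


# ---------------------------------------------------------------------------
# annotated variant tables with designed decoys
# ---------------------------------------------------------------------------

DECOY_KINDS = ("high_maf", "low_delta", "affected_not_hom", "parent_hom")


def simulate_variant_table(
    n_decoys: int = 8,
    causal_spec: Mapping | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[OutlierInterval], PedigreeSpec, SimTruth]:
    """One planted causal deep-intronic variant among single-fault decoys.

    The causal variant is absent from population databases (MAF 0), has a
    strong splice-disruption score (donor gain 0.42 by default), segregates
    recessively in the trio (proband hom-alt, parents het) and lies 3 bp from
    a splice-outlier interval. Each decoy violates exactly one retention
    filter (high MAF, sub-threshold delta, affected not homozygous, or a
    homozygous unaffected parent) while satisfying all others; decoys sit
    far (> 250 bp) from any outlier interval.
    """
    spec = dict(gene="CDK5RAP3", chrom="chr17", pos=FOCAL_POS,
                ref="G", alt="A", max_delta=0.42, delta_channel="ds_dg")
    if causal_spec:
        spec.update(causal_spec)
    rng = np.random.default_rng(seed)

    def deltas(max_d: float, channel: str) -> dict[str, float]:
        d = {c: round(float(rng.uniform(0.0, 0.02)), 3) for c in
             ("ds_ag", "ds_al", "ds_dg", "ds_dl")}
        d[channel] = max_d
        return d

    rows = [dict(chrom=spec["chrom"], pos=spec["pos"], ref=spec["ref"],
                 alt=spec["alt"], gene=spec["gene"], maf=0.0,
                 **deltas(spec["max_delta"], spec["delta_channel"]),
                 gt_proband=2, gt_father=1, gt_mother=1, kind="causal")]
    for i in range(n_decoys):
        kind = DECOY_KINDS[i % len(DECOY_KINDS)]
        row = dict(chrom=spec["chrom"], pos=48_100_000 + 10_000 * i,
                   ref="C", alt="T", gene=f"DECOY{i + 1}", maf=0.0,
                   **deltas(0.42, "ds_ag"),
                   gt_proband=2, gt_father=1, gt_mother=1, kind=kind)
        if kind == "high_maf":
            row["maf"] = 0.02
        elif kind == "low_delta":
            for c in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
                row[c] = 0.01
            row["ds_ag"] = 0.09
        elif kind == "affected_not_hom":
            row["gt_proband"] = 1
        elif kind == "parent_hom":
            row["gt_father"] = 2
        rows.append(row)
    variants = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth = SimTruth(variants[["chrom", "pos", "gene", "kind"]].copy(),
                     params=dict(causal=spec, n_decoys=n_decoys, seed=seed))
    variants = variants.drop(columns=["kind"])
    outliers = [OutlierInterval(spec["chrom"], spec["pos"] - 103, spec["pos"] - 3,
                                "splice-outlier", 1e-6)]
    ped = PedigreeSpec(pd.DataFrame(
        {
            "father": [None, None, "father"],
            "mother": [None, None, "mother"],
            "sex": ["male", "female", "female"],
            "affected": ["no", "no", "yes"],
        },
        index=pd.Index(["father", "mother", "proband"], name="id"),
    ))
    return variants, outliers, ped, truth
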