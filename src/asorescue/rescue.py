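"""ASO-T rescue-set classification for splice-correction (phospho)proteomics.

The experiment has four arms: proband and control cells, each treated with a
scrambled-control ASO (ASO-S) or the target ASO (ASO-T). A feature enters the
"rescue set" when

1. it is *disease-altered*: significantly different between ASO-S-treated
   proband and either ASO-S- or ASO-T-treated control cells (primary
   thresholds);
2. it is *treatment-responsive*: significantly different between ASO-T- and
   ASO-S-treated proband cells (rescue thresholds; a more permissive
   fold-change cutoff may be used here to keep partially restored features);
3. its per-feature z-score moves *toward* a control arm under ASO-T
   (restoration fraction r > 0); and
4. it is not an *off-target* ASO-T effect: not significantly different
   between ASO-T- and ASO-S-treated control cells.

The restoration fraction r = (mean z in proband-T - mean z in proband-S) /
(mean z in control - mean z in proband-S) quantifies how far ASO-T moves a
feature back to the control level (1 = fully restored). Labels full /
partial / overshoot based on r are a package convention with configurable
cutoffs; the source procedure does not formalise degrees of restoration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import Contrast, Thresholds, ZMatrix, run_contrast, z_scores
from .io_formats import AbundanceTable, SampleDesign

PROBAND_S = ("proband", "ASO_S")
PROBAND_T = ("proband", "ASO_T")
CONTROL_S = ("control", "ASO_S")
CONTROL_T = ("control", "ASO_T")

EPS_DENOM = 1e-9  # |control - proband_S| below this counts as "no gap"


@dataclass(frozen=True)
class RescueConfig:
    """Thresholds for the three significance filters and the r-based labels.

    ``primary`` drives the disease filter (its ``lfc_min_primary`` is the
    fold-change cutoff there); ``rescue`` drives the treatment-responsiveness
    filter; ``off_target`` defaults to the rescue thresholds. Label cutoffs:
    r > overshoot_min -> overshoot; r >= full_min -> full; r >= partial_min
    -> partial.
    """

    primary: Thresholds = field(default_factory=Thresholds)
    rescue: Thresholds = field(default_factory=Thresholds)
    off_target: Thresholds | None = None
    partial_min: float = 0.05
    full_min: float = 0.8
    overshoot_min: float = 1.2
    test_method: str = "welch"
    responsive_family: str = "disease_altered"  # BH family for criterion 2
    off_target_rule: str = "raw_p"  # or "bh"

    def __post_init__(self) -> None:
        if not (0 < self.partial_min <= self.full_min <= self.overshoot_min):
            raise ValueError(
                "label cutoffs must satisfy 0 < partial_min <= full_min <= overshoot_min"
            )
        if self.responsive_family not in ("disease_altered", "all"):
            raise ValueError("responsive_family must be 'disease_altered' or 'all'")
        if self.off_target_rule not in ("raw_p", "bh"):
            raise ValueError("off_target_rule must be 'raw_p' or 'bh'")

    @property
    def off_target_thresholds(self) -> Thresholds:
        return self.off_target if self.off_target is not None else self.rescue


def disease_altered(
    results: list[pd.DataFrame], config: RescueConfig
) -> pd.DataFrame:
    """Disjunction of the disease contrasts at the primary thresholds.

    Accepts one comparison result (untreated proband-vs-control design) or
    several (one per qualifying contrast); all must share the same feature
    universe. Returns columns ``disease_altered`` and ``qualifying`` (a
    comma-joined list of contrast labels).
    """
    if not results:
        raise ValueError("at least one comparison result required")
    universe = results[0].index
    for res in results[1:]:
        if not universe.equals(res.index):
            diff = set(universe).symmetric_difference(res.index)
            raise ValueError(f"feature universes differ: {sorted(diff)[:10]}")
    thr = config.primary
    flags, quals = [], []
    for res in results:
        sig = (
            (res["log2FC"].abs() >= thr.lfc_min_primary)
            & (res["q"] <= thr.q_max)
        ).fillna(False)
        flags.append(sig.to_numpy())
        quals.append(res["contrast"].iloc[0] if len(res) else "")
    mat = np.column_stack(flags)
    qualifying = [
        ",".join(q for q, f in zip(quals, row) if f) for row in mat
    ]
    return pd.DataFrame(
        {"disease_altered": mat.any(axis=1), "qualifying": qualifying},
        index=universe,
    )


def shift_toward_control(zmatrix: ZMatrix, design: SampleDesign) -> pd.DataFrame:
    """Restoration fraction toward each control arm and the z-shift flag.

    For each control arm c, r_c = (mPT - mPS) / (m_c - mPS) using per-arm
    means of the z-scores; the flag is true when r_c > 0 for at least one arm
    with a non-degenerate denominator. The reported r is taken from the
    control arm with the larger |m_c - mPS| (the better-resolved gap).
    """
    arm_means = {}
    for arm in (PROBAND_S, PROBAND_T, CONTROL_S, CONTROL_T):
        samples = design.arm_samples(*arm)
        if not samples:
            raise ValueError(f"design lacks arm {arm}")
        arm_means[arm] = np.nanmean(
            zmatrix.values[samples].to_numpy(dtype=float), axis=1
        )
    m_ps, m_pt = arm_means[PROBAND_S], arm_means[PROBAND_T]
    num = m_pt - m_ps
    out = {}
    for name, arm in (("CS", CONTROL_S), ("CT", CONTROL_T)):
        denom = arm_means[arm] - m_ps
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(np.abs(denom) > EPS_DENOM, num / denom, np.nan)
        out[name] = (r, np.abs(denom))
    r_cs, gap_cs = out["CS"]
    r_ct, gap_ct = out["CT"]
    flag = (np.nan_to_num(r_cs, nan=-np.inf) > 0) | (
        np.nan_to_num(r_ct, nan=-np.inf) > 0
    )
    use_ct = gap_ct > gap_cs
    r = np.where(use_ct, r_ct, r_cs)
    # fall back to the other arm when the preferred denominator is degenerate
    r = np.where(np.isnan(r), np.where(use_ct, r_cs, r_ct), r)
    target = np.where(use_ct, "CT", "CS")
    target = np.where(np.isnan(r), "", target)
    return pd.DataFrame(
        {
            "shift_toward_control": flag,
            "target_arm": target,
            "restoration_fraction": r,
            "r_CS": r_cs,
            "r_CT": r_ct,
        },
        index=zmatrix.values.index,
    )


def off_target(result: pd.DataFrame, config: RescueConfig) -> pd.Series:
    """Flag features altered by ASO-T in control cells (excluded from rescue).

    With the default ``off_target_rule="raw_p"`` a feature is flagged when
    |log2FC| clears the off-target fold-change cutoff and the *unadjusted*
    p-value is below the threshold's q_max. An exclusion screen is kept
    deliberately sensitive: at the study's scale (n = 4 per arm) an
    FDR-adjusted exclusion test has almost no power against moderate ASO
    off-target effects, which would make the criterion vacuous, and
    over-excluding is the conservative direction for the final rescue set.
    ``off_target_rule="bh"`` restores BH-adjusted exclusion.
    """
    thr = config.off_target_thresholds
    evidence = result["p"] if config.off_target_rule == "raw_p" else result["q"]
    sig = (result["log2FC"].abs() >= thr.lfc_min) & (evidence <= thr.q_max)
    return sig.fillna(False).rename("off_target")


def _label(r: float, in_set: bool, config: RescueConfig) -> str:
    if not in_set or np.isnan(r):
        return "none"
    if r > config.overshoot_min:
        return "overshoot"
    if r >= config.full_min:
        return "full"
    if r >= config.partial_min:
        return "partial"
    return "none"


def classify(
    table: AbundanceTable,
    design: SampleDesign,
    config: RescueConfig = RescueConfig(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Run the full rescue-set procedure on a four-arm dataset.

    Returns (calls, summary): ``calls`` has one row per feature with every
    criterion flag, the qualifying disease contrast(s), the restoration
    fraction and the final label; ``summary`` counts features per label plus
    the rescue-set size. Deterministic given inputs.
    """
    res_ps_cs = run_contrast(
        table, design, Contrast(PROBAND_S, CONTROL_S, "PS_vs_CS"),
        config.primary, method=config.test_method,
        lfc_min=config.primary.lfc_min_primary,
    )
    res_ps_ct = run_contrast(
        table, design, Contrast(PROBAND_S, CONTROL_T, "PS_vs_CT"),
        config.primary, method=config.test_method,
        lfc_min=config.primary.lfc_min_primary,
    )
    res_pt_ps = run_contrast(
        table, design, Contrast(PROBAND_T, PROBAND_S, "PT_vs_PS"),
        config.rescue, method=config.test_method,
    )
    res_ct_cs = run_contrast(
        table, design, Contrast(CONTROL_T, CONTROL_S, "CT_vs_CS"),
        config.off_target_thresholds, method=config.test_method,
    )
    disease = disease_altered([res_ps_cs, res_ps_ct], config)
    shift = shift_toward_control(z_scores(table), design)
    off = off_target(res_ct_cs, config)

    # The restoration test is sequential: only disease-altered features are
    # candidates, so by default its BH family is that list rather than the
    # whole matrix (configurable back to the full universe).
    if config.responsive_family == "disease_altered":
        from .differential import bh_adjust

        p = res_pt_ps["p"].where(disease["disease_altered"], np.nan)
        q = pd.Series(bh_adjust(p), index=res_pt_ps.index)
        res_pt_ps = res_pt_ps.assign(
            q=q,
            significant=(
                (res_pt_ps["log2FC"].abs() >= config.rescue.lfc_min)
                & (q <= config.rescue.q_max)
            ).fillna(False),
        )
    responsive = res_pt_ps["significant"].rename("treatment_responsive")

    in_set = (
        disease["disease_altered"]
        & responsive
        & shift["shift_toward_control"]
        & ~off
    )
    calls = pd.DataFrame(
        {
            "disease_altered": disease["disease_altered"],
            "qualifying": disease["qualifying"],
            "treatment_responsive": responsive,
            "shift_toward_control": shift["shift_toward_control"],
            "target_arm": shift["target_arm"],
            "off_target": off,
            "in_rescue_set": in_set,
            "restoration_fraction": shift["restoration_fraction"],
            "log2FC_PS_vs_CS": res_ps_cs["log2FC"],
            "log2FC_PT_vs_PS": res_pt_ps["log2FC"],
            "log2FC_CT_vs_CS": res_ct_cs["log2FC"],
        },
        index=table.values.index,
    )
    calls["label"] = [
        _label(r, s, config)
        for r, s in zip(calls["restoration_fraction"], calls["in_rescue_set"])
    ]
    calls.index.name = "feature"
    counts = calls["label"].value_counts()
    summary = pd.Series(
        {
            "n_features": len(calls),
            "n_disease_altered": int(calls["disease_altered"].sum()),
            "n_off_target": int(calls["off_target"].sum()),
            "n_rescue_set": int(calls["in_rescue_set"].sum()),
            "n_full": int(counts.get("full", 0)),
            "n_partial": int(counts.get("partial", 0)),
            "n_overshoot": int(counts.get("overshoot", 0)),
        },
        name="count",
    )
    return calls, summary
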