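"""Founder-haplotype genetics and splice-variant prioritisation.

Covers: runs of homozygosity (ROH) around a focal variant, the minimal
region shared across families, a GQ-filtered haplotype-concordance matrix, a
Somalier-style relatedness screen, the MAF / SpliceAI / segregation variant
filter with splice-outlier proximity, and the four-tier gene prioritisation.

Boundary conventions follow the published filtering wording exactly:
MAF strictly < cutoff, SpliceAI delta >= cutoff, GQ strictly > cutoff, and
outlier proximity inclusive (distance <= window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    GenotypeMatrix,
    OutlierInterval,
    PedigreeSpec,
    distance_to_interval,
)

logger = logging.getLogger("asorescue")

DELTA_COLUMNS = ("ds_ag", "ds_al", "ds_dg", "ds_dl")  # acceptor/donor gain/loss


class GeneticsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROHSegment:
    """A run of homozygous calls containing the focal position."""

    individual: str
    chrom: str
    start: int
    end: int
    n_markers: int
    het_interruptions: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GeneticsError("ROH start > end")


def detect_roh(
    gm: GenotypeMatrix,
    individual: str,
    focal_pos: int,
    *,
    chrom: str | None = None,
    max_het: int = 0,
    gq_min: float = 0.0,
) -> ROHSegment:
    """Maximal run of homozygous calls containing the focal position.

    The run extends greedily in both directions from the focal marker,
    consuming at most ``max_het`` heterozygous calls in total (the split of
    the allowance between the two directions is chosen to maximise the
    marker count, ties going to the left extension). Missing calls and
    markers with GQ <= ``gq_min`` end the extension. Boundaries are the
    outermost *homozygous* markers included; a het or missing focal call is
    an error (no ROH contains it by definition).
    """
    if chrom is None:
        hits = gm.markers.index[gm.markers["pos"] == focal_pos]
        if len(hits) != 1:
            raise GeneticsError(
                f"focal position {focal_pos} matches {len(hits)} marker(s); "
                "pass chrom to disambiguate"
            )
        chrom = gm.markers.at[hits[0], "chrom"]
    on_chrom = np.flatnonzero(gm.markers["chrom"] == chrom)
    pos = gm.markers["pos"].to_numpy()[on_chrom]
    calls = gm.column(individual)[on_chrom]
    gq = gm.gq_column(individual)[on_chrom]
    # low-GQ markers are unusable for this individual: treated like missing
    calls = np.where(gq > gq_min, calls, MISSING)
    focal_hits = np.flatnonzero(pos == focal_pos)
    if len(focal_hits) == 0:
        raise GeneticsError(f"no marker at {chrom}:{focal_pos}")
    f = int(focal_hits[0])
    if calls[f] not in (0, 2):
        raise GeneticsError(
            f"{individual}: focal call at {chrom}:{focal_pos} is not homozygous"
        )

    def extend(direction: int, budget: int) -> tuple[int, int]:
        """Walk from focal; return (outermost hom index, hets consumed)."""
        boundary, used = f, 0
        i = f + direction
        pending_hets = 0
        while 0 <= i < len(calls):
            c = calls[i]
            if c in (0, 2):
                boundary = i
                used += pending_hets
                pending_hets = 0
            elif c == 1:
                if used + pending_hets + 1 > budget:
                    break
                pending_hets += 1
            else:  # missing / low-GQ: blocks extension
                break
            i += direction
        return boundary, used

    best = None
    for left_budget in range(max_het, -1, -1):
        li, lu = extend(-1, left_budget)
        ri, ru = extend(+1, max_het - left_budget)
        n = ri - li + 1
        if best is None or n > best[0]:
            best = (n, li, ri, lu + ru)
    n, li, ri, used = best
    return ROHSegment(individual, chrom, int(pos[li]), int(pos[ri]), n, used)


def minimal_shared_region(segments: Sequence[ROHSegment]) -> tuple[str, int, int]:
    """Intersection of ROH segments that all contain the focal position."""
    if not segments:
        raise GeneticsError("no segments given")
    chroms = {s.chrom for s in segments}
    if len(chroms) > 1:
        raise GeneticsError(f"segments on different chromosomes: {sorted(chroms)}")
    start = max(s.start for s in segments)
    end = min(s.end for s in segments)
    if start > end:
        raise GeneticsError("segments are disjoint")
    return (segments[0].chrom, start, end)


# ---------------------------------------------------------------------------
# haplotype-concordance matrix
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMatrix:
    """GQ-filtered allele states in a region plus the concordant sub-interval.

    ``states`` is markers (indexed by position) x individuals with values
    0 (hom ref), 1 (het), 2 (hom alt). ``funnel`` records marker counts at
    each filter step; ``concordant`` is the maximal interval around the focal
    position where all carrier individuals share an identical allele count.
    """

    chrom: str
    states: pd.DataFrame
    funnel: dict[str, int]
    concordant: tuple[int, int]


def haplotype_matrix(
    gm: GenotypeMatrix,
    region: tuple[str, int, int],
    individuals: Sequence[str],
    focal_pos: int,
    carriers: Sequence[str],
    *,
    gq_min: float = 35.0,
) -> HaplotypeMatrix:
    """High-quality shared-region variants and the concordance interval.

    Markers inside ``region`` are kept only if called in *all* individuals
    and with GQ strictly greater than ``gq_min`` in all of them. The
    concordant sub-interval extends from the focal marker outwards while all
    ``carriers`` (the homozygous affected individuals) agree on the allele
    count at every kept marker.
    """
    chrom, start, end = region
    cols = [gm.individuals.index(i) for i in individuals]
    in_region = np.flatnonzero(
        (gm.markers["chrom"] == chrom)
        & (gm.markers["pos"] >= start)
        & (gm.markers["pos"] <= end)
    )
    total = len(in_region)
    sub_geno = gm.geno[np.ix_(in_region, cols)]
    sub_gq = gm.gq[np.ix_(in_region, cols)]
    called = (sub_geno != MISSING).all(axis=1)
    n_drop_call = int((~called).sum())
    good_gq = (sub_gq > gq_min).all(axis=1)
    keep = called & good_gq
    n_drop_gq = int((called & ~good_gq).sum())
    kept = int(keep.sum())
    funnel = dict(total=total, dropped_by_call=n_drop_call,
                  dropped_by_gq=n_drop_gq, kept=kept)
    logger.info(
        "haplotype matrix funnel: %d -> %d (dropped: %d uncalled, %d low GQ)",
        total, kept, n_drop_call, n_drop_gq,
    )
    if kept == 0:
        raise GeneticsError(f"no markers survive filtering; funnel: {funnel}")
    kept_idx = in_region[keep]
    positions = gm.markers["pos"].to_numpy()[kept_idx]
    states = pd.DataFrame(
        gm.geno[np.ix_(kept_idx, cols)],
        index=pd.Index(positions, name="pos"),
        columns=list(individuals),
    )
    carrier_states = states[list(carriers)].to_numpy()
    agree = (carrier_states == carrier_states[:, [0]]).all(axis=1)
    at_or_before = np.searchsorted(positions, focal_pos, side="right") - 1
    if at_or_before < 0 or positions[at_or_before] != focal_pos:
        # the focal marker itself may have been filtered out; anchor on the
        # nearest kept marker inside the region instead
        anchor = int(np.argmin(np.abs(positions - focal_pos)))
    else:
        anchor = int(at_or_before)
    if not agree[anchor]:
        raise GeneticsError("carriers disagree at the anchor marker")
    lo = anchor
    while lo - 1 >= 0 and agree[lo - 1]:
        lo -= 1
    hi = anchor
    while hi + 1 < len(positions) and agree[hi + 1]:
        hi += 1
    return HaplotypeMatrix(chrom, states, funnel,
                           (int(positions[lo]), int(positions[hi])))


# ---------------------------------------------------------------------------
# relatedness screen
# ---------------------------------------------------------------------------

UNRELATED_CUTOFF = 0.05


def relatedness(
    gm: GenotypeMatrix,
    individual_i: str,
    individual_j: str,
    *,
    min_markers: int = 200,
) -> float:
    """Somalier-style pairwise relatedness from shared genotype calls.

    score = (N_both_het - 2 * N_opposite_hom) / min(N_het_i, N_het_j)
    over markers called in both individuals. Near zero for unrelated pairs;
    the screen classifies a pair as unrelated when score < 0.05.
    """
    a = gm.column(individual_i)
    b = gm.column(individual_j)
    both = (a != MISSING) & (b != MISSING)
    n_overlap = int(both.sum())
    if n_overlap < min_markers:
        raise GeneticsError(
            f"only {n_overlap} overlapping markers (< {min_markers})"
        )
    a, b = a[both], b[both]
    n_both_het = int(((a == 1) & (b == 1)).sum())
    n_opp_hom = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    n_het_i = int((a == 1).sum())
    n_het_j = int((b == 1).sum())
    denom = min(n_het_i, n_het_j)
    if denom == 0:
        raise GeneticsError("one individual has no heterozygous calls in overlap")
    return (n_both_het - 2 * n_opp_hom) / denom


def is_unrelated(score: float, cutoff: float = UNRELATED_CUTOFF) -> bool:
    return score < cutoff


# ---------------------------------------------------------------------------
# variant prioritisation
# ---------------------------------------------------------------------------


def max_delta(variants: pd.DataFrame) -> pd.Series:
    """Row-wise maximum of the four SpliceAI delta scores."""
    for col in DELTA_COLUMNS:
        if col not in variants.columns:
            raise GeneticsError(f"variant table missing delta column {col!r}")
    return variants[list(DELTA_COLUMNS)].max(axis=1)


def _gt(variants: pd.DataFrame, individual: str) -> pd.Series:
    col = f"gt_{individual}"
    if col not in variants.columns:
        raise GeneticsError(f"variant table lacks genotypes for {individual!r}")
    return variants[col]


def _segregation_recessive(
    variants: pd.DataFrame, pedigree: PedigreeSpec
) -> pd.Series:
    """Homozygous-recessive segregation: affected 2, unaffected parents 1,
    unaffected sibs 0 or 1. Missing genotypes degrade to 'unknown'."""
    status = pd.Series("segregates", index=variants.index)
    unknown = pd.Series(False, index=variants.index)
    fails = pd.Series(False, index=variants.index)
    for affected in pedigree.affected():
        g = _gt(variants, affected)
        unknown |= g == MISSING
        fails |= (g != MISSING) & (g != 2)
        father, mother = pedigree.parents(affected)
        for parent in (father, mother):
            if parent is None:
                unknown |= True
                continue
            pg = _gt(variants, parent)
            if pedigree.table.at[parent, "affected"] == "no":
                unknown |= pg == MISSING
                fails |= (pg != MISSING) & (pg != 1)
        for sib in pedigree.siblings(affected):
            if pedigree.table.at[sib, "affected"] != "no":
                continue
            sg = _gt(variants, sib)
            unknown |= sg == MISSING
            fails |= (sg != MISSING) & ~sg.isin([0, 1])
    status[unknown] = "unknown"
    status[fails] = "fails"
    return status


def _segregation_de_novo(variants: pd.DataFrame, pedigree: PedigreeSpec) -> pd.Series:
    status = pd.Series("segregates", index=variants.index)
    unknown = pd.Series(False, index=variants.index)
    fails = pd.Series(False, index=variants.index)
    for affected in pedigree.affected():
        g = _gt(variants, affected)
        unknown |= g == MISSING
        fails |= (g != MISSING) & (g == 0)
        for parent in pedigree.parents(affected):
            if parent is None:
                unknown |= True
                continue
            pg = _gt(variants, parent)
            unknown |= pg == MISSING
            fails |= (pg != MISSING) & (pg != 0)
    status[unknown] = "unknown"
    status[fails] = "fails"
    return status


def prioritise_variants(
    variants: pd.DataFrame,
    pedigree: PedigreeSpec,
    mode: str,
    *,
    maf_max: float = 0.01,
    delta_min: float = 0.10,
) -> pd.DataFrame:
    """Retain rare, splice-disrupting, segregating variants.

    Filters: population MAF strictly below ``maf_max``; maximum SpliceAI
    delta score at least ``delta_min``; segregation consistent with ``mode``
    (``recessive_hom``, ``comp_het`` or ``de_novo``). Variants whose
    segregation cannot be evaluated because a parental genotype is missing
    are retained with segregation status ``unknown`` rather than dropped.
    Output is sorted by tier (if assigned) then descending max delta.
    """
    if mode not in ("recessive_hom", "comp_het", "de_novo"):
        raise GeneticsError(f"unknown segregation mode {mode!r}")
    v = variants.copy()
    v["max_delta"] = max_delta(v)
    keep = (v["maf"] < maf_max) & (v["max_delta"] >= delta_min)
    v = v[keep].copy()

    if mode == "recessive_hom":
        v["segregation"] = _segregation_recessive(v, pedigree)
        v = v[v["segregation"] != "fails"]
    elif mode == "de_novo":
        v["segregation"] = _segregation_de_novo(v, pedigree)
        v = v[v["segregation"] != "fails"]
    else:  # comp_het: >= 2 retained variants in one gene, one from each parent
        v["segregation"] = "unknown"
        keep_rows = []
        for affected in pedigree.affected():
            father, mother = pedigree.parents(affected)
            g_aff = _gt(v, affected)
            candidate = g_aff == 1
            if father is None or mother is None:
                v.loc[candidate, "segregation"] = "unknown"
                keep_rows.append(candidate)
                continue
            g_f, g_m = _gt(v, father), _gt(v, mother)
            paternal = candidate & (g_f >= 1) & (g_m == 0)
            maternal = candidate & (g_m >= 1) & (g_f == 0)
            unknown = candidate & ((g_f == MISSING) | (g_m == MISSING))
            for gene, grp in v.groupby("gene"):
                idx = grp.index
                if paternal[idx].any() and maternal[idx].any():
                    ok = idx[(paternal | maternal | unknown)[idx]]
                    v.loc[ok, "segregation"] = "segregates"
                    keep_rows.append(pd.Series(v.index.isin(ok), index=v.index))
                elif unknown[idx].any():
                    ok = idx[unknown[idx]]
                    keep_rows.append(pd.Series(v.index.isin(ok), index=v.index))
        if keep_rows:
            mask = np.logical_or.reduce([m.to_numpy() for m in keep_rows])
        else:
            mask = np.zeros(len(v), dtype=bool)
        v = v[mask]

    sort_cols = ["max_delta"]
    ascending = [False]
    if "tier" in v.columns:
        sort_cols = ["tier", "max_delta"]
        ascending = [True, False]
    return v.sort_values(sort_cols, ascending=ascending, kind="mergesort")


def outlier_proximity(
    variants: pd.DataFrame,
    outliers: Iterable[OutlierInterval],
    *,
    window: int = 250,
) -> pd.DataFrame:
    """Flag variants within ``window`` bp (inclusive) of any outlier interval.

    Adds ``outlier_distance`` (nearest interval on the same chromosome; NaN
    when there is none) and ``outlier_proximal``.
    """
    outliers = list(outliers)
    v = variants.copy()
    dist = np.full(len(v), np.nan)
    for i, (chrom, pos) in enumerate(zip(v["chrom"], v["pos"])):
        best = None
        for iv in outliers:
            if iv.chrom != chrom:
                continue
            d = distance_to_interval(int(pos), iv.start, iv.end)
            best = d if best is None else min(best, d)
        if best is not None:
            dist[i] = best
    v["outlier_distance"] = dist
    v["outlier_proximal"] = ~np.isnan(dist) & (dist <= window)
    return v


def assign_tiers(
    variants: pd.DataFrame,
    gene_list_1: Iterable[str],
    gene_list_2: Iterable[str],
    gene_list_3: Iterable[str],
) -> pd.DataFrame:
    """Four-tier gene prioritisation; membership is case-insensitive.

    Tier 1: neuromuscular/neurological genes; tier 2: other clinically
    relevant Mendelian genes; tier 3: murine-essential genes without a known
    human disorder; tier 4: all remaining genes. A gene in several lists
    takes the first (lowest) tier; a variant without a gene symbol is tier 4
    with a warning.
    """
    lists = [
        {g.upper() for g in gene_list_1},
        {g.upper() for g in gene_list_2},
        {g.upper() for g in gene_list_3},
    ]
    tiers = []
    for gene in variants["gene"]:
        if gene is None or (isinstance(gene, float) and np.isnan(gene)) or gene == "":
            logger.warning("variant without gene symbol assigned tier 4")
            tiers.append(4)
            continue
        up = str(gene).upper()
        for tier, members in enumerate(lists, start=1):
            if up in members:
                tiers.append(tier)
                break
        else:
            tiers.append(4)
    out = variants.copy()
    out["tier"] = tiers
    return out
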