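import numpy as np
import pandas as pd
import pytest

from asorescue import genetics
from asorescue.io_formats import MISSING, GenotypeMatrix, OutlierInterval, PedigreeSpec
from asorescue.simulate import simulate_variant_table


def _gm(calls, gq=None, positions=None, chrom="chr1"):
    """Single-individual genotype matrix from a call vector."""
    calls = np.asarray(calls, dtype=np.int8).reshape(-1, 1)
    n = len(calls)
    positions = positions if positions is not None else 100 * np.arange(1, n + 1)
    markers = pd.DataFrame(dict(chrom=chrom, pos=positions,
                                ref=["A"] * n, alt=["G"] * n))
    gq = np.full((n, 1), 99.0) if gq is None else np.asarray(gq, float).reshape(-1, 1)
    return GenotypeMatrix(markers, ["ind"], calls, gq)


class TestDetectRoh:
    # positions 100..600 with calls [2, 2, 0, 2, 1, 2]; focal marker at 400
    CALLS = [2, 2, 0, 2, 1, 2]

    def test_het_stops_run(self):
        seg = genetics.detect_roh(_gm(self.CALLS), "ind", 400)
        assert (seg.start, seg.end) == (100, 400)
        assert seg.n_markers == 4 and seg.het_interruptions == 0

    def test_het_allowance_extends_run(self):
        seg = genetics.detect_roh(_gm(self.CALLS), "ind", 400, max_het=1)
        assert (seg.start, seg.end) == (100, 600)
        assert seg.het_interruptions == 1

    def test_all_homozygous_spans_everything(self):
        seg = genetics.detect_roh(_gm([2, 0, 2, 2, 0]), "ind", 300)
        assert (seg.start, seg.end) == (100, 500)

    def test_het_or_missing_focal_rejected(self):
        with pytest.raises(genetics.GeneticsError, match="not homozygous"):
            genetics.detect_roh(_gm([2, 1, 2]), "ind", 200)
        with pytest.raises(genetics.GeneticsError, match="not homozygous"):
            genetics.detect_roh(_gm([2, MISSING, 2]), "ind", 200)

    def test_missing_call_blocks_extension(self):
        seg = genetics.detect_roh(_gm([2, MISSING, 2, 2]), "ind", 300, max_het=5)
        assert (seg.start, seg.end) == (300, 400)

    def test_low_gq_marker_ignored(self):
        gq = [99, 10, 99, 99]
        seg = genetics.detect_roh(_gm([2, 2, 2, 2], gq=gq), "ind", 300, gq_min=35)
        assert (seg.start, seg.end) == (300, 400)

    def test_growing_allowance_never_shrinks_segment(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([0, 1, 2], size=60, p=[0.4, 0.2, 0.4])
        calls[30] = 2
        gm = _gm(calls)
        focal = int(gm.markers["pos"][30])
        prev = 0
        for max_het in range(4):
            seg = genetics.detect_roh(gm, "ind", focal, max_het=max_het)
            assert seg.start <= focal <= seg.end
            assert seg.n_markers >= prev
            prev = seg.n_markers


class TestMinimalSharedRegion:
    def _seg(self, start, end):
        return genetics.ROHSegment("x", "chr1", start, end, 1, 0)

    def test_pairwise_intersection(self):
        assert genetics.minimal_shared_region(
            [self._seg(100, 900), self._seg(200, 700)]) == ("chr1", 200, 700)

    def test_single_segment_is_itself(self):
        assert genetics.minimal_shared_region([self._seg(5, 9)]) == ("chr1", 5, 9)

    def test_nested_segments_give_innermost(self):
        segs = [self._seg(1, 100), self._seg(10, 90), self._seg(20, 80)]
        assert genetics.minimal_shared_region(segs) == ("chr1", 20, 80)

    def test_disjoint_rejected(self):
        with pytest.raises(genetics.GeneticsError, match="disjoint"):
            genetics.minimal_shared_region([self._seg(1, 5), self._seg(10, 20)])


class TestHaplotypeMatrix:
    def _gm_two(self, geno, gq):
        n = geno.shape[0]
        markers = pd.DataFrame(dict(chrom="chr1", pos=100 * np.arange(1, n + 1),
                                    ref=["A"] * n, alt=["G"] * n))
        return GenotypeMatrix(markers, ["p1", "p2"], geno.astype(np.int8),
                              gq.astype(float))

    def test_gq_exactly_35_excluded(self):
        geno = np.array([[2, 2], [2, 2], [2, 2]])
        gq = np.array([[36, 36], [35, 99], [99, 99]])
        gm = self._gm_two(geno, gq)
        hm = genetics.haplotype_matrix(gm, ("chr1", 100, 300), ["p1", "p2"],
                                       100, ["p1", "p2"])
        assert list(hm.states.index) == [100, 300]
        assert hm.funnel == dict(total=3, dropped_by_call=0, dropped_by_gq=1,
                                 kept=2)

    def test_concordance_ends_at_divergence(self):
        geno = np.array([[2, 2], [2, 2], [2, 0], [2, 2]])
        gq = np.full((4, 2), 99.0)
        gm = self._gm_two(geno, gq)
        hm = genetics.haplotype_matrix(gm, ("chr1", 100, 400), ["p1", "p2"],
                                       100, ["p1", "p2"])
        assert hm.concordant == (100, 200)

    def test_funnel_arithmetic(self):
        rng = np.random.default_rng(1)
        geno = rng.choice([0, 1, 2, MISSING], size=(50, 2), p=[0.4, 0.1, 0.4, 0.1])
        geno[0] = [2, 2]
        gq = rng.uniform(20, 99, size=(50, 2))
        gq[0] = 99
        gm = self._gm_two(geno, gq)
        hm = genetics.haplotype_matrix(gm, ("chr1", 100, 5000), ["p1", "p2"],
                                       100, ["p1"])
        f = hm.funnel
        assert f["kept"] + f["dropped_by_call"] + f["dropped_by_gq"] == f["total"]

    def test_no_survivors_reports_funnel(self):
        geno = np.array([[2, 2]])
        gq = np.array([[10.0, 10.0]])
        with pytest.raises(genetics.GeneticsError, match="funnel"):
            genetics.haplotype_matrix(self._gm_two(geno, gq), ("chr1", 100, 100),
                                      ["p1", "p2"], 100, ["p1"])


class TestRelatedness:
    def _pair(self, a, b):
        a, b = np.asarray(a, np.int8), np.asarray(b, np.int8)
        n = len(a)
        markers = pd.DataFrame(dict(chrom="chr1", pos=np.arange(1, n + 1),
                                    ref=["A"] * n, alt=["G"] * n))
        return GenotypeMatrix(markers, ["i", "j"], np.column_stack([a, b]),
                              np.full((n, 2), 99.0))

    def test_identical_genomes_score_one(self):
        calls = [0, 1, 2, 1, 0, 1, 2, 2, 1, 0]
        gm = self._pair(calls, calls)
        assert genetics.relatedness(gm, "i", "j", min_markers=5) == 1.0

    def test_hand_computed_negative_score(self):
        # 1 shared het and 10 opposite homozygotes: (1 - 20) / 1 = -19
        a = [1] + [0] * 10
        b = [1] + [2] * 10
        gm = self._pair(a, b)
        assert genetics.relatedness(gm, "i", "j", min_markers=5) == -19.0

    def test_no_hets_is_an_error(self):
        gm = self._pair([0] * 10, [2] * 10)
        with pytest.raises(genetics.GeneticsError, match="heterozygous"):
            genetics.relatedness(gm, "i", "j", min_markers=5)

    def test_too_few_markers_rejected(self):
        gm = self._pair([1, 1], [1, 1])
        with pytest.raises(genetics.GeneticsError, match="overlapping"):
            genetics.relatedness(gm, "i", "j")


def _trio():
    return PedigreeSpec(pd.DataFrame(
        {"father": [None, None, "father"], "mother": [None, None, "mother"],
         "sex": ["male", "female", "female"],
         "affected": ["no", "no", "yes"]},
        index=pd.Index(["father", "mother", "proband"], name="id")))


def _variant(**kw):
    row = dict(chrom="chr1", pos=1000, ref="G", alt="A", gene="GENE1", maf=0.0,
               ds_ag=0.0, ds_al=0.0, ds_dg=0.42, ds_dl=0.0,
               gt_proband=2, gt_father=1, gt_mother=1)
    row.update(kw)
    return row


class TestPrioritiseVariants:
    def test_causal_variant_retained(self):
        out = genetics.prioritise_variants(pd.DataFrame([_variant()]), _trio(),
                                           "recessive_hom")
        assert len(out) == 1 and out.iloc[0]["segregation"] == "segregates"

    @pytest.mark.parametrize(
        "kw,kept",
        [
            (dict(ds_dg=0.10), True),   # delta boundary is inclusive
            (dict(ds_dg=0.09), False),
            (dict(maf=0.02), False),
            (dict(maf=0.009), True),    # MAF boundary is strict
            (dict(maf=0.01), False),
            (dict(gt_proband=1), False),
            (dict(gt_father=2), False),
        ],
    )
    def test_filter_boundaries(self, kw, kept):
        out = genetics.prioritise_variants(pd.DataFrame([_variant(**kw)]),
                                           _trio(), "recessive_hom")
        assert (len(out) == 1) == kept

    def test_missing_parent_genotype_kept_as_unknown(self):
        out = genetics.prioritise_variants(
            pd.DataFrame([_variant(gt_father=MISSING)]), _trio(), "recessive_hom")
        assert len(out) == 1 and out.iloc[0]["segregation"] == "unknown"

    def test_order_independent_and_idempotent(self):
        rows = [_variant(pos=1000), _variant(pos=2000, ds_dg=0.2, gene="GENE2"),
                _variant(pos=3000, maf=0.5)]
        v = pd.DataFrame(rows)
        out1 = genetics.prioritise_variants(v, _trio(), "recessive_hom")
        out2 = genetics.prioritise_variants(v.iloc[::-1], _trio(), "recessive_hom")
        assert list(out1["pos"]) == list(out2["pos"])
        again = genetics.prioritise_variants(out1, _trio(), "recessive_hom")
        assert list(again["pos"]) == list(out1["pos"])

    def test_unknown_mode_rejected(self):
        with pytest.raises(genetics.GeneticsError):
            genetics.prioritise_variants(pd.DataFrame([_variant()]), _trio(),
                                         "dominant")

    def test_comp_het_requires_one_from_each_parent(self):
        rows = [
            _variant(pos=1000, gt_proband=1, gt_father=1, gt_mother=0),
            _variant(pos=2000, gt_proband=1, gt_father=0, gt_mother=1),
            _variant(pos=9000, gene="GENE2", gt_proband=1, gt_father=1,
                     gt_mother=0),
        ]
        out = genetics.prioritise_variants(pd.DataFrame(rows), _trio(), "comp_het")
        assert set(out["gene"]) == {"GENE1"} and len(out) == 2


class TestOutlierProximity:
    INTERVAL = [OutlierInterval("chr17", 47_974_586, 47_974_688)]

    def test_published_cryptic_acceptor_distance(self):
        v = pd.DataFrame([_variant(chrom="chr17", pos=47_974_691)])
        out = genetics.outlier_proximity(v, self.INTERVAL)
        assert out.iloc[0]["outlier_distance"] == 3
        assert bool(out.iloc[0]["outlier_proximal"])

    @pytest.mark.parametrize("pos,flagged", [(47_974_938, True),
                                             (47_974_939, False)])
    def test_window_boundary_inclusive(self, pos, flagged):
        v = pd.DataFrame([_variant(chrom="chr17", pos=pos)])
        out = genetics.outlier_proximity(v, self.INTERVAL)
        assert bool(out.iloc[0]["outlier_proximal"]) == flagged

    def test_empty_outlier_table(self):
        out = genetics.outlier_proximity(pd.DataFrame([_variant()]), [])
        assert not out["outlier_proximal"].any()
        assert np.isnan(out.iloc[0]["outlier_distance"])


class TestAssignTiers:
    def test_precedence_case_and_default(self):
        v = pd.DataFrame([_variant(gene="Cdk5rap3"), _variant(gene="TTN"),
                          _variant(gene="NOVEL1")])
        out = genetics.assign_tiers(v, ["CDK5RAP3", "TTN"], ["TTN"], [])
        assert list(out["tier"]) == [1, 1, 4]

    def test_missing_gene_symbol_tier4(self, caplog):
        out = genetics.assign_tiers(pd.DataFrame([_variant(gene=None)]),
                                    ["A"], [], [])
        assert out.iloc[0]["tier"] == 4


class TestEndToEndVariants:
    def test_unique_survivor_among_designed_decoys(self):
        variants, outliers, ped, truth = simulate_variant_table(n_decoys=8, seed=1)
        kept = genetics.prioritise_variants(variants, ped, "recessive_hom")
        kept = genetics.outlier_proximity(kept, outliers)
        assert list(kept["gene"]) == ["CDK5RAP3"]
        assert bool(kept.iloc[0]["outlier_proximal"])
        # every decoy fails exactly its designed filter
        decoys = truth.data[truth.data["kind"] != "causal"]
        assert not set(decoys["gene"]) & set(kept["gene"])
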