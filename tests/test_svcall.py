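"""Split-read classification, candidate calling, depth filters."""

import itertools

import numpy as np
import pytest

from balancerscan.core_io import DepthTrack
from balancerscan.realign import Placement, SplitRead
from balancerscan.svcall import (
    DepthRatio,
    VariantCandidate,
    apply_depth_filters,
    call_deletions,
    call_large_breakpoint_pairs,
    call_paired_variants,
    classify_split_read,
    cluster_split_reads,
    depth_ratio,
    filter_complicated,
    normalized_depth,
    subtract_control,
)


def sr(lg5, s5, e5, st5, lg3, s3, e3, st3, read_id="r", category=None):
    out = SplitRead(read_id=read_id,
                    seg5=Placement(lg5, s5, e5, st5),
                    seg3=Placement(lg3, s3, e3, st3),
                    category=category)
    if lg5 == lg3:
        out.gap = out.junction3 - out.junction5
    return out


def classify_oracle(sr_obj: SplitRead) -> str:
    """Independent geometry oracle, straight from the category definitions."""
    a, b = sr_obj.seg5, sr_obj.seg3
    if a.lg != b.lg:
        return ("translocational_inversion" if a.strand != b.strand
                else "translocation")
    if a.strand != b.strand:
        return "inversion"
    j5 = a.end if a.strand == "+" else a.start
    j3 = b.start if b.strand == "+" else b.end
    direction = (j3 - j5) if a.strand == "+" else (j5 - j3)
    return "deletion" if direction > 0 else "insertion"


class TestClassification:
    def test_downstream_same_strand_is_deletion(self):
        assert classify_split_read(
            sr("chrI", 1000, 1090, "+", "chrI", 5000, 5050, "+")) == "deletion"

    def test_opposite_strand_same_group_is_inversion(self):
        assert classify_split_read(
            sr("chrI", 1000, 1090, "+", "chrI", 5000, 5050, "-")) == "inversion"

    def test_different_group_opposite_strand_is_translocational_inversion(self):
        assert classify_split_read(
            sr("chrI", 1000, 1090, "+", "chrII", 500, 550, "-")) == \
            "translocational_inversion"

    def test_identical_placements_error(self):
        with pytest.raises(ValueError):
            classify_split_read(
                sr("chrI", 1000, 1090, "+", "chrI", 1000, 1090, "+"))

    def test_exhaustive_geometry_agrees_with_oracle(self):
        """Totality: all (group, strand, order) combinations, one category
        each, agreeing with an independently coded oracle."""
        coords = [(1000, 1060), (5000, 5070)]
        for lg3, st5, st3, (c5, c3) in itertools.product(
                ["chrI", "chrII"], "+-", "+-",
                itertools.permutations(range(2), 2)):
            s5, e5 = coords[c5]
            s3, e3 = coords[c3]
            x = sr("chrI", s5, e5, st5, lg3, s3, e3, st3)
            got = classify_split_read(x)
            assert got in {"deletion", "insertion", "inversion",
                           "translocation", "translocational_inversion"}
            assert got == classify_oracle(x), (st5, st3, lg3, c5, c3)


class TestControlSubtraction:
    def test_identical_sr_removed(self):
        case = [sr("chrI", 0, 90, "+", "chrI", 500, 550, "+",
                   category="deletion")]
        ctrl = [sr("chrI", 0, 90, "+", "chrI", 500, 550, "+",
                   category="deletion")]
        assert subtract_control(case, ctrl) == []

    def test_case_only_sr_kept(self):
        case = [sr("chrI", 0, 90, "+", "chrI", 500, 550, "+",
                   category="deletion")]
        assert subtract_control(case, []) == case

    def test_same_loci_different_category_kept(self):
        case = [sr("chrI", 0, 90, "+", "chrI", 500, 550, "+",
                   category="deletion")]
        ctrl = [sr("chrI", 0, 90, "+", "chrI", 500, 550, "-",
                   category="inversion")]
        assert subtract_control(case, ctrl) == case

    def test_tolerance_boundary(self):
        case = [sr("chrI", 0, 90, "+", "chrI", 500, 550, "+",
                   category="deletion")]
        near = [sr("chrI", 0, 100, "+", "chrI", 510, 560, "+",
                   category="deletion")]
        far = [sr("chrI", 0, 101, "+", "chrI", 511, 561, "+",
                  category="deletion")]
        assert subtract_control(case, near, tol=10) == []
        assert subtract_control(case, far, tol=10) == case

    def test_rule_oracle_over_enumerated_pairs(self):
        # removal iff same category AND both junctions within tol
        base = sr("chrI", 0, 90, "+", "chrI", 500, 550, "+",
                  category="deletion")
        for cat, dj5, dj3 in itertools.product(
                ["deletion", "insertion"], [0, 10, 11], [0, 10, 11]):
            ctrl = [sr("chrI", 0, 90 + dj5, "+", "chrI", 500 + dj3, 550, "+",
                       category=cat)]
            removed = subtract_control([base], ctrl, tol=10) == []
            expected = (cat == "deletion" and dj5 <= 10 and dj3 <= 10)
            assert removed == expected, (cat, dj5, dj3)


class TestDeletionCalling:
    def _cluster(self, n, j5=1000, j3=1500):
        return [sr("chrI", j5 - 90, j5, "+", "chrI", j3, j3 + 50, "+",
                   read_id=f"r{j5}_{i}", category="deletion")
                for i in range(n)]

    def test_three_srs_make_a_candidate(self):
        cands = call_deletions(self._cluster(3))
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end, cands[0].count) == (1000, 1500, 3)

    def test_two_srs_do_not(self):
        assert call_deletions(self._cluster(2)) == []

    def test_two_plus_two_at_distinct_gaps_do_not(self):
        srs = self._cluster(2) + self._cluster(2, j5=3000, j3=3700)
        assert call_deletions(srs) == []


class TestPairedVariants:
    def test_del_plus_ins_clusters_call_insertion(self):
        # copy of [4000, 4300) inserted at 1000: left junction gives
        # deletion-type SRs (1000 -> 4000), right gives insertion-type
        # (4300 -> 1000)
        srs = []
        for i in range(6):
            srs.append(sr("chrI", 910, 1000, "+", "chrI", 4000, 4090, "+",
                          read_id=f"d{i}", category="deletion"))
            srs.append(sr("chrI", 4210, 4300, "+", "chrI", 1000, 1090, "+",
                          read_id=f"i{i}", category="insertion"))
        cands = call_paired_variants(srs)
        ins = [c for c in cands if c.kind == "insertion"]
        assert len(ins) == 1
        assert (ins[0].start, ins[0].end) == (4000, 4300)
        assert ins[0].pos2 == 1000
        assert ins[0].count == 12

    def test_single_sided_cluster_no_candidate(self):
        srs = [sr("chrI", 910, 1000, "+", "chrI", 4000, 4090, "+",
                  read_id=f"d{i}", category="deletion") for i in range(6)]
        assert call_paired_variants(srs) == []

    def test_border_gap_also_calls_deletion(self):
        # junction coordinates differ by 5 bp at the insertion point: the
        # target site lost bases
        srs = []
        for i in range(6):
            srs.append(sr("chrI", 910, 1000, "+", "chrI", 4000, 4090, "+",
                          read_id=f"d{i}", category="deletion"))
            srs.append(sr("chrI", 4210, 4300, "+", "chrI", 1005, 1090, "+",
                          read_id=f"i{i}", category="insertion"))
        cands = call_paired_variants(srs)
        kinds = sorted(c.kind for c in cands)
        assert kinds == ["deletion", "insertion"]
        gap = [c for c in cands if c.kind == "deletion"][0]
        assert (gap.start, gap.end) == (1000, 1005)

    def test_reciprocal_inversion_clusters_call_local_inversion(self):
        srs = []
        for i in range(5):
            srs.append(sr("chrI", 910, 1000, "+", "chrI", 1310, 1400, "-",
                          read_id=f"a{i}", category="inversion"))
            srs.append(sr("chrI", 1000, 1090, "-", "chrI", 1400, 1490, "+",
                          read_id=f"b{i}", category="inversion"))
        cands = call_paired_variants(srs)
        assert len(cands) == 1
        c = cands[0]
        assert c.kind == "local_inversion_or_inverted_insertion"
        assert (c.start, c.end) == (1000, 1400)


class TestLargeBreakpointPairs:
    def test_reciprocal_inversion_clusters_pair_up(self):
        srs = []
        for i in range(5):
            srs.append(sr("chrI", 9910, 10000, "+", "chrI", 29910, 30000, "-",
                          read_id=f"a{i}", category="inversion"))
            srs.append(sr("chrI", 10000, 10090, "-", "chrI", 30000, 30090, "+",
                          read_id=f"b{i}", category="inversion"))
        cands = call_large_breakpoint_pairs(srs)
        assert len(cands) == 1
        c = cands[0]
        assert c.kind == "inversion_breakpoint_pair"
        assert (c.start, c.end) == (10000, 30000)
        assert c.count == 10 and c.notes == ""

    def test_translocation_clusters_pair_up(self):
        srs = []
        for i in range(5):
            srs.append(sr("chrI", 44910, 45000, "+", "chrII", 25000, 25090, "+",
                          read_id=f"a{i}", category="translocation"))
            srs.append(sr("chrII", 24910, 25000, "+", "chrI", 45000, 45090, "+",
                          read_id=f"b{i}", category="translocation"))
        cands = call_large_breakpoint_pairs(srs)
        assert len(cands) == 1
        c = cands[0]
        assert c.kind == "translocation_breakpoint_pair"
        assert (c.lg, c.start, c.lg2, c.pos2) == ("chrI", 45000, "chrII", 25000)

    def test_unpaired_cluster_flagged(self):
        srs = [sr("chrI", 9910, 10000, "+", "chrI", 30000, 30090, "-",
                  read_id=f"a{i}", category="inversion") for i in range(5)]
        cands = call_large_breakpoint_pairs(srs)
        assert len(cands) == 1 and cands[0].notes == "unpaired"

    def test_no_srs_no_candidates(self):
        assert call_large_breakpoint_pairs([]) == []


class TestSupportFilter:
    def _cand(self, kind, n):
        return VariantCandidate(kind=kind, lg="chrI", start=0, end=500,
                                support={f"r{i}" for i in range(n)})

    def test_nine_reads_removed_ten_kept(self):
        nine = self._cand("insertion", 9)
        ten = self._cand("insertion", 10)
        filter_complicated([nine, ten])
        assert nine.status == "removed_support"
        assert ten.status == "kept"

    def test_simple_deletion_untouched(self):
        c = self._cand("deletion", 3)
        filter_complicated([c])
        assert c.status == "kept"

    def test_monotone_in_min_reads(self):
        for kind in ("insertion", "local_inversion_or_inverted_insertion"):
            kept_counts = []
            for min_reads in (5, 10, 15):
                cands = [self._cand(kind, n) for n in range(1, 20)]
                filter_complicated(cands, min_reads)
                kept_counts.append(sum(c.status == "kept" for c in cands))
            assert kept_counts == sorted(kept_counts, reverse=True)


class TestDepth:
    def _track(self, values, lg="chrI"):
        return DepthTrack({lg: np.asarray(values, dtype=np.int64)})

    def test_nd_is_depth_over_coverage(self):
        nd = normalized_depth(self._track([20] * 10), coverage=20.0)
        assert np.allclose(nd.nd["chrI"], 1.0)

    def test_depth_one_is_outside_mapped_region(self):
        nd = normalized_depth(self._track([1, 2, 0, 5]), coverage=2.0)
        assert nd.mask["chrI"].tolist() == [False, True, False, True]
        assert np.isnan(nd.nd["chrI"][0])

    def test_identical_samples_have_dr_one(self):
        nd = normalized_depth(self._track([10, 20, 30, 2]), coverage=10.0)
        dr = depth_ratio(nd, nd)
        assert np.allclose(dr.dr["chrI"], 1.0)

    def test_half_depth_region_has_dr_half(self):
        case = normalized_depth(self._track([10] * 50 + [5] * 50), 10.0)
        ctrl = normalized_depth(self._track([10] * 100), 10.0)
        dr = depth_ratio(case, ctrl)
        assert dr.region("chrI", 50, 100) == pytest.approx(0.5)
        assert dr.region("chrI", 0, 50) == pytest.approx(1.0)

    def test_region_without_joint_mapping_is_nan(self):
        case = normalized_depth(self._track([0, 0, 10]), 10.0)
        ctrl = normalized_depth(self._track([10, 10, 10]), 10.0)
        assert np.isnan(depth_ratio(case, ctrl).region("chrI", 0, 2))


class TestDepthFilters:
    def _dr(self, value, n=1000):
        return DepthRatio({"chrI": np.full(n, float(value))})

    def test_deletion_dr_above_threshold_removed(self):
        c = VariantCandidate("deletion", "chrI", 100, 200)
        apply_depth_filters([c], self._dr(0.8))
        assert c.status == "removed_depth"

    def test_deletion_with_real_loss_kept(self):
        c = VariantCandidate("deletion", "chrI", 100, 200)
        apply_depth_filters([c], self._dr(0.1))
        assert c.status == "kept" and c.dr == pytest.approx(0.1)

    def test_insertion_dr_two_becomes_duplication(self):
        c = VariantCandidate("insertion", "chrI", 100, 200)
        apply_depth_filters([c], self._dr(2.0))
        assert c.kind == "duplication" and c.status == "kept"

    def test_insertion_dr_three_becomes_multiplication(self):
        c = VariantCandidate("insertion", "chrI", 100, 200)
        apply_depth_filters([c], self._dr(3.0))
        assert c.kind == "multiplication"

    def test_breakpoint_pairs_skipped(self):
        c = VariantCandidate("inversion_breakpoint_pair", "chrI", 100, 90_000)
        apply_depth_filters([c], self._dr(0.1))
        assert c.status == "kept" and c.dr is None

    def test_nan_dr_keeps_and_flags(self):
        c = VariantCandidate("deletion", "chrI", 100, 200)
        apply_depth_filters([c], self._dr(np.nan))
        assert c.status == "kept" and "DR unavailable" in c.notes

    def test_lowering_del_threshold_never_keeps_more(self):
        kept = []
        for thr in (0.9, 0.75, 0.5):
            cands = [VariantCandidate("deletion", "chrI", 0, 10)
                     for _ in range(5)]
            for c, v in zip(cands, (0.1, 0.4, 0.6, 0.8, 1.0)):
                apply_depth_filters([c], self._dr(v), dr_del=thr)
            kept.append(sum(c.status == "kept" for c in cands))
        assert kept == sorted(kept, reverse=True)


class TestReportRoundTrip:
    def test_tsv_roundtrip(self, tmp_path):
        from balancerscan.svcall import read_variant_tsv, write_variant_tsv

        cands = [
            VariantCandidate("deletion", "chrI", 100, 200,
                             support={"a", "b", "c"}, dr=0.25),
            VariantCandidate("translocation_breakpoint_pair", "chrI", 45000,
                             45000, lg2="chrII", pos2=25000,
                             support={"x"}, status="kept"),
            VariantCandidate("insertion", "chrI", 10, 40, support=set(),
                             status="removed_support", notes="border_gap"),
        ]
        p = tmp_path / "v.tsv"
        write_variant_tsv(cands, str(p))
        back = read_variant_tsv(str(p))
        for orig, rt in zip(cands, back):
            assert (orig.kind, orig.lg, orig.start, orig.end, orig.lg2,
                    orig.pos2, orig.status, orig.support) == \
                (rt.kind, rt.lg, rt.start, rt.end, rt.lg2, rt.pos2,
                 rt.status, rt.support)

    def test_empty_candidate_list_valid_outputs(self, tmp_path, toy_ref):
        from balancerscan.svcall import (read_variant_tsv, write_variant_tsv,
                                         write_variant_vcf)

        write_variant_tsv([], str(tmp_path / "v.tsv"))
        assert read_variant_tsv(str(tmp_path / "v.tsv")) == []
        write_variant_vcf([], toy_ref, str(tmp_path / "v.vcf"))
        text = (tmp_path / "v.vcf").read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert "#CHROM" in text
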