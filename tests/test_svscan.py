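"""SV detection: evidence extraction, breakpoint resolution, calling."""

from __future__ import annotations

import math

import numpy as np
import pytest

from poolscan import svscan, synthio

from conftest import simulate_sam


def rec(
    pos=1000,
    contig="rp1",
    is_reverse=False,
    mapq=60,
    ref_len=125,
    lclip=0,
    rclip=0,
    lseq="",
    rseq="",
    mate_contig="rp1",
    mate_pos=1300,
    mate_rev=True,
    tlen=350,
    qname="q",
    cigar=None,
    seq="",
):
    if cigar is None:
        cigar = tuple(
            t for t in (((4, lclip) if lclip else None), (0, ref_len), ((4, rclip) if rclip else None))
            if t
        )
    return svscan.AlignmentRecord(
        qname, contig, pos, is_reverse, mapq, ref_len, lclip, rclip,
        lseq, rseq, cigar, mate_contig, mate_pos, mate_rev, tlen, seq,
    )


class TestPreprocess:
    def test_mapq_boundary(self):
        records = [rec(mapq=9), rec(pos=1001, mapq=10)]
        out = svscan.preprocess(records)
        assert len(out) == 1 and out[0].mapq == 10

    def test_identical_records_collapse_to_one(self):
        records = [rec(qname="a"), rec(qname="b")]
        assert len(svscan.preprocess(records)) == 1

    def test_distinct_cigars_at_same_position_kept(self):
        records = [rec(qname="a"), rec(qname="b", rclip=20, ref_len=105)]
        assert len(svscan.preprocess(records)) == 2

    def test_unsorted_input_raises(self):
        with pytest.raises(svscan.UnsortedInputError):
            svscan.preprocess([rec(pos=2000), rec(pos=1000)])

    def test_survivor_count_matches_set_based_dedup(self, rng):
        records = []
        positions = np.sort(rng.integers(1, 500, size=300))
        for i, p in enumerate(positions):
            records.append(rec(pos=int(p), qname=f"q{i}", mate_pos=int(p) + 225))
        out = svscan.preprocess(records)
        expect = {(r.contig, r.pos, r.is_reverse, r.cigar, r.mate_pos) for r in records}
        assert len(out) == len(expect)


class TestDepthProfile:
    def test_uniform_pool_relative_depth_one(self, small_ref, tmp_path):
        records = simulate_sam(small_ref, [], [1.0], str(tmp_path / "u.sam"), coverage=40)
        prof = svscan.depth_profile(records, {c: len(s) for c, s in small_ref.contigs.items()})
        assert prof.median == pytest.approx(40, abs=4)
        interior = prof.smoothed["rp1"][2000:-2000]
        assert abs(interior.mean() - 1.0) < 0.05

    def test_duplication_doubles_relative_depth(self, small_ref, tmp_path):
        dup = synthio.StructuralEdit("tandem_duplication", "rp1", 10_000, 16_000, copies=2)
        records = simulate_sam(small_ref, [[dup]], [0.0, 1.0], str(tmp_path / "d.sam"))
        prof = svscan.depth_profile(records, {c: len(s) for c, s in small_ref.contigs.items()})
        inside = prof.smoothed["rp1"][11_000:15_000].mean()
        assert abs(inside - 2.0) < 0.2

    def test_fixed_deletion_zero_relative_depth(self, small_ref, tmp_path):
        dele = synthio.StructuralEdit("deletion", "rp1", 10_000, 16_000)
        records = simulate_sam(small_ref, [[dele]], [0.0, 1.0], str(tmp_path / "x.sam"))
        prof = svscan.depth_profile(records, {c: len(s) for c, s in small_ref.contigs.items()})
        assert prof.relative["rp1"][11_000:15_000].mean() < 0.02

    def test_no_coverage_is_an_error(self):
        with pytest.raises(ValueError):
            svscan.depth_profile([], {"rp1": 1000})


class TestCNVRegions:
    def test_flat_profile_yields_nothing(self, small_ref, tmp_path):
        records = simulate_sam(small_ref, [], [1.0], str(tmp_path / "u.sam"))
        prof = svscan.depth_profile(records, {c: len(s) for c, s in small_ref.contigs.items()})
        assert svscan.cnv_candidate_regions(prof) == []

    def test_fixed_duplication_detected_as_gain(self, small_ref, tmp_path):
        dup = synthio.StructuralEdit("tandem_duplication", "rp1", 10_000, 16_900, copies=2)
        records = simulate_sam(small_ref, [[dup]], [0.0, 1.0], str(tmp_path / "d.sam"))
        prof = svscan.depth_profile(records, {c: len(s) for c, s in small_ref.contigs.items()})
        gains = [iv for iv in svscan.cnv_candidate_regions(prof) if iv.kind == "gain"]
        assert len(gains) == 1
        assert gains[0].start < 11_000 and gains[0].end > 15_900

    def test_half_frequency_duplication_passes_default_threshold(self, small_ref, tmp_path):
        # expected relative depth 1.5 >= 1.4
        dup = synthio.StructuralEdit("tandem_duplication", "rp1", 10_000, 16_900, copies=2)
        records = simulate_sam(small_ref, [[dup]], [0.5, 0.5], str(tmp_path / "h.sam"))
        prof = svscan.depth_profile(records, {c: len(s) for c, s in small_ref.contigs.items()})
        gains = [iv for iv in svscan.cnv_candidate_regions(prof) if iv.kind == "gain"]
        assert gains and abs(gains[0].mean_relative_depth - 1.5) < 0.15


class TestPairClasses:
    def test_concordant_insert(self):
        pc = svscan.classify_read_pairs([rec(tlen=350)])
        assert len(pc.concordant) == 1

    def test_huge_insert_is_deletion_type(self):
        pc = svscan.classify_read_pairs([rec(tlen=7000, mate_pos=7000)])
        assert len(pc.deletion_type) == 1

    def test_threshold_is_mean_plus_k_sd(self):
        at = rec(tlen=550, mate_pos=1500)
        above = rec(tlen=551, mate_pos=1500)
        assert len(svscan.classify_read_pairs([at]).deletion_type) == 0
        assert len(svscan.classify_read_pairs([above]).deletion_type) == 1

    def test_everted_orientation_is_tandem_type(self):
        r = rec(is_reverse=True, mate_rev=False, mate_pos=1500, tlen=600)
        pc = svscan.classify_read_pairs([r])
        assert len(pc.tandem_type) == 1

    def test_mate_on_other_contig_is_interchromosomal(self):
        r = rec(mate_contig="te_library", mate_pos=10)
        pc = svscan.classify_read_pairs([r])
        assert len(pc.interchromosomal) == 1

    def test_simulated_tandem_everted_count_matches_truth_census(self, small_ref, tmp_path):
        dup = synthio.StructuralEdit("tandem_duplication", "rp1", 10_000, 16_000, copies=2)
        hap = synthio.apply_edits(small_ref, [dup], name="dup")
        pool = synthio.HaplotypePool([hap], [1.0])
        pairs = synthio.simulate_pool_reads(pool, 40.0, seed=13)
        synthio.write_sam(pairs, small_ref, str(tmp_path / "t.sam"))
        records = svscan.preprocess(svscan.read_alignments(str(tmp_path / "t.sam")))
        pc = svscan.classify_read_pairs(records)
        everted_names = {r.qname for r in pc.tandem_type}
        # truth bounds: every junction-spanning pair with unclipped mates
        # must appear everted; every everted pair must cross the junction
        # (reads crossing the junction themselves may or may not evert,
        # depending on which end anchors)
        junction = 16_000  # haplotype coordinate of the copy2 start
        must_evert = set()
        for p in pairs:
            a1, a2 = p.read1, p.read2
            if a1.aln is None or a2.aln is None:
                continue
            if a1.hap_start + 125 <= junction <= a2.hap_start and not (
                a1.aln.left_clip or a1.aln.right_clip or a2.aln.left_clip or a2.aln.right_clip
            ):
                must_evert.add(p.name)
        crossing = {p.name for p in pairs if p.crosses_breakpoint}
        assert must_evert and must_evert <= everted_names
        assert everted_names <= crossing


class TestClipClusters:
    def test_no_clipped_reads_no_clusters(self):
        assert svscan.clip_clusters([rec(), rec(pos=2000)]) == []

    def test_consensus_of_identical_strings(self):
        records = [
            rec(pos=1000 + i, qname=f"q{i}", ref_len=100, rclip=25, rseq="ACGTACGTACGTACGTACGTACGTA",
                cigar=((0, 100 - i), (4, 25)))
            for i in range(3)
        ]
        # align boundaries: make all reads end at the same reference base
        records = [
            rec(pos=1000, qname=f"q{i}", ref_len=100, rclip=25,
                rseq="ACGTACGTACGTACGTACGTACGTA")
            for i in range(3)
        ]
        out = svscan.clip_clusters(records)
        assert len(out) == 1
        assert out[0].consensus == "ACGTACGTACGTACGTACGTACGTA"
        assert out[0].boundary == 1099  # last aligned base, 1-based

    def test_majority_vote_consensus(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "AAACAAAAAA"]
        records = [
            rec(pos=1000, qname=f"q{i}", ref_len=100, rclip=10, rseq=s)
            for i, s in enumerate(seqs)
        ]
        out = svscan.clip_clusters(records)
        assert out[0].consensus == "AAAAAAAAAA"

    def test_min_support_threshold(self):
        records = [
            rec(pos=1000, qname=f"q{i}", ref_len=100, rclip=10, rseq="ACGTACGTAC")
            for i in range(2)
        ]
        assert svscan.clip_clusters(records, min_support=3) == []

    def test_deletion_simulation_gives_one_cluster_per_breakpoint(self, small_ref, tmp_path):
        left, right = 10_000, 16_000
        dele = synthio.StructuralEdit("deletion", "rp1", left, right)
        records = simulate_sam(small_ref, [[dele]], [0.0, 1.0], str(tmp_path / "d.sam"))
        clusters = svscan.clip_clusters(records)
        sides = {(c.side, c.boundary) for c in clusters}
        assert ("right", left) in sides
        assert ("left", right + 1) in sides


class TestChimericMatch:
    def test_deletion_breakpoints_recovered_exactly(self, small_ref, tmp_path):
        left, right = 10_000, 16_000
        dele = synthio.StructuralEdit("deletion", "rp1", left, right)
        records = simulate_sam(small_ref, [[dele]], [0.0, 1.0], str(tmp_path / "d.sam"))
        matches = [
            m for c in svscan.clip_clusters(records)
            if (m := svscan.match_chimeric(c, small_ref.contigs)) is not None
        ]
        assert matches and all(m.kind == "deletion" for m in matches)
        assert all((m.left, m.right) == (left, right) for m in matches)

    def test_tandem_head_to_tail_match(self, small_ref, tmp_path):
        left, right = 10_000, 16_000
        dup = synthio.StructuralEdit("tandem_duplication", "rp1", left, right, copies=2)
        records = simulate_sam(small_ref, [[dup]], [0.0, 1.0], str(tmp_path / "t.sam"))
        matches = [
            m for c in svscan.clip_clusters(records)
            if (m := svscan.match_chimeric(c, small_ref.contigs)) is not None
        ]
        assert matches and all(m.kind == "tandem_duplication" for m in matches)
        assert all((m.left, m.right) == (left, right) for m in matches)

    def test_random_consensus_unmatched(self, small_ref):
        cluster = svscan.ClipCluster("rp1", 5_000, "right", 5, "TTTTGTATTGGCCTTAGCAATTTCAGT")
        # a random 27-mer is effectively never present at >= 90% identity
        m = svscan.match_chimeric(cluster, small_ref.contigs)
        assert m is None or m.identity < 0.95


class TestCalling:
    def test_table1_length_convention(self):
        # all nine printed breakpoint pairs reproduce their printed lengths
        table = [
            (37_410, 43_954, 6.5),
            (17_910, 24_836, 6.9),
            (46_407, 52_668, 6.2),
            (10_311, 71_182, 60.8),
            (18_643, 25_686, 7.0),
            (19_133, 25_617, 6.4),
            (19_043, 35_875, 16.8),
            (46_771, 50_640, 3.8),
            (46_864, 49_106, 2.2),
        ]
        for left, right, printed in table:
            assert svscan.length_kb(left, right) == pytest.approx(printed)

    def test_label_format(self):
        r = svscan.SVRecord("deletion", "rp1", 37_410, 43_954)
        assert r.label == "rp1:37410–43954"

    def test_depth_only_candidate_not_called(self):
        iv = svscan.CNVInterval("rp1", 1000, 3000, "gain", 2.0)
        pairs = svscan.PairClasses([], [], [], [])
        out = svscan.call_svs([iv], pairs, [])
        assert out == []

    def test_two_of_three_evidence_rule(self, small_ref, tmp_path):
        # chimeric + pairs suffices even when the depth line carries no clear
        # loss signal (expected relative depth 0.75 at 25% carrier frequency)
        dele = synthio.StructuralEdit("deletion", "rp1", 10_000, 16_000)
        records = simulate_sam(small_ref, [[dele]], [0.75, 0.25], str(tmp_path / "q.sam"))
        prof = svscan.depth_profile(records, {c: len(s) for c, s in small_ref.contigs.items()})
        cnv = svscan.cnv_candidate_regions(prof)
        pc = svscan.classify_read_pairs(records)
        matches = [
            m for c in svscan.clip_clusters(records)
            if (m := svscan.match_chimeric(c, small_ref.contigs)) is not None
        ]
        out = svscan.call_svs(cnv, pc, matches)
        exact = [r for r in out if r.exact]
        assert len(exact) == 1 and exact[0].kind == "deletion"
        assert (exact[0].left, exact[0].right) == (10_000, 16_000)

    def test_nested_deletion_within_duplication_resolved(self, small_ref, tmp_path):
        dup = synthio.StructuralEdit("tandem_duplication", "rp1", 10_000, 18_000, copies=2)
        nested = synthio.StructuralEdit("deletion", "rp1", 11_000, 15_000)
        records = simulate_sam(small_ref, [[dup, nested]], [0.0, 1.0], str(tmp_path / "n.sam"))
        svs, _ = _scan_records(records, small_ref)
        kinds = {(r.kind, r.left, r.right) for r in svs}
        assert ("tandem_duplication", 10_000, 18_000) in kinds
        assert ("deletion", 11_000, 15_000) in kinds
        dele = next(r for r in svs if r.kind == "deletion")
        assert dele.nested_in == "rp1:10000–18000"


def _scan_records(records, ref):
    prof = svscan.depth_profile(records, {c: len(s) for c, s in ref.contigs.items()})
    cnv = svscan.cnv_candidate_regions(prof)
    pc = svscan.classify_read_pairs(records)
    matches = [
        m for c in svscan.clip_clusters(records)
        if (m := svscan.match_chimeric(c, ref.contigs)) is not None
    ]
    svs = svscan.call_svs(cnv, pc, matches)
    for sv in svs:
        sv.frequency = svscan.sv_frequency(sv, records)
    return svs, prof


class TestFrequencyAndCopies:
    def test_all_junction_reads_frequency_one(self, small_ref, tmp_path):
        dele = synthio.StructuralEdit("deletion", "rp1", 10_000, 16_000)
        records = simulate_sam(small_ref, [[dele]], [0.0, 1.0], str(tmp_path / "f.sam"))
        svs, _ = _scan_records(records, small_ref)
        assert svs[0].frequency == pytest.approx(1.0, abs=0.05)

    def test_absent_variant_frequency_zero(self, small_ref):
        sv = svscan.SVRecord("deletion", "rp1", 10_000, 16_000)
        records = [rec(pos=9_950, qname=f"q{i}", mate_pos=10_200 + i) for i in range(20)]
        assert svscan.sv_frequency(sv, records) == 0.0

    def test_no_informative_reads_missing(self, small_ref):
        sv = svscan.SVRecord("deletion", "rp1", 10_000, 16_000)
        assert math.isnan(svscan.sv_frequency(sv, []))

    def test_mixture_frequency_recovered(self, small_ref, tmp_path):
        # the 80:20 insertion/deletion polymorphism: deletion at 20%
        dele = synthio.StructuralEdit("deletion", "rp1", 10_000, 16_000)
        records = simulate_sam(
            small_ref, [[dele]], [0.8, 0.2], str(tmp_path / "m.sam"), coverage=60, seed=21
        )
        svs, _ = _scan_records(records, small_ref)
        assert abs(svs[0].frequency - 0.2) < 0.1

    def test_copy_number_rounding(self):
        prof = svscan.DepthProfile(
            {"rp1": np.ones(30_000, dtype=np.int32)},
            1.0,
            {"rp1": np.full(30_000, 2.0)},
            {"rp1": np.full(30_000, 2.0)},
            250.0,
        )
        sv = svscan.SVRecord("tandem_duplication", "rp1", 10_000, 16_000, frequency=1.0)
        assert svscan.copy_number_estimate(sv, prof) == (2, 2)
        prof.relative["rp1"][:] = 3.5
        assert svscan.copy_number_estimate(sv, prof) == (3, 4)

    def test_simulated_three_copies_estimated(self, small_ref, tmp_path):
        dup = synthio.StructuralEdit("tandem_duplication", "rp1", 10_000, 16_900, copies=3)
        records = simulate_sam(small_ref, [[dup]], [0.0, 1.0], str(tmp_path / "c3.sam"))
        svs, prof = _scan_records(records, small_ref)
        dup_call = next(r for r in svs if r.kind == "tandem_duplication")
        dup_call.frequency = 1.0  # known carrier frequency
        lo, hi = svscan.copy_number_estimate(dup_call, prof)
        assert lo <= 3 <= hi

    def test_polymorphic_relabeling(self):
        r = svscan.SVRecord("deletion", "rp1", 100, 200, frequency=0.2)
        svscan.classify_polymorphic([r])
        assert r.kind == "insertion_polymorphism"
        r2 = svscan.SVRecord("deletion", "rp1", 100, 200, frequency=0.99)
        svscan.classify_polymorphic([r2])
        assert r2.kind == "deletion"


class TestBreakpointExactness:
    def test_exact_at_zero_error_and_near_exact_at_low_error(self, small_ref, tmp_path):
        left, right = 10_000, 16_000
        dele = synthio.StructuralEdit("deletion", "rp1", left, right)
        hits = 0
        for seed in range(6):
            records = simulate_sam(
                small_ref, [[dele]], [0.0, 1.0], str(tmp_path / f"e{seed}.sam"),
                seed=seed, error_rate=0.002,
            )
            svs, _ = _scan_records(records, small_ref)
            dels = [r for r in svs if r.kind == "deletion"]
            if dels and abs(dels[0].left - left) <= 2 and abs(dels[0].right - right) <= 2:
                hits += 1
        assert hits >= 5
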