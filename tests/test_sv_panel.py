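import numpy as np
import pytest

from svjunction import simdata as sim
from svjunction import sv_panel as sp
from svjunction.sequtil import revcomp


def _tsv(tmp_path, rows):
    header = "sv_id\tchrom_a\tpos_a\torient_a\tchrom_b\tpos_b\torient_b\tsomatic_score\tinserted_seq\tsample_id"
    path = tmp_path / "calls.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return str(path)


class TestParseSvCalls:
    def test_tsv_canonical_ordering(self, tmp_path):
        path = _tsv(tmp_path, ["SV1\t2\t500000\t+\t2\t100000\t+\t40\t\tS1"])
        (call,) = sp.parse_sv_calls(path)
        assert (call.pos_a, call.pos_b) == (100000, 500000)
        assert call.span == 400000

    def test_vcf_mate_pair_collapse(self, tmp_path):
        genome = {"1": "A" * 1000, "5": "C" * 1000}
        call = sp.SvCall("T1", "1", 500, "+", "5", 600, "+", somatic_score=55)
        vcf = tmp_path / "t.vcf"
        sp.write_sv_vcf([call], genome, str(vcf))
        calls = sp.parse_sv_calls(str(vcf))
        assert len(calls) == 1
        assert (calls[0].chrom_a, calls[0].chrom_b) == ("1", "5")
        assert calls[0].somatic_score == 55

    def test_unpaired_bnd_is_error(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t500\tX:0\tA\tA[5:600[\t.\tPASS\tSVTYPE=BND;MATEID=X:1\n"
        )
        with pytest.raises(ValueError, match="X:0"):
            sp.parse_sv_calls(str(vcf))

    def test_malformed_coordinates_name_line(self, tmp_path):
        path = _tsv(tmp_path, ["SV1\t2\tnotanumber\t+\t2\t100000\t+\t40\t\tS1"])
        with pytest.raises(ValueError, match="line 2"):
            sp.parse_sv_calls(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = _tsv(
            tmp_path,
            [
                "SV1\t1\t1000\t+\t1\t300000\t+\t40\t\tS1",
                "SV1\t2\t1000\t+\t2\t300000\t+\t40\t\tS1",
            ],
        )
        with pytest.raises(ValueError, match="duplicate"):
            sp.parse_sv_calls(path)

    def test_vcf_roundtrip_all_orientations(self, sim_genome):
        import os
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            vcf = os.path.join(d, "calls.vcf")
            sp.write_sv_vcf(sim_genome.calls, sim_genome.reference, vcf)
            parsed = {c.sv_id: c for c in sp.parse_sv_calls(vcf)}
        for c in sim_genome.calls:
            p = parsed[c.sv_id]
            assert (p.chrom_a, p.pos_a, p.orient_a) == (c.chrom_a, c.pos_a, c.orient_a)
            assert (p.chrom_b, p.pos_b, p.orient_b) == (c.chrom_b, c.pos_b, c.orient_b)
            assert p.inserted_seq == c.inserted_seq


class TestFindCnSteps:
    def test_step_at_cn_change(self):
        segs = [sp.CnSegment("chr1", 0, 1000, 2), sp.CnSegment("chr1", 1000, 2000, 4)]
        assert sp.find_cn_steps(segs) == [("chr1", 1000)]

    def test_no_step_when_equal(self):
        segs = [sp.CnSegment("chr1", 0, 1000, 2), sp.CnSegment("chr1", 1000, 2000, 2)]
        assert sp.find_cn_steps(segs) == []

    def test_three_segments_two_steps(self):
        # hand enumeration: boundaries at 1000 (2->3) and 2000 (3->2)
        segs = [
            sp.CnSegment("chr1", 0, 1000, 2),
            sp.CnSegment("chr1", 1000, 2000, 3),
            sp.CnSegment("chr1", 2000, 3000, 2),
        ]
        assert sp.find_cn_steps(segs) == [("chr1", 1000), ("chr1", 2000)]

    def test_permutation_invariant(self):
        segs = [
            sp.CnSegment("chr1", 2000, 3000, 2),
            sp.CnSegment("chr1", 0, 1000, 2),
            sp.CnSegment("chr1", 1000, 2000, 3),
        ]
        assert sp.find_cn_steps(segs) == [("chr1", 1000), ("chr1", 2000)]

    def test_overlap_is_error(self):
        segs = [sp.CnSegment("chr1", 0, 1500, 2), sp.CnSegment("chr1", 1000, 2000, 4)]
        with pytest.raises(ValueError, match="overlap"):
            sp.find_cn_steps(segs)


def _call(sv_id, ca, pa, cb, pb, score=60, sample="S1", oa="+", ob="+"):
    return sp.SvCall(sv_id, ca, pa, oa, cb, pb, ob, somatic_score=score, sample_id=sample)


class TestClusterRecurrentBreakpoints:
    def test_rule_ii_interchromosomal_close_pair(self):
        calls = [
            _call("A", "1", 10_000, "5", 99_000, sample="S1"),
            _call("B", "1", 10_150, "7", 500_000, sample="S2"),
        ]
        bl = sp.cluster_recurrent_breakpoints(calls)
        assert ("1", 10_000) in bl and ("1", 10_150) in bl

    def test_rule_i_large_span_within_2kb(self):
        calls = [
            _call("A", "1", 100_000, "1", 350_000, sample="S1"),
            _call("B", "1", 101_500, "1", 352_000, sample="S2"),
        ]
        bl = sp.cluster_recurrent_breakpoints(calls)
        assert ("1", 100_000) in bl and ("1", 101_500) in bl

    def test_same_sample_not_recurrent(self):
        calls = [
            _call("A", "1", 10_000, "5", 99_000, sample="S1"),
            _call("B", "1", 10_100, "7", 500_000, sample="S1"),
            _call("C", "9", 1_000_000, "10", 2_000_000, sample="S2"),
        ]
        bl = sp.cluster_recurrent_breakpoints(calls)
        assert ("1", 10_000) not in bl and ("1", 10_100) not in bl

    def test_single_sample_warns_empty(self):
        calls = [_call("A", "1", 10_000, "5", 99_000, sample="S1")]
        with pytest.warns(UserWarning):
            assert sp.cluster_recurrent_breakpoints(calls) == set()

    def test_small_span_pairs_not_clustered_at_2kb(self):
        # 50 kb span SVs do not qualify for rule (i); 1.5 kb apart is > 200 bp
        calls = [
            _call("A", "1", 100_000, "1", 150_000, sample="S1"),
            _call("B", "1", 101_500, "1", 151_500, sample="S2"),
        ]
        assert sp.cluster_recurrent_breakpoints(calls) == set()


class TestFilterHighConfidence:
    steps = [("1", 250_000)]

    def test_low_score_threshold(self):
        call = _call("A", "1", 248_000, "1", 500_000, score=30)
        report = sp.filter_high_confidence([call], self.steps)
        assert report.reasons["A"] == ("low_score",)
        report31 = sp.filter_high_confidence(
            [_call("B", "1", 248_000, "1", 500_000, score=31)], self.steps
        )
        assert report31.decision("B") == "retained"

    def test_intra_large_span_near_step_retained(self):
        call = _call("A", "1", 247_000, "1", 497_000, score=40)  # 3 kb from step
        report = sp.filter_high_confidence([call], self.steps)
        assert report.decision("A") == "retained"

    def test_no_cn_step_within_10kb(self):
        call = _call("A", "1", 265_000, "5", 272_000, score=40)  # 15 kb and wrong chrom
        report = sp.filter_high_confidence([call], self.steps)
        assert "no_cn_step" in report.reasons["A"]

    def test_step_exactly_at_10kb_counts(self):
        call = _call("A", "1", 260_000, "5", 900_000, score=40)
        report = sp.filter_high_confidence([call], self.steps)
        assert "no_cn_step" not in report.reasons["A"]

    def test_short_intra_span(self):
        call = _call("A", "1", 250_000, "1", 349_000, score=40)  # span 99,000
        report = sp.filter_high_confidence([call], self.steps)
        assert "short_intra_span" in report.reasons["A"]

    def test_span_exactly_100kb_rejected(self):
        call = _call("A", "1", 250_000, "1", 350_000, score=40)
        report = sp.filter_high_confidence([call], self.steps)
        assert "short_intra_span" in report.reasons["A"]

    def test_non_primary_chrom(self):
        call = _call("A", "chrM", 250_000, "1", 500_000, score=40)
        report = sp.filter_high_confidence([call], [("chrM", 250_000), ("1", 500_000)])
        assert "non_primary_chrom" in report.reasons["A"]

    def test_mask_and_blacklist(self):
        mask = sp.RegionMask([("1", 246_000, 246_200, "simple_repeat")])
        call = _call("A", "1", 246_100, "1", 500_000, score=40)
        report = sp.filter_high_confidence([call], self.steps, mask=mask)
        assert "repeat_or_gap_adjacent" in report.reasons["A"]
        report2 = sp.filter_high_confidence(
            [call], self.steps, blacklist={("1", 246_100)}
        )
        assert "recurrent_breakpoint" in report2.reasons["A"]

    def test_short_repeat_not_masked(self):
        mask = sp.RegionMask([("1", 246_050, 246_140, "simple_repeat")])  # 90 bp
        call = _call("A", "1", 246_100, "1", 500_000, score=40)
        report = sp.filter_high_confidence([call], self.steps, mask=mask)
        assert "repeat_or_gap_adjacent" not in report.reasons["A"]

    def test_gap_adjacency_window(self):
        mask = sp.RegionMask([("1", 246_150, 246_200, "gap")])
        near = _call("A", "1", 246_100, "1", 500_000, score=40)  # 50 bp away
        far = _call("B", "1", 245_000, "1", 500_000, score=40)  # > 100 bp away
        report = sp.filter_high_confidence([near, far], self.steps, mask=mask)
        assert "repeat_or_gap_adjacent" in report.reasons["A"]
        assert "repeat_or_gap_adjacent" not in report.reasons["B"]

    def test_conservation_and_exclusive_decisions(self, sim_genome):
        calls = sim_genome.calls + sim_genome.decoys
        steps = sp.find_cn_steps(sim_genome.cn_segments)
        blacklist = sp.cluster_recurrent_breakpoints(calls)
        report = sp.filter_high_confidence(calls, steps, sim_genome.mask, blacklist)
        assert set(report.reasons) == {c.sv_id for c in calls}
        assert len(report.retained_ids) + len(report.rejected_ids) == len(calls)
        for c in sim_genome.calls:
            assert report.decision(c.sv_id) == "retained", report.reasons[c.sv_id]
        for d in sim_genome.decoys:
            assert report.decision(d.sv_id) == "rejected"

    def test_monotone_in_thresholds(self, sim_genome):
        calls = sim_genome.calls + sim_genome.decoys
        steps = sp.find_cn_steps(sim_genome.cn_segments)
        strict = sp.filter_high_confidence(
            calls, steps, sim_genome.mask, params=sp.FilterParams(min_score=50, cn_step_window=5_000)
        )
        relaxed = sp.filter_high_confidence(
            calls, steps, sim_genome.mask, params=sp.FilterParams(min_score=20, cn_step_window=20_000)
        )
        assert set(strict.retained_ids) <= set(relaxed.retained_ids)


class TestBuildJunctionReference:
    def test_simple_deletion_concatenation(self):
        rng = np.random.default_rng(1)
        contig = "".join(rng.choice(list("ACGT"), size=1000))
        genome = {"c1": contig}
        call = sp.SvCall("D1", "c1", 300, "+", "c1", 700, "+")
        j = sp.build_junction_reference(call, genome)
        assert len(j.sequence) == 300
        assert j.center == 150
        assert j.sequence == (contig[150:300] + contig[699:849]).upper()

    def test_insertion_shifts_center(self):
        contig = "ACGT" * 250
        genome = {"c1": contig}
        call = sp.SvCall("I1", "c1", 300, "+", "c1", 700, "+", inserted_seq="TTAGC")
        j = sp.build_junction_reference(call, genome)
        assert len(j.sequence) == 305
        assert j.center == 155
        assert j.sequence[150:155] == "TTAGC"

    def test_inversion_flank_is_reverse_complement(self):
        rng = np.random.default_rng(2)
        contig = "".join(rng.choice(list("ACGT"), size=400))
        genome = {"c1": contig}
        call = sp.SvCall("V1", "c1", 160, "+", "c1", 240, "-")
        j = sp.build_junction_reference(call, genome, flank_len=50)
        # hand-built: 50-mer ending at 160, then revcomp of the 50-mer ending at 240
        expected = contig[110:160] + revcomp(contig[190:240])
        assert j.sequence == expected.upper()

    def test_breakpoint_too_close_to_contig_end(self):
        genome = {"c1": "ACGT" * 100}
        call = sp.SvCall("E1", "c1", 50, "+", "c1", 300, "+")
        with pytest.raises(ValueError, match="flank"):
            sp.build_junction_reference(call, genome, flank_len=150)

    def test_roundtrip_all_orientations(self, sim_genome, junctions):
        orientations = {(c.orient_a, c.orient_b) for c in sim_genome.calls}
        assert len(orientations) >= 3  # ++, +-, -+ at minimum
        truth = {t.sv_id: t for t in sim_genome.junction_truth}
        for j in junctions:
            assert j.sequence == truth[j.sv_id].sequence
            assert j.center == truth[j.sv_id].center

    def test_fasta_roundtrip(self, junctions, tmp_path):
        path = str(tmp_path / "junc.fa")
        sp.write_junction_fasta(junctions, path)
        loaded = {j.sv_id: j for j in sp.load_junction_fasta(path)}
        for j in junctions:
            assert loaded[j.sv_id].sequence == j.sequence
            assert loaded[j.sv_id].center == j.center

    def test_pyfaidx_path_input(self, sim_genome, tmp_path):
        from svjunction.sequtil import write_fasta

        fa = str(tmp_path / "ref.fa")
        write_fasta(sim_genome.reference, fa)
        call = sim_genome.calls[0]
        j_dict = sp.build_junction_reference(call, sim_genome.reference)
        j_file = sp.build_junction_reference(call, fa)
        assert j_file.sequence == j_dict.sequence
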