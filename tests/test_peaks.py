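import numpy as np
import pytest

from histodiff.annotation import ChromSizes, GeneModel, GenomicInterval
from histodiff.coverage import CoverageTrack
from histodiff import peaks as pk


SIZES = ChromSizes({"chr1": 100_000})


def gene(gene_id, start, end, strand="+", exons=None, chrom="chr1"):
    body = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        exon_ivs = (body,)
    else:
        exon_ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return GeneModel(gene_id, body, exon_ivs)


def peak(start, end, sample="case", chrom="chr1"):
    return pk.Peak(GenomicInterval(chrom, start, end), sample)


class TestReadPeaks:
    def test_broadpeak_score_from_column7(self, tmp_path):
        p = tmp_path / "p.broadPeak"
        p.write_text("chr1\t100\t900\tpeak1\t60\t.\t7.5\t3.1\t2.0\n")
        (out,) = pk.read_peaks(p, "case", SIZES)
        assert out.score == 7.5 and out.sample == "case"

    def test_bed3_has_no_score(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t900\n")
        (out,) = pk.read_peaks(p, "control", SIZES)
        assert out.score is None

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t900\t100\n")
        with pytest.raises(Exception):
            pk.read_peaks(p, "case", SIZES)

    def test_output_sorted(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t500\t600\nchr1\t100\t200\n")
        out = pk.read_peaks(p, "case", SIZES)
        assert [q.interval.start for q in out] == [100, 500]


class TestAssignPeaks:
    def test_peak_in_exon_counts_for_exon_and_body(self):
        g = gene("g1", 10_000, 20_000, exons=[(10_000, 11_000), (15_000, 16_000)])
        counts = pk.assign_peaks([peak(15_200, 15_400)], [g])
        assert counts["g1"] == {"promoter": 0, "exon": 1, "gene_body": 1}

    def test_single_bp_overlap_counts_for_promoter(self):
        g = gene("g1", 10_000, 20_000)  # distal promoter = [5000, 11000)
        counts = pk.assign_peaks([peak(4_800, 5_001)], [g])
        assert counts["g1"]["promoter"] == 1
        counts = pk.assign_peaks([peak(4_800, 5_000)], [g])
        assert counts["g1"]["promoter"] == 0

    def test_matches_exhaustive_enumeration(self):
        genes = [
            gene("a", 10_000, 14_000, "+", exons=[(10_000, 10_500), (13_000, 14_000)]),
            gene("b", 30_000, 36_000, "-", exons=[(30_000, 31_000), (35_000, 36_000)]),
            gene("c", 50_000, 52_000, "+"),
        ]
        ps = [peak(9_000, 10_200), peak(13_500, 13_600), peak(31_500, 40_800), peak(70_000, 71_000)]
        counts = pk.assign_peaks(ps, genes)
        scheme = pk.RegionScheme()
        for g in genes:
            regions = {
                "promoter": [scheme.promoter_window(g)],
                "exon": list(g.exons),
                "gene_body": [g.body],
            }
            for cat, ivs in regions.items():
                expected = sum(
                    1 for q in ps if any(q.interval.overlaps(iv) for iv in ivs)
                )
                assert counts[g.gene_id][cat] == expected, (g.gene_id, cat)

    def test_minus_strand_promoter_extends_rightward(self):
        g = gene("g1", 10_000, 20_000, "-")  # tss 19999; promoter [19750, 25000)
        assert pk.assign_peaks([peak(24_000, 24_500)], [g])["g1"]["promoter"] == 1
        assert pk.assign_peaks([peak(14_000, 14_500)], [g])["g1"]["promoter"] == 0


class TestClassifyGainLoss:
    def _counts(self, prom, ex, body):
        return {"promoter": prom, "exon": ex, "gene_body": body}

    def test_gain_and_loss_definitions(self):
        ctrl = {"g": self._counts(0, 0, 0)}
        case = {"g": self._counts(1, 0, 0)}
        (call,) = pk.classify_gain_loss(ctrl, case)
        assert call.status == "gained"
        (call,) = pk.classify_gain_loss(case, ctrl)
        assert call.status == "lost"

    def test_category_shift_is_unchanged_present(self):
        ctrl = {"g": self._counts(1, 0, 0)}
        case = {"g": self._counts(0, 1, 0)}
        (call,) = pk.classify_gain_loss(ctrl, case)
        assert call.status == "unchanged_present"

    def test_absent_everywhere(self):
        z = {"g": self._counts(0, 0, 0)}
        (call,) = pk.classify_gain_loss(z, z)
        assert call.status == "unchanged_absent"

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pk.classify_gain_loss({"a": self._counts(0, 0, 0)}, {"b": self._counts(0, 0, 0)})

    def test_pure_function_of_tables(self):
        rng = np.random.default_rng(0)
        ctrl = {f"g{i}": self._counts(*rng.integers(0, 2, 3)) for i in range(30)}
        case = {f"g{i}": self._counts(*rng.integers(0, 2, 3)) for i in range(30)}
        by_id = {c.gene_id: c.status for c in pk.classify_gain_loss(ctrl, case)}
        # permuting the gene order permutes the output identically
        perm_ctrl = dict(reversed(list(ctrl.items())))
        perm_case = dict(reversed(list(case.items())))
        by_id2 = {c.gene_id: c.status for c in pk.classify_gain_loss(perm_ctrl, perm_case)}
        assert by_id == by_id2


class TestOverlapSummary:
    def test_identical_lists_fully_shared(self):
        ps = [peak(100, 200), peak(500, 800)]
        s = pk.overlap_summary(ps, ps)
        assert s.n_shared_control == s.n_shared_case == 2
        assert s.n_control_only == s.n_case_only == 0

    def test_disjoint_lists(self):
        s = pk.overlap_summary([peak(100, 200)], [peak(300, 400)])
        assert s.n_shared_control == s.n_shared_case == 0
        assert s.n_control_only == 1 and s.n_case_only == 1

    def test_matches_brute_force(self):
        ctrl = [peak(0, 100), peak(200, 300), peak(400, 500), peak(600, 700), peak(900, 950)]
        case = [peak(90, 210), peak(450, 460), peak(800, 850), peak(970, 980)]
        s = pk.overlap_summary(ctrl, case)
        shared_ctrl = sum(
            1 for p in ctrl if any(p.interval.overlaps(q.interval) for q in case)
        )
        shared_case = sum(
            1 for q in case if any(q.interval.overlaps(p.interval) for p in ctrl)
        )
        assert s.n_shared_control == shared_ctrl == 3
        assert s.n_shared_case == shared_case == 2
        assert s.n_control == s.n_shared_control + s.n_control_only
        assert s.n_case == s.n_shared_case + s.n_case_only

    def test_width_stats_per_class(self):
        s = pk.overlap_summary([peak(0, 100)], [peak(50, 350)])
        assert s.width_shared.n == 2 and s.width_shared.mean == pytest.approx(200.0)
        assert s.width_control_only.n == 0


class TestStandinCaller:
    def _track(self, values):
        v = np.asarray(values, dtype=float)
        return CoverageTrack({"chr1": v}, 1, 1.0, normalized=True)

    def test_constant_track_below_threshold_gives_nothing(self):
        assert pk.standin_call_peaks(self._track(np.ones(1000)), min_value=2) == []

    def test_single_block_recovered_exactly(self):
        v = np.zeros(1000)
        v[300:600] = 5.0
        (p,) = pk.standin_call_peaks(self._track(v), min_value=2, min_width=100)
        assert (p.interval.start, p.interval.end) == (300, 600)

    def test_merge_across_small_gap(self):
        v = np.zeros(1000)
        v[100:250] = 5.0
        v[290:440] = 5.0  # 40 bp gap
        out = pk.standin_call_peaks(self._track(v), min_value=2, min_width=100, merge_gap=50)
        assert len(out) == 1 and (out[0].interval.start, out[0].interval.end) == (100, 440)
        out2 = pk.standin_call_peaks(self._track(v), min_value=2, min_width=100, merge_gap=30)
        assert len(out2) == 2

    def test_requires_normalized_track(self):
        t = CoverageTrack({"chr1": np.ones(10)}, 1, 1.0, normalized=False)
        with pytest.raises(ValueError):
            pk.standin_call_peaks(t)
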