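import math

import numpy as np
import pytest

from histodiff.annotation import GeneModel, GenomicInterval, MappedRead
from histodiff.coverage import CoverageTrack
from histodiff.profiles import WindowStatResult
from histodiff import amplification as amp


def poisson_tail_oracle(lam, k):
    """Direct log-space pmf summation: 1 - sum_{i<k} e^-lam lam^i / i!"""
    k = math.ceil(k)
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    total = 0.0
    log_pmf = -lam  # log P(X=0)
    for i in range(k):
        total += math.exp(log_pmf)
        log_pmf += math.log(lam) - math.log(i + 1)
    return max(0.0, 1.0 - total)


def mread(start, end, strand="+", seq=None, chrom="chr1"):
    return MappedRead(GenomicInterval(chrom, start, end, strand), sequence=seq)


class TestDedup:
    def test_identical_reads_collapse(self):
        reads = [mread(0, 36, seq="AAA"), mread(0, 36, seq="AAA")]
        kept, removed = amp.dedup_reads(reads)
        assert len(kept) == 1 and removed == 1

    def test_same_coords_different_sequences_kept(self):
        reads = [mread(0, 36, seq="AAA"), mread(0, 36, seq="CCC")]
        kept, removed = amp.dedup_reads(reads)
        assert len(kept) == 2 and removed == 0

    def test_coordinate_fallback_without_sequence(self):
        reads = [mread(0, 36), mread(0, 36)]
        kept, removed = amp.dedup_reads(reads)
        assert len(kept) == 1 and removed == 1

    def test_empty_stream(self):
        assert amp.dedup_reads([]) == ([], 0)


class TestPoissonUpperTail:
    def test_k_zero_covers_whole_support(self):
        assert amp.poisson_upper_tail(3.7, 0) == 1.0
        assert amp.poisson_upper_tail(0.0, 0) == 1.0

    def test_zero_lambda_point_mass(self):
        assert amp.poisson_upper_tail(0.0, 3) == 0.0

    def test_hand_computed_example(self):
        # P(X >= 5 | lam=2) = 1 - sum_{i=0..4} e^-2 2^i/i!
        expect = 1 - math.exp(-2) * (1 + 2 + 2 + 4 / 3 + 2 / 3)
        assert amp.poisson_upper_tail(2, 5) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(5.265e-2, abs=1e-4)

    def test_matches_summation_oracle(self):
        for lam in (0.1, 1.0, 4.2, 17.0, 50.0):
            for k in (0, 1, 2, 5, 20, 77, 200):
                assert amp.poisson_upper_tail(lam, k) == pytest.approx(
                    poisson_tail_oracle(lam, k), abs=1e-10
                )

    def test_monotone_nonincreasing_in_k(self):
        vals = [amp.poisson_upper_tail(9.3, k) for k in range(60)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_non_integer_k_rounds_up(self):
        assert amp.poisson_upper_tail(2, 4.2) == amp.poisson_upper_tail(2, 5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            amp.poisson_upper_tail(-1, 2)
        with pytest.raises(ValueError):
            amp.poisson_upper_tail(1, -2)


def paired_tracks(length, case_fn, ctrl_fn, total_reads=10_000, read_len=36):
    """Build a consistent normalized track pair from per-base raw lambdas."""
    out = []
    for fn in (case_fn, ctrl_fn):
        v = np.fromfunction(np.vectorize(fn), (length,))
        mean = v.mean()
        out.append(
            CoverageTrack(
                {"chr1": v / mean},
                total_reads=max(1, int(v.sum() / read_len)),
                genome_mean=float(mean),
                normalized=True,
            )
        )
    return out


class TestScanAmplified:
    def test_flat_equal_tracks_give_nothing(self):
        case, ctrl = paired_tracks(50_000, lambda i: 1.0, lambda i: 1.0)
        assert amp.scan_amplified(case, ctrl) == []

    def test_constructed_region_recovered(self):
        # 2-kb block at 10x the case genome mean; control flat at its mean
        def case_fn(i):
            return 10.0 if 20_000 <= i < 22_000 else 0.7

        case, ctrl = paired_tracks(100_000, case_fn, lambda i: 0.7)
        (r,) = amp.scan_amplified(case, ctrl)
        assert r.interval.start <= 20_000 and r.interval.end >= 22_000
        assert all(r.criteria_passed)
        assert 0.0 <= r.p_value < 1e-6

    def test_narrow_region_excluded_by_width(self):
        def case_fn(i):
            return 10.0 if 20_000 <= i < 20_800 else 0.7

        case, ctrl = paired_tracks(100_000, case_fn, lambda i: 0.7)
        assert amp.scan_amplified(case, ctrl) == []

    def test_emitted_folds_verify_against_region_sums(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(1.0, 60_000).astype(float)
        case_raw = base.copy()
        case_raw[30_000:33_000] *= 8
        case = CoverageTrack({"chr1": case_raw / case_raw.mean()}, 1500,
                             float(case_raw.mean()), normalized=True)
        ctrl = CoverageTrack({"chr1": base / base.mean()}, 1500,
                             float(base.mean()), normalized=True)
        for r in amp.scan_amplified(case, ctrl):
            s, e = r.interval.start, r.interval.end
            w = e - s
            case_sum = case.values("chr1")[s:e].sum()
            ctrl_sum = ctrl.values("chr1")[s:e].sum()
            assert r.fold_vs_case_mean == pytest.approx(case_sum / w)
            assert r.fold_vs_control == pytest.approx(case_sum / ctrl_sum)
            assert r.fold_vs_case_mean >= 5 and r.fold_vs_control >= 5

    def test_more_amplification_never_fewer_regions(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(1.0, 60_000).astype(float)
        n_regions = []
        for fold in (1, 3, 6, 12, 24):
            case_raw = base.copy()
            case_raw[30_000:33_000] *= fold
            case = CoverageTrack({"chr1": case_raw / case_raw.mean()}, 1500,
                                 float(case_raw.mean()), normalized=True)
            ctrl = CoverageTrack({"chr1": base / base.mean()}, 1500,
                                 float(base.mean()), normalized=True)
            n_regions.append(len(amp.scan_amplified(case, ctrl)))
        assert n_regions == sorted(n_regions)

    def test_mismatched_chromosomes_rejected(self):
        a = CoverageTrack({"chr1": np.ones(100)}, 1, 1.0, normalized=True)
        b = CoverageTrack({"chr2": np.ones(100)}, 1, 1.0, normalized=True)
        with pytest.raises(ValueError):
            amp.scan_amplified(a, b)

    def test_unnormalized_rejected(self):
        a = CoverageTrack({"chr1": np.ones(100)}, 1, 1.0, normalized=False)
        with pytest.raises(ValueError):
            amp.scan_amplified(a, a)


def region(start, end, p):
    return amp.AmplifiedRegion(
        interval=GenomicInterval("chr1", start, end),
        count_case=100.0, count_control=10.0,
        fold_vs_case_mean=10.0, fold_vs_control=10.0, fold_vs_control_mean=10.0,
        p_value=p, criteria_passed=(True,) * 5,
    )


def simple_gene(gene_id, start, end, strand="+"):
    body = GenomicInterval("chr1", start, end, strand)
    return GeneModel(gene_id, body, (body,))


class TestAnnotateAndReport:
    def test_no_regions_empty_table(self):
        assert amp.annotate_amplified([], [simple_gene("g", 0, 100)]) == {}

    def test_region_spanning_two_genes_lists_both(self):
        regions = [region(900, 1200, 1e-8)]
        genes = [simple_gene("a", 500, 1000), simple_gene("b", 1100, 1600),
                 simple_gene("c", 5000, 6000)]
        table = amp.annotate_amplified(regions, genes)
        assert table == {"a": 1e-8, "b": 1e-8}

    def test_best_p_value_kept(self):
        regions = [region(0, 200, 1e-3), region(150, 400, 1e-9)]
        table = amp.annotate_amplified(regions, [simple_gene("g", 100, 300)])
        assert table["g"] == 1e-9

    def test_evidence_report_flags(self):
        v = np.ones(20_000)
        v_case = v.copy()
        v_case[4_500:6_000] = 0.5  # reduced promoter signal in case
        case = CoverageTrack({"chr1": v_case}, 100, 1.0, normalized=True)
        ctrl = CoverageTrack({"chr1": v}, 100, 1.0, normalized=True)
        genes = [simple_gene("marker", 5_000, 9_000)]
        ttest = WindowStatResult(1.0, 0.5, 2.0, 0.04, 10, 10)
        rep = amp.subgroup_evidence_report(
            case, ctrl, genes, ["marker", "ghost"], {"marker": 1e-5}, ttest
        )
        m = rep["markers"]["marker"]
        assert m["ratio_case_over_control"] < 1
        assert set(m["flags"]) == {"reduced in case", "amplified"}
        assert rep["markers"]["ghost"] == {"status": "not evaluable"}
        assert rep["cpg_window_ttest"]["p_value"] == 0.04
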