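import numpy as np
import pytest
from scipy import stats as sps

from histodiff.annotation import CpGIsland, GeneModel, GenomicInterval
from histodiff.coverage import CoverageTrack
from histodiff import profiles as prof


def track_from(values, chrom="chr1"):
    v = np.asarray(values, dtype=float)
    return CoverageTrack({chrom: v}, total_reads=1, genome_mean=1.0, normalized=True)


def brute_force_profile(track, anchors, w):
    """Oracle: explicit per-anchor, per-offset lookup with zero padding."""
    total = np.zeros(2 * w)
    for a in anchors.anchors:
        v = track.data[a.chrom]
        for i, d in enumerate(range(-w, w)):
            pos = a.position + (d if a.strand == "+" else -d)
            if 0 <= pos < len(v):
                total[i] += v[pos]
    return total / len(anchors.anchors)


def make_gene(gene_id, start, end, strand, chrom="chr1"):
    body = GenomicInterval(chrom, start, end, strand)
    return GeneModel(gene_id, body, (body,))


class TestMetaProfile:
    def test_flat_track_gives_flat_profile(self):
        t = track_from(np.ones(1000))
        anchors = prof.AnchorSet("x", (prof.Anchor("chr1", 300), prof.Anchor("chr1", 700, "-")))
        mp = prof.meta_profile(t, anchors, 100)
        assert np.allclose(mp.values, 1.0) and mp.n_anchors == 2

    def test_spike_lands_at_offset_zero(self):
        v = np.zeros(1000)
        v[400] = 7.0
        mp = prof.meta_profile(
            track_from(v), prof.AnchorSet("x", (prof.Anchor("chr1", 400),)), 50
        )
        assert mp.values[50] == 7.0 and mp.values.sum() == 7.0

    def test_minus_anchor_flips_offsets(self):
        """A spike 100 bp 5' of a minus-strand anchor appears at offset -100."""
        v = np.zeros(1000)
        v[600] = 3.0  # 5' of a minus-strand anchor at 500 means rightward
        mp = prof.meta_profile(
            track_from(v), prof.AnchorSet("x", (prof.Anchor("chr1", 500, "-"),)), 200
        )
        assert mp.values[200 - 100] == 3.0

    def test_mirror_anchors_equal_single(self):
        # a + anchor and a - anchor flanked by mirror-image signal
        v = np.zeros(40)
        v[10:13] = [1.0, 2.0, 3.0]  # + anchor at 11
        v[27:30] = [3.0, 2.0, 1.0]  # - anchor at 28 sees the mirror image
        t = track_from(v)
        single = prof.meta_profile(t, prof.AnchorSet("p", (prof.Anchor("chr1", 11),)), 5)
        both = prof.meta_profile(
            t,
            prof.AnchorSet(
                "b", (prof.Anchor("chr1", 11), prof.Anchor("chr1", 28, "-"))
            ),
            5,
        )
        assert np.allclose(both.values, single.values)

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(3)
        v = rng.random(2000)
        t = track_from(v)
        anchors = prof.AnchorSet(
            "r",
            tuple(
                prof.Anchor("chr1", int(rng.integers(0, 2000)), "+" if rng.integers(2) else "-")
                for _ in range(20)
            ),
        )
        mp = prof.meta_profile(t, anchors, 150)
        assert np.allclose(mp.values, brute_force_profile(t, anchors, 150))

    def test_linearity(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(500), rng.random(500)
        anchors = prof.AnchorSet("x", (prof.Anchor("chr1", 100), prof.Anchor("chr1", 400, "-")))
        pa = prof.meta_profile(track_from(a), anchors, 50).values
        pb = prof.meta_profile(track_from(b), anchors, 50).values
        pab = prof.meta_profile(track_from(a + b), anchors, 50).values
        assert np.allclose(pab, pa + pb)

    def test_edge_windows_padded_with_zeros(self):
        t = track_from(np.ones(100))
        mp = prof.meta_profile(t, prof.AnchorSet("x", (prof.Anchor("chr1", 10),)), 50)
        assert mp.n_truncated == 1
        assert np.allclose(mp.values[:40], 0.0) and np.allclose(mp.values[40:], 1.0)

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            prof.meta_profile(track_from(np.ones(10)), prof.AnchorSet("x", ()), 5)


class TestCpGWindowTTest:
    def _islands(self, centers, chrom="chr1"):
        return [CpGIsland(GenomicInterval(chrom, c - 100, c + 100)) for c in centers]

    def test_identical_tracks_give_null(self):
        rng = np.random.default_rng(5)
        v = rng.random(5000)
        t = track_from(v)
        res = prof.cpg_window_ttest(t, t, self._islands([1000, 2000, 3000, 4000]))
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_doubling_doubles_mean(self):
        rng = np.random.default_rng(6)
        v = rng.random(5000)
        res = prof.cpg_window_ttest(
            track_from(v), track_from(2 * v), self._islands([1000, 2500, 4000])
        )
        assert res.mean_b == pytest.approx(2 * res.mean_a)

    def test_matches_welch_reference(self):
        rng = np.random.default_rng(7)
        va, vb = rng.random(6000), rng.random(6000)
        islands = self._islands([500, 1500, 2500, 3500, 4500, 5500])
        res = prof.cpg_window_ttest(track_from(va), track_from(vb), islands, window=500)
        ma = [va[c - 250 : c + 250].mean() for c in (500, 1500, 2500, 3500, 4500, 5500)]
        mb = [vb[c - 250 : c + 250].mean() for c in (500, 1500, 2500, 3500, 4500, 5500)]
        ref = sps.ttest_ind(ma, mb, equal_var=False)
        assert res.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_few_islands_rejected(self):
        t = track_from(np.ones(1000))
        with pytest.raises(ValueError):
            prof.cpg_window_ttest(t, t, self._islands([500]))


class TestTssVicinityCounts:
    def test_constant_track_gives_window_length(self):
        t = track_from(np.ones(10_000))
        genes = [make_gene("gp", 3000, 5000, "+"), make_gene("gm", 6000, 8000, "-")]
        counts = prof.tss_vicinity_counts(t, genes)
        assert counts == {"gp": 1500.0, "gm": 1500.0}

    def test_minus_strand_window_extends_leftward(self):
        v = np.zeros(10_000)
        g = make_gene("gm", 6000, 8000, "-")  # tss = 7999
        # 1000 bp downstream (5'->3') of a minus-strand TSS is leftward
        v[7999 - 800] = 5.0
        counts = prof.tss_vicinity_counts(track_from(v), [g])
        assert counts["gm"] == 5.0
        # a position 800 bp rightward (upstream beyond 500) is excluded
        v2 = np.zeros(10_000)
        v2[7999 + 800] = 5.0
        assert prof.tss_vicinity_counts(track_from(v2), [g])["gm"] == 0.0

    def test_block_inside_window_adds_exact_mass(self):
        v = np.ones(10_000)
        g1 = make_gene("g1", 3000, 5000, "+")
        g2 = make_gene("g2", 7000, 9000, "+")
        v[3100:3200] = 3.0  # +2 over background for 100 bp inside g1's window
        counts = prof.tss_vicinity_counts(track_from(v), [g1, g2])
        assert counts["g1"] - counts["g2"] == pytest.approx(200.0)
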