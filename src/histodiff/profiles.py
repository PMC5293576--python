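"""Anchor-centered average profiles and CpG-island window statistics.

A meta-profile averages the normalized signal over a set of anchors (TSSs,
TTSs, CpG-island centers), orienting each window by the anchor's strand so
that positive offsets always point in the direction of transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation import CpGIsland, GeneModel
from .coverage import CoverageTrack, region_count
from .stats import TTestResult, pooled_ttest, welch_ttest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    chrom: str
    position: int
    strand: str = "+"


@dataclass(frozen=True)
class AnchorSet:
    name: str
    anchors: tuple[Anchor, ...]

    def __len__(self):
        return len(self.anchors)


def anchors_from_genes(genes: list[GeneModel], which: str = "tss") -> AnchorSet:
    """Anchor set at gene TSSs or TTSs, keeping the gene strand."""
    if which not in ("tss", "tts"):
        raise ValueError("which must be 'tss' or 'tts'")
    anchors = tuple(
        Anchor(g.body.chrom, g.tss if which == "tss" else g.tts, g.strand)
        for g in genes
    )
    return AnchorSet(which, anchors)


def anchors_from_cpg(islands: list[CpGIsland]) -> AnchorSet:
    anchors = tuple(
        Anchor(isl.interval.chrom, isl.center, "+") for isl in islands
    )
    return AnchorSet("cpg_center", anchors)


@dataclass
class MetaProfile:
    """Average signal at each offset relative to the anchors.

    ``offsets`` runs from ``-half_window`` to ``half_window - 1``;
    ``values[i]`` is the mean signal at ``offsets[i]``, with offsets
    oriented 5'->3' for minus-strand anchors.
    """

    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int
    n_truncated: int = 0


def meta_profile(
    track: CoverageTrack, anchors: AnchorSet, half_window: int = 3000
) -> MetaProfile:
    """Average anchor-centered profile.

    Value at offset d = (sum over anchors of track[anchor + orient(d)]) /
    n_anchors, where orient flips the sign of d for minus-strand anchors.
    Windows that run past a chromosome edge contribute zeros there (the
    divisor stays the anchor count), and the truncation is counted.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    w = half_window
    total = np.zeros(2 * w, dtype=np.float64)
    n_truncated = 0
    for a in anchors.anchors:
        v = track.data[a.chrom]
        if a.strand == "-":
            # offset d reads track[pos - d]; reversing [pos-w+1, pos+w+1)
            # puts position pos - d at index d + w
            lo, hi = a.position - w + 1, a.position + w + 1
        else:
            lo, hi = a.position - w, a.position + w
        window = np.zeros(2 * w, dtype=np.float64)
        src_lo, src_hi = max(0, lo), min(len(v), hi)
        if src_lo > lo or src_hi < hi:
            n_truncated += 1
        if src_lo < src_hi:
            window[src_lo - lo : src_hi - lo] = v[src_lo:src_hi]
        if a.strand == "-":
            window = window[::-1]
        total += window
    if n_truncated:
        logger.info("meta_profile: %d windows truncated at chromosome edges", n_truncated)
    return MetaProfile(
        offsets=np.arange(-w, w),
        values=total / len(anchors),
        n_anchors=len(anchors),
        n_truncated=n_truncated,
    )


@dataclass(frozen=True)
class WindowStatResult:
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


def cpg_window_ttest(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    islands: list[CpGIsland],
    window: int = 500,
    pooled: bool = False,
) -> WindowStatResult:
    """Two-sample t-test of per-island mean signal in a window around each
    CpG-island midpoint (0.5 kb by default).

    Welch's unequal-variance form by default; ``pooled`` switches to the
    classical pooled-variance Student test.
    """
    if len(islands) < 2:
        raise ValueError("need >= 2 CpG islands")
    half = window // 2
    means_a, means_b = [], []
    for isl in islands:
        c = isl.center
        from .annotation import GenomicInterval

        iv = GenomicInterval(isl.interval.chrom, max(0, c - half), c - half + window)
        means_a.append(region_count(track_a, iv) / window)
        means_b.append(region_count(track_b, iv) / window)
    test = pooled_ttest if pooled else welch_ttest
    res: TTestResult = test(means_a, means_b)
    return WindowStatResult(
        mean_a=float(np.mean(means_a)),
        mean_b=float(np.mean(means_b)),
        t_statistic=res.t_statistic,
        p_value=res.p_value,
        n_a=len(means_a),
        n_b=len(means_b),
    )


def tss_vicinity_counts(
    track: CoverageTrack,
    genes: list[GeneModel],
    upstream: int = 500,
    downstream: int = 1000,
) -> dict[str, float]:
    """Per-gene signal in the strand-oriented TSS vicinity.

    The window covers offsets ``[-upstream, +downstream)`` relative to the
    TSS in the direction of transcription, i.e. for a minus-strand gene it
    extends leftward in genomic coordinates.
    """
    if not genes:
        raise ValueError("empty gene list")
    from .annotation import GenomicInterval

    out: dict[str, float] = {}
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        else:
            # offsets d in [-up, down) map to genomic positions tss - d
            lo, hi = g.tss - downstream + 1, g.tss + upstream + 1
        lo = max(0, lo)
        if hi <= lo:
            out[g.gene_id] = 0.0
            continue
        out[g.gene_id] = region_count(track, GenomicInterval(g.body.chrom, lo, hi))
    return out
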