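"""Copy-number amplification detection from paired coverage tracks.

A region is called amplified when it satisfies five criteria: (1) wider
than 1 kb (strict), (2) its signal is >= 5-fold the case genome average,
(3) >= 5-fold higher in case than in control, (4) >= 2-fold over the
control genome average (case signal expressed on the control library's
depth scale), and (5) duplicate reads have been excluded by sequence.
Each surviving region is scored with an upper-tail Poisson p-value using
the (depth-scaled) control read count as lambda and the case count as k.

Candidates are delimited by a sliding-window scan (200-bp windows,
100-bp step): windows passing the fold criteria pointwise are merged and
the merged region is re-tested on its aggregate counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .annotation import GeneModel, GenomicInterval, MappedRead
from .coverage import CoverageTrack
from .profiles import WindowStatResult, tss_vicinity_counts
from .stats import poisson_upper_tail

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AmplificationParams:
    min_width: int = 1000
    fold_over_case_mean: float = 5.0
    fold_case_over_control: float = 5.0
    fold_over_control_mean: float = 2.0
    window: int = 200
    step: int = 100
    merge_gap: int = 250
    depth_scaling: bool = True
    dedup: bool = True

    def __post_init__(self):
        if min(self.fold_over_case_mean, self.fold_case_over_control,
               self.fold_over_control_mean) <= 0:
            raise ValueError("fold thresholds must be > 0")
        if self.min_width < 1 or self.window < 1 or self.step < 1:
            raise ValueError("widths must be >= 1")


@dataclass(frozen=True)
class AmplifiedRegion:
    interval: GenomicInterval
    count_case: float           # estimated read count in region, case
    count_control: float        # estimated read count in region, control
    fold_vs_case_mean: float
    fold_vs_control: float
    fold_vs_control_mean: float
    p_value: float
    criteria_passed: tuple[bool, bool, bool, bool, bool]


def dedup_reads(reads: Iterable[MappedRead]) -> tuple[list[MappedRead], int]:
    """Remove duplicate reads, keyed by coordinates+strand+sequence.

    When the sequence tag is absent the key degrades to coordinates and
    strand alone, which also removes genuine co-mapping molecules; supply
    sequences when duplicate structure matters.  Returns the retained
    reads and the number removed.
    """
    seen: set[tuple] = set()
    kept: list[MappedRead] = []
    n_removed = 0
    for r in reads:
        iv = r.interval
        key = (iv.chrom, iv.start, iv.end, iv.strand, r.sequence)
        if key in seen:
            n_removed += 1
            continue
        seen.add(key)
        kept.append(r)
    if n_removed:
        logger.info("dedup: removed %d duplicate reads", n_removed)
    return kept, n_removed


def _window_sums(v: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window sums via cumulative sums: (starts, sums)."""
    n = len(v)
    if n < window:
        return np.array([], dtype=int), np.array([])
    cs = np.concatenate([[0.0], np.cumsum(v)])
    starts = np.arange(0, n - window + 1, step)
    return starts, cs[starts + window] - cs[starts]


def scan_amplified(
    track_case: CoverageTrack,
    track_control: CoverageTrack,
    params: AmplificationParams = AmplificationParams(),
    dedup_applied: bool = True,
) -> list[AmplifiedRegion]:
    """Scan both normalized tracks for amplified regions.

    Returns regions passing all five criteria, sorted by p-value
    ascending.  ``dedup_applied`` records whether criterion (5) was
    honoured upstream (:func:`dedup_reads` before the pileup).
    """
    if not (track_case.normalized and track_control.normalized):
        raise ValueError("both tracks must be normalized")
    if set(track_case.data) != set(track_control.data) or any(
        len(track_case.data[c]) != len(track_control.data[c]) for c in track_case.data
    ):
        raise ValueError("tracks are on different chromosome sets")

    # convert a normalized coverage sum into an estimated read count
    def est_reads(track: CoverageTrack, norm_sum: float) -> float:
        raw = norm_sum * track.genome_mean
        return raw / track.mean_read_footprint

    depth_ratio = (
        track_case.total_reads / track_control.total_reads
        if params.depth_scaling
        else 1.0
    )
    # case-over-control genome-mean ratio for criterion 4: expresses the
    # case region mean on the control library's depth scale
    case_to_control_scale = (
        track_control.genome_mean / track_case.genome_mean * depth_ratio
        if params.depth_scaling
        else 1.0
    )

    regions: list[AmplifiedRegion] = []
    for chrom in track_case.data:
        vc = track_case.data[chrom]
        vn = track_control.data[chrom]
        starts, case_sums = _window_sums(vc, params.window, params.step)
        if len(starts) == 0:
            continue
        _, ctrl_sums = _window_sums(vn, params.window, params.step)
        w = params.window
        ok2 = case_sums / w >= params.fold_over_case_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            ok3 = case_sums >= params.fold_case_over_control * ctrl_sums
        ok3 &= case_sums > 0
        # case mean, re-expressed in units of the control genome mean
        ok4 = (case_sums / w) / case_to_control_scale >= params.fold_over_control_mean
        passing = ok2 & ok3 & ok4
        if not passing.any():
            continue
        # merge passing windows, bridging short runs of failing windows so
        # sampling noise inside a genuine region does not fragment it; the
        # merged region is re-tested on its aggregate counts below
        merged: list[list[int]] = []
        for s in starts[passing]:
            e = int(s) + w
            if merged and int(s) - merged[-1][1] <= params.merge_gap:
                merged[-1][1] = e
            else:
                merged.append([int(s), e])
        for s, e in merged:
            iv = GenomicInterval(chrom, s, e)
            case_sum = float(vc[s:e].sum())
            ctrl_sum = float(vn[s:e].sum())
            width = e - s
            fold_case_mean = case_sum / width
            fold_ctrl = case_sum / ctrl_sum if ctrl_sum > 0 else float("inf")
            fold_ctrl_mean = fold_case_mean / case_to_control_scale
            crit = (
                width > params.min_width,
                fold_case_mean >= params.fold_over_case_mean,
                fold_ctrl >= params.fold_case_over_control,
                fold_ctrl_mean >= params.fold_over_control_mean,
                dedup_applied,
            )
            if not all(crit):
                continue
            lam = est_reads(track_control, ctrl_sum) * depth_ratio
            k = est_reads(track_case, case_sum)
            p = poisson_upper_tail(lam, k)
            regions.append(
                AmplifiedRegion(
                    interval=iv,
                    count_case=k,
                    count_control=est_reads(track_control, ctrl_sum),
                    fold_vs_case_mean=fold_case_mean,
                    fold_vs_control=fold_ctrl,
                    fold_vs_control_mean=fold_ctrl_mean,
                    p_value=p,
                    criteria_passed=crit,
                )
            )
    regions.sort(key=lambda r: (r.p_value, r.interval))
    return regions


def annotate_amplified(
    regions: list[AmplifiedRegion], genes: list[GeneModel]
) -> dict[str, float]:
    """Genes overlapping (>= 1 bp) any amplified region, with the minimum
    p-value among the regions they touch."""
    out: dict[str, float] = {}
    for g in genes:
        best = None
        for r in regions:
            if r.interval.overlaps(g.body):
                if best is None or r.p_value < best:
                    best = r.p_value
        if best is not None:
            out[g.gene_id] = best
    return out


def subgroup_evidence_report(
    track_case: CoverageTrack,
    track_control: CoverageTrack,
    genes: list[GeneModel],
    marker_ids: list[str],
    amplified: dict[str, float],
    cpg_ttest: WindowStatResult | None = None,
) -> dict:
    """Assemble per-marker promoter signal, amplification hits and the
    CpG-window test into one evidence report.

    The report states evidence (signal ratios, amplification flags, the
    t-test), not a subgroup diagnosis.
    """
    by_id = {g.gene_id: g for g in genes}
    markers = {}
    for mid in marker_ids:
        g = by_id.get(mid)
        if g is None:
            markers[mid] = {"status": "not evaluable"}
            continue
        counts_case = tss_vicinity_counts(track_case, [g])[mid]
        counts_ctrl = tss_vicinity_counts(track_control, [g])[mid]
        ratio = counts_case / counts_ctrl if counts_ctrl > 0 else float("inf")
        flags = []
        if ratio < 1:
            flags.append("reduced in case")
        if mid in amplified:
            flags.append("amplified")
        markers[mid] = {
            "status": "evaluated",
            "tss_count_case": counts_case,
            "tss_count_control": counts_ctrl,
            "ratio_case_over_control": ratio,
            "flags": flags,
        }
    report: dict = {
        "markers": markers,
        "amplified_genes": {k: v for k, v in sorted(amplified.items())},
    }
    if cpg_ttest is not None:
        report["cpg_window_ttest"] = {
            "mean_control": cpg_ttest.mean_a,
            "mean_case": cpg_ttest.mean_b,
            "t_statistic": cpg_ttest.t_statistic,
            "p_value": cpg_ttest.p_value,
            "n_islands": cpg_ttest.n_a,
        }
    return report


def write_amplified_bed(regions: list[AmplifiedRegion], path) -> None:
    """BED5 with -log10 p-value in column 5."""
    from .annotation import _open_text

    with _open_text(path, "wt") as fh:
        for i, r in enumerate(regions):
            iv = r.interval
            neglog = -np.log10(r.p_value) if r.p_value > 0 else 999.0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tamp_{i}\t{neglog:.3f}\n")
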