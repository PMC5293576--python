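"""Peak I/O, gene-region assignment, gain/loss classification, overlap stats.

A gene "gains" the mark when it has no peak in any of promoter, exon or
gene body in the control sample but at least one such peak in the case
sample; "loses" it in the reverse situation.  Category assignment uses
>= 1 bp overlap by default; a peak may count for several categories and
several genes.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from intervaltree import IntervalTree

from .annotation import AnnotationError, ChromSizes, GeneModel, GenomicInterval, _open_text
from .coverage import CoverageTrack

CATEGORIES = ("promoter", "exon", "gene_body")


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    sample: str
    score: float | None = None

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class RegionScheme:
    """Promoter window definitions relative to the TSS.

    The distal window (-5 kb / +1 kb) and the proximal window
    (-250 / +250 bp) are both strand-oriented.
    """

    promoter_upstream: int = 5000
    promoter_downstream: int = 1000
    proximal_upstream: int = 250
    proximal_downstream: int = 250

    def promoter_window(self, gene: GeneModel, which: str = "distal") -> GenomicInterval:
        if which == "distal":
            up, down = self.promoter_upstream, self.promoter_downstream
        elif which == "proximal":
            up, down = self.proximal_upstream, self.proximal_downstream
        else:
            raise ValueError("which must be 'distal' or 'proximal'")
        if gene.strand == "+":
            lo, hi = gene.tss - up, gene.tss + down
        else:
            lo, hi = gene.tss - down + 1, gene.tss + up + 1
        return GenomicInterval(gene.body.chrom, max(0, lo), hi)


def read_peaks(path, sample_label: str, sizes: ChromSizes) -> list[Peak]:
    """Read peaks from BED3+ or ENCODE broadPeak.

    With >= 7 columns the 7th (broadPeak signalValue) becomes the score.
    Peaks on unknown chromosomes are dropped; intervals are clipped and
    the list returned sorted by (chrom, start).
    """
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"{path}:{lineno}: BED requires >= 3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            score = float(fields[6]) if len(fields) >= 7 else None
            if iv.chrom not in sizes:
                continue
            clipped = sizes.clip(iv)
            if clipped is None:
                continue
            peaks.append(Peak(clipped, sample_label, score))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def _peak_trees(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, i
        )
    return trees


def _overlapping_indices(
    trees: dict[str, IntervalTree],
    region: GenomicInterval,
    peaks: list[Peak],
    min_overlap_frac: float,
) -> set[int]:
    tree = trees.get(region.chrom)
    if tree is None:
        return set()
    hits = tree.overlap(region.start, region.end)
    if min_overlap_frac <= 0:
        return {h.data for h in hits}
    out = set()
    for h in hits:
        ov = min(h.end, region.end) - max(h.begin, region.start)
        if ov >= min_overlap_frac * (h.end - h.begin):
            out.add(h.data)
    return out


def assign_peaks(
    peaks: list[Peak],
    genes: list[GeneModel],
    scheme: RegionScheme = RegionScheme(),
    promoter: str = "distal",
    min_overlap_frac: float = 0.0,
) -> dict[str, dict[str, int]]:
    """Count peaks per gene per category (promoter / exon / gene_body).

    A peak counts for a category when it overlaps the category interval by
    at least 1 bp (or the given fraction of the peak).  A peak overlapping
    several exons of a gene counts once for the exon category.
    """
    trees = _peak_trees(peaks)
    counts: dict[str, dict[str, int]] = {}
    for g in genes:
        prom = scheme.promoter_window(g, promoter)
        promoter_hits = _overlapping_indices(trees, prom, peaks, min_overlap_frac)
        exon_hits: set[int] = set()
        for ex in g.exons:
            exon_hits |= _overlapping_indices(trees, ex, peaks, min_overlap_frac)
        body_hits = _overlapping_indices(trees, g.body, peaks, min_overlap_frac)
        counts[g.gene_id] = {
            "promoter": len(promoter_hits),
            "exon": len(exon_hits),
            "gene_body": len(body_hits),
        }
    return counts


@dataclass(frozen=True)
class GainLossCall:
    gene_id: str
    status: str  # gained | lost | unchanged_present | unchanged_absent
    evidence: dict = field(hash=False)


def classify_gain_loss(
    counts_control: dict[str, dict[str, int]],
    counts_case: dict[str, dict[str, int]],
) -> list[GainLossCall]:
    """Classify every gene by peak presence across the three categories.

    gained: no peak anywhere in control, >= 1 peak somewhere in case;
    lost: the reverse; presence in both -> unchanged_present; in neither
    -> unchanged_absent.  Category identity is irrelevant: presence is
    pooled over promoter, exon and gene body.
    """
    if set(counts_control) != set(counts_case):
        raise ValueError("control and case count tables cover different genes")
    calls = []
    for gene_id in counts_control:
        ctrl = counts_control[gene_id]
        case = counts_case[gene_id]
        has_ctrl = any(ctrl[c] > 0 for c in CATEGORIES)
        has_case = any(case[c] > 0 for c in CATEGORIES)
        if has_case and not has_ctrl:
            status = "gained"
        elif has_ctrl and not has_case:
            status = "lost"
        elif has_ctrl and has_case:
            status = "unchanged_present"
        else:
            status = "unchanged_absent"
        calls.append(
            GainLossCall(gene_id, status, {"control": dict(ctrl), "case": dict(case)})
        )
    return calls


@dataclass(frozen=True)
class WidthStats:
    n: int
    mean: float
    median: float


def _width_stats(widths: list[int]) -> WidthStats:
    if not widths:
        return WidthStats(0, float("nan"), float("nan"))
    return WidthStats(len(widths), statistics.fmean(widths), statistics.median(widths))


@dataclass(frozen=True)
class PeakOverlapSummary:
    """Venn-style overlap counts between two peak sets.

    Sharing is per peak, not per pair: a control peak overlapping two case
    peaks is one shared control peak, so the shared count can differ
    between the two sides and is reported for each.
    """

    n_control: int
    n_case: int
    n_shared_control: int
    n_shared_case: int
    n_control_only: int
    n_case_only: int
    width_shared: WidthStats
    width_control_only: WidthStats
    width_case_only: WidthStats


def overlap_summary(
    peaks_control: list[Peak], peaks_case: list[Peak]
) -> PeakOverlapSummary:
    """Per-peak sharing (>= 1 bp overlap) and width statistics per class."""
    if not peaks_control or not peaks_case:
        raise ValueError("both peak lists must be non-empty")
    trees_case = _peak_trees(peaks_case)
    trees_ctrl = _peak_trees(peaks_control)
    shared_w, ctrl_only_w, case_only_w = [], [], []
    n_shared_ctrl = 0
    for p in peaks_control:
        if _overlapping_indices(trees_case, p.interval, peaks_case, 0.0):
            n_shared_ctrl += 1
            shared_w.append(p.width)
        else:
            ctrl_only_w.append(p.width)
    n_shared_case = 0
    for p in peaks_case:
        if _overlapping_indices(trees_ctrl, p.interval, peaks_control, 0.0):
            n_shared_case += 1
            shared_w.append(p.width)
        else:
            case_only_w.append(p.width)
    return PeakOverlapSummary(
        n_control=len(peaks_control),
        n_case=len(peaks_case),
        n_shared_control=n_shared_ctrl,
        n_shared_case=n_shared_case,
        n_control_only=len(peaks_control) - n_shared_ctrl,
        n_case_only=len(peaks_case) - n_shared_case,
        width_shared=_width_stats(shared_w),
        width_control_only=_width_stats(ctrl_only_w),
        width_case_only=_width_stats(case_only_w),
    )


def standin_call_peaks(
    track: CoverageTrack,
    sample_label: str = "sample",
    min_value: float = 4.0,
    min_width: int = 200,
    merge_gap: int = 50,
) -> list[Peak]:
    """Deterministic threshold peak caller for self-contained runs.

    Emits maximal runs of positions whose normalized value is at least
    ``min_value`` (fold over the genome mean), merges runs separated by at
    most ``merge_gap`` bp, and drops merged runs narrower than
    ``min_width``.  This is a simple threshold caller, not a model-based
    broad-peak caller; real analyses should supply externally called
    peaks.
    """
    if not track.normalized:
        raise ValueError("stand-in caller requires a normalized track")
    peaks: list[Peak] = []
    for chrom, v in track.data.items():
        above = v >= min_value
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        diffs = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diffs == 1)
        run_ends = np.flatnonzero(diffs == -1)
        merged: list[list[int]] = []
        for s, e in zip(run_starts.tolist(), run_ends.tolist()):
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= min_width:
                score = float(v[s:e].max())
                peaks.append(Peak(GenomicInterval(chrom, s, e), sample_label, score))
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    with _open_text(path, "wt") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            score = f"{p.score:.3f}" if p.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.sample}_{i}\t{score}\n")
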