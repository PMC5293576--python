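"""Normalized coverage tracks from mapped reads.

The pileup follows the classical ChIP-seq recipe: each read is shifted
50 bp toward the presumed fragment center (plus-strand reads downstream,
minus-strand reads upstream), per-base counts are the number of shifted
reads covering each position, and the track is normalized by the
genome-wide average per-base count so that enrichment reads directly as
fold over the genomic mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .annotation import ChromSizes, GenomicInterval, MappedRead

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftParams:
    """Read shift/extension parameters.

    ``shift_bp``
        Distance each read is moved along its strand (default 50 bp).
    ``extend_to``
        If set, reads are first extended from their 5' end to this fixed
        fragment length.
    ``literal_5prime``
        Move reads in the literal 5' direction instead of center-ward
        (plus-strand reads upstream, minus-strand downstream).  Off by
        default: center-ward shifting is what stacks the two strands'
        reads onto the fragment midpoint and reproduces the expected TSS
        enrichment profile.
    """

    shift_bp: int = 50
    extend_to: int | None = None
    literal_5prime: bool = False

    def __post_init__(self):
        if self.shift_bp < 0:
            raise ValueError("shift_bp must be >= 0")
        if self.extend_to is not None and self.extend_to < 1:
            raise ValueError("extend_to must be >= 1")


@dataclass
class CoverageTrack:
    """Per-chromosome per-base signal vectors plus library metadata.

    ``genome_mean`` is the mean raw per-base count over every position of
    every chromosome (zero-coverage bases included).  ``mean_read_footprint``
    is the average number of bases a retained read contributes, used to
    convert coverage sums back to approximate read counts.
    """

    data: dict[str, np.ndarray]
    total_reads: int
    genome_mean: float
    normalized: bool = False
    n_dropped: int = 0

    @property
    def genome_length(self) -> int:
        return sum(len(v) for v in self.data.values())

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    @property
    def mean_read_footprint(self) -> float:
        raw_sum = self.total_signal * (self.genome_mean if self.normalized else 1.0)
        return raw_sum / self.total_reads

    def values(self, chrom: str) -> np.ndarray:
        return self.data[chrom]


def shift_read(
    read: MappedRead, params: ShiftParams, sizes: ChromSizes
) -> GenomicInterval | None:
    """Shift (and optionally extend) one read; None if clipped away entirely.

    Center-ward by default: + reads translate ``+shift_bp``, - reads
    ``-shift_bp``.  With ``literal_5prime`` the signs flip.
    """
    iv = read.interval
    if iv.strand not in ("+", "-"):
        raise ValueError("cannot shift an unstranded read")
    start, end = iv.start, iv.end
    if params.extend_to is not None:
        if iv.strand == "+":
            end = start + params.extend_to
        else:
            start = end - params.extend_to
    sign = 1 if iv.strand == "+" else -1
    if params.literal_5prime:
        sign = -sign
    delta = sign * params.shift_bp
    start += delta
    end += delta
    length = sizes[iv.chrom]
    start = max(0, start)
    end = min(length, end)
    if start >= end:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def pileup(
    reads: Iterable[MappedRead], params: ShiftParams, sizes: ChromSizes
) -> CoverageTrack:
    """Raw per-base coverage: value at p = number of shifted reads covering p."""
    # gather per-chromosome coordinate arrays, then shift/clip vectorized
    by_chrom: dict[str, list[list[int]]] = {c: [[], [], []] for c in sizes}
    for read in reads:
        iv = read.interval
        if iv.strand not in ("+", "-"):
            raise ValueError("cannot shift an unstranded read")
        cols = by_chrom[iv.chrom]
        cols[0].append(iv.start)
        cols[1].append(iv.end)
        cols[2].append(1 if iv.strand == "+" else -1)
    deltas = {chrom: np.zeros(length + 1, dtype=np.float64) for chrom, length in sizes.items()}
    n_used = 0
    n_dropped = 0
    for chrom, (starts_l, ends_l, signs_l) in by_chrom.items():
        if not starts_l:
            continue
        length = sizes[chrom]
        starts = np.asarray(starts_l, dtype=np.int64)
        ends = np.asarray(ends_l, dtype=np.int64)
        signs = np.asarray(signs_l, dtype=np.int64)
        if params.extend_to is not None:
            ends = np.where(signs > 0, starts + params.extend_to, ends)
            starts = np.where(signs > 0, starts, ends - params.extend_to)
        if params.literal_5prime:
            signs = -signs
        shift = signs * params.shift_bp
        starts = np.clip(starts + shift, 0, length)
        ends = np.clip(ends + shift, 0, length)
        keep = starts < ends
        n_dropped += int((~keep).sum())
        starts, ends = starts[keep], ends[keep]
        n_used += len(starts)
        d = deltas[chrom]
        np.add.at(d, starts, 1.0)
        np.add.at(d, ends, -1.0)
    if n_used == 0:
        raise ValueError("no reads retained: empty library")
    if n_dropped:
        logger.info("pileup: %d reads clipped off-chromosome and dropped", n_dropped)
    data = {chrom: np.cumsum(d[:-1]) for chrom, d in deltas.items()}
    total_len = sizes.total
    genome_mean = float(sum(v.sum() for v in data.values())) / total_len
    return CoverageTrack(
        data=data,
        total_reads=n_used,
        genome_mean=genome_mean,
        normalized=False,
        n_dropped=n_dropped,
    )


def normalize(track: CoverageTrack) -> CoverageTrack:
    """Divide every value by the genome-average per-base count.

    The normalized track has global mean 1, so a value of ``f`` reads as
    ``f``-fold over the genomic average.  Re-normalizing is rejected.
    """
    if track.normalized:
        raise ValueError("track is already normalized")
    if track.genome_mean <= 0:
        raise ValueError("cannot normalize a track with zero genome mean")
    data = {chrom: v / track.genome_mean for chrom, v in track.data.items()}
    return CoverageTrack(
        data=data,
        total_reads=track.total_reads,
        genome_mean=track.genome_mean,
        normalized=True,
        n_dropped=track.n_dropped,
    )


def region_count(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Sum of per-base track values over ``[start, end)``, clipped to bounds."""
    if interval.chrom not in track.data:
        return 0.0
    v = track.data[interval.chrom]
    start = max(0, interval.start)
    end = min(len(v), interval.end)
    if start >= end:
        return 0.0
    return float(v[start:end].sum())


# ---------------------------------------------------------------------------
# bedGraph round-trip

_BEDGRAPH_DECIMALS = 6


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write the track as run-length-encoded bedGraph (zero runs omitted)."""
    from .annotation import _open_text

    with _open_text(path, "wt") as fh:
        fh.write(
            f"track type=bedGraph total_reads={track.total_reads} "
            f"genome_mean={track.genome_mean!r} "
            f"normalized={int(track.normalized)}\n"
        )
        for chrom in track.data:
            v = np.round(track.data[chrom], _BEDGRAPH_DECIMALS)
            if len(v) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(v)]])
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{val:.{_BEDGRAPH_DECIMALS}f}\n")


def read_bedgraph(path, sizes: ChromSizes) -> CoverageTrack:
    """Read a bedGraph written by :func:`write_bedgraph`.

    Overlapping lines are a format error; unknown chromosomes too.
    """
    from .annotation import AnnotationError, _open_text

    data = {chrom: np.zeros(length, dtype=np.float64) for chrom, length in sizes.items()}
    last_end: dict[str, int] = {}
    total_reads = 0
    genome_mean = 0.0
    normalized = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("track"):
                for token in line.split():
                    if token.startswith("total_reads="):
                        total_reads = int(token.split("=", 1)[1])
                    elif token.startswith("genome_mean="):
                        genome_mean = float(token.split("=", 1)[1])
                    elif token.startswith("normalized="):
                        normalized = bool(int(token.split("=", 1)[1]))
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise AnnotationError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise AnnotationError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start < last_end.get(chrom, 0):
                raise AnnotationError(f"{path}:{lineno}: overlapping bedGraph lines")
            if end > len(data[chrom]):
                raise AnnotationError(f"{path}:{lineno}: interval beyond chromosome end")
            data[chrom][start:end] = value
            last_end[chrom] = end
    return CoverageTrack(
        data=data,
        total_reads=total_reads,
        genome_mean=genome_mean,
        normalized=normalized,
    )
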