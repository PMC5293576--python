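"""Genome annotation and read I/O.

All coordinates are 0-based half-open (BED convention) internally; GTF-lite
input (1-based inclusive) is converted at the boundary.  The minus-strand
TSS is the last base of the interval (``end - 1``), mirroring UCSC txEnd
semantics.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class ChromSizes(Mapping):
    """Mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        for name, length in sizes.items():
            if length <= 0:
                raise AnnotationError(f"non-positive length for {name}: {length}")
        self._sizes = dict(sizes)

    def __getitem__(self, k):
        return self._sizes[k]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self):
        return len(self._sizes)

    @property
    def total(self) -> int:
        return sum(self._sizes.values())

    def clip(self, iv: GenomicInterval) -> GenomicInterval | None:
        """Clip an interval to chromosome bounds; None if nothing remains."""
        if iv.chrom not in self._sizes:
            return None
        start = max(0, iv.start)
        end = min(self._sizes[iv.chrom], iv.end)
        if start >= end:
            return None
        return GenomicInterval(iv.chrom, start, end, iv.strand)


@dataclass(frozen=True)
class MappedRead:
    """A uniquely mapped sequencing read.

    ``sequence`` (optional) is used only for duplicate exclusion; the BED6
    name column carries it.
    """

    interval: GenomicInterval
    sequence: str | None = None

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise AnnotationError("mapped reads must be stranded (+/-)")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TTS and an exon chain."""

    gene_id: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if self.body.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand required")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.body.chrom:
                raise AnnotationError(f"gene {self.gene_id}: exon off-chromosome")
            if ex.start < self.body.start or ex.end > self.body.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside body"
                )
            if prev_end is not None and ex.start < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        """Transcription start site: body.start on +, body.end - 1 on -."""
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site (opposite end from the TSS)."""
        return self.body.end - 1 if self.strand == "+" else self.body.start


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass
class ReadSet:
    """Reads retained from a BED6 file plus drop accounting."""

    reads: list[MappedRead] = field(default_factory=list)
    n_dropped_unknown_chrom: int = 0
    n_dropped_empty: int = 0

    def __iter__(self) -> Iterator[MappedRead]:
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


# ---------------------------------------------------------------------------
# readers


def read_chrom_sizes(path) -> ChromSizes:
    """Read a two-column (name, length) TSV of chromosome sizes."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from exc
            if length <= 0:
                raise AnnotationError(f"{path}:{lineno}: non-positive length")
            if name in sizes:
                raise AnnotationError(f"{path}:{lineno}: duplicate chromosome {name}")
            sizes[name] = length
    return ChromSizes(sizes)


def read_reads_bed(path, sizes: ChromSizes) -> ReadSet:
    """Read mapped reads from BED6.

    Reads on chromosomes absent from ``sizes`` are dropped and counted;
    coordinates are clipped to chromosome bounds.  The name column is kept
    as the read's sequence tag for duplicate exclusion.
    """
    out = ReadSet()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}:{lineno}: BED6 with strand required, got "
                    f"{len(fields)} columns"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if chrom not in sizes:
                out.n_dropped_unknown_chrom += 1
                continue
            clipped = sizes.clip(iv)
            if clipped is None:
                out.n_dropped_empty += 1
                continue
            out.reads.append(MappedRead(clipped, sequence=name or None))
    if out.n_dropped_unknown_chrom or out.n_dropped_empty:
        logger.info(
            "%s: dropped %d reads on unknown chromosomes, %d clipped empty",
            path,
            out.n_dropped_unknown_chrom,
            out.n_dropped_empty,
        )
    return out


def read_gene_models(path, sizes: ChromSizes) -> list[GeneModel]:
    """Read gene models from BED12 (blockStarts/blockSizes define exons)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes_str = fields[10].rstrip(",").split(",")
            starts_str = fields[11].rstrip(",").split(",")
            if len(sizes_str) != n_blocks or len(starts_str) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: block count mismatch")
            if chrom not in sizes:
                raise AnnotationError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if name in seen:
                raise AnnotationError(f"{path}:{lineno}: duplicate gene_id {name}")
            seen.add(name)
            body = GenomicInterval(chrom, start, end, strand)
            exons = tuple(
                GenomicInterval(chrom, start + int(bs), start + int(bs) + int(sz), strand)
                for bs, sz in zip(starts_str, sizes_str)
            )
            try:
                genes.append(GeneModel(name, body, exons))
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_gene_models_gtf(path, sizes: ChromSizes) -> list[GeneModel]:
    """Read a GTF-lite gene table (1-based inclusive; converted on input).

    Recognizes ``gene`` and ``exon`` feature lines carrying a ``gene_id``
    attribute; exons without an explicit gene line derive the body from
    their span.
    """
    bodies: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            gene_id = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gene_id = token.split(None, 1)[1].strip('" ')
            if gene_id is None:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            if feature == "gene":
                if gene_id in bodies:
                    raise AnnotationError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
                bodies[gene_id] = iv
            else:
                exons.setdefault(gene_id, []).append(iv)
    genes = []
    for gene_id in sorted(set(bodies) | set(exons)):
        ex = sorted(exons.get(gene_id, []), key=lambda e: e.start)
        if gene_id in bodies:
            body = bodies[gene_id]
        else:
            body = GenomicInterval(
                ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand
            )
        if body.chrom not in sizes:
            raise AnnotationError(f"gene {gene_id}: unknown chromosome {body.chrom}")
        if not ex:
            ex = [body]
        genes.append(GeneModel(gene_id, body, tuple(ex)))
    return genes


def read_cpg_islands(path, sizes: ChromSizes) -> list[CpGIsland]:
    """Read CpG islands from BED (first three columns used)."""
    islands = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"{path}:{lineno}: BED requires >= 3 columns")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            if iv.chrom not in sizes:
                raise AnnotationError(f"{path}:{lineno}: unknown chromosome {iv.chrom}")
            islands.append(CpGIsland(iv))
    return islands


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers; used by the simulator)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with _open_text(path, "wt") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def write_reads_bed(reads: Iterable[MappedRead], path) -> None:
    """Write reads as BED6; sequence tag goes in the name column."""
    path = Path(path)
    if path.suffix == ".gz":
        # fixed mtime so identical read sets give byte-identical files
        raw = io.StringIO()
        _write_reads(reads, raw)
        with open(path, "wb") as out:
            with gzip.GzipFile(fileobj=out, mode="wb", mtime=0) as gz:
                gz.write(raw.getvalue().encode())
    else:
        with open(path, "wt") as fh:
            _write_reads(reads, fh)


def _write_reads(reads: Iterable[MappedRead], fh) -> None:
    for r in reads:
        iv = r.interval
        name = r.sequence or "."
        fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_gene_models_bed12(genes: Iterable[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            b = g.body
            block_sizes = ",".join(str(e.width) for e in g.exons)
            block_starts = ",".join(str(e.start - b.start) for e in g.exons)
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{g.gene_id}\t0\t{b.strand}\t"
                f"{b.start}\t{b.end}\t0\t{len(g.exons)}\t{block_sizes}\t{block_starts}\n"
            )


def write_cpg_bed(islands: Iterable[CpGIsland], path) -> None:
    with _open_text(path, "wt") as fh:
        for i, isl in enumerate(islands):
            iv = isl.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tcpg_{i}\n")
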