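"""Synthetic two-sample ChIP-seq fixture with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, on a small genome:

* background reads with uniform 5' starts at a Poisson-thinned per-base
  rate on each strand;
* promoter-localized enrichment: extra read pairs whose fragment centers
  are normally distributed around the TSS, with 5' starts offset 50 bp
  outward so that the standard 50-bp center-ward shift stacks them on the
  fragment center;
* a subset of genes enriched only in the case sample (gained) or only in
  the control (lost), the rest in both;
* one amplified region in which every case read is duplicated
  ``floor(fold) - 1`` times as genuine extra molecules (distinct sequence
  tags), optionally plus PCR duplicates (identical tags);
* an expression table coupled to the case sample's true promoter signal.

A single seed drives one named generator; identical configurations give
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation import (
    ChromSizes,
    CpGIsland,
    GeneModel,
    GenomicInterval,
    MappedRead,
    write_chrom_sizes,
    write_cpg_bed,
    write_gene_models_bed12,
    write_reads_bed,
)
from .expression import ExpressionTable, write_expression_tsv


@dataclass(frozen=True)
class SimulationConfig:
    """Fixture parameters; defaults give a 1-Mb two-chromosome genome with
    60 genes, 10% gained and 10% lost, and one 2-kb fold-6 amplification."""

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 500_000), ("chr2", 500_000))
    n_genes: int = 60
    read_length: int = 36
    background_depth: float = 0.02  # reads per bp, both strands combined
    enriched_fold: float = 8.0
    gained_gene_frac: float = 0.1
    lost_gene_frac: float = 0.1
    amplify: bool = True
    amplified_region: tuple[str, int, int] | None = None  # None = auto-place
    amplified_width: int = 2000
    amplified_fold: float = 6.0
    expression_slope: float = 0.01
    expression_sigma: float = 0.5
    promoter_extent: int = 1500  # sets expected enriched reads per promoter
    promoter_spread: float = 150.0  # sd of fragment centers around the TSS
    shift_bp: int = 50
    gene_min_len: int = 2000
    gene_max_len: int = 6000
    gene_spacing: int = 10_000
    pcr_duplicate_frac: float = 0.0

    def __post_init__(self):
        if self.gained_gene_frac + self.lost_gene_frac > 1:
            raise ValueError("gained + lost fractions must be <= 1")
        if self.enriched_fold <= 1 or self.amplified_fold <= 1:
            raise ValueError("folds must be > 1")
        if self.background_depth <= 0:
            raise ValueError("background_depth must be > 0")
        sizes = dict(self.genome)
        if self.amplified_region is not None:
            chrom, start, end = self.amplified_region
            if chrom not in sizes or not (0 <= start < end <= sizes[chrom]):
                raise ValueError("amplified_region outside genome")


@dataclass
class GroundTruth:
    gained_gene_ids: list[str]
    lost_gene_ids: list[str]
    amplified_region: GenomicInterval | None
    amplified_fold: float
    # per gene, per sample: true promoter enrichment level (fold units;
    # 0 = background only)
    enrichment_levels: dict[str, dict[str, float]]
    # per gene: the case-sample true promoter signal expression couples to
    true_signal: dict[str, float]

    def to_json(self) -> str:
        d = {
            "gained_gene_ids": sorted(self.gained_gene_ids),
            "lost_gene_ids": sorted(self.lost_gene_ids),
            "amplified_region": (
                None
                if self.amplified_region is None
                else {
                    "chrom": self.amplified_region.chrom,
                    "start": self.amplified_region.start,
                    "end": self.amplified_region.end,
                    "fold": self.amplified_fold,
                }
            ),
            "enrichment_levels": {
                g: dict(v) for g, v in sorted(self.enrichment_levels.items())
            },
            "true_signal": {g: round(v, 6) for g, v in sorted(self.true_signal.items())},
        }
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SimulatedData:
    config: SimulationConfig
    sizes: ChromSizes
    genes: list[GeneModel]
    cpg_islands: list[CpGIsland]
    reads_control: list[MappedRead]
    reads_case: list[MappedRead]
    expression: ExpressionTable
    truth: GroundTruth

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": outdir / "chrom.sizes",
            "genes": outdir / "genes.bed12",
            "cpg": outdir / "cpg.bed",
            "reads_control": outdir / "reads_control.bed.gz",
            "reads_case": outdir / "reads_case.bed.gz",
            "expression": outdir / "expr.tsv",
            "truth": outdir / "truth.json",
        }
        write_chrom_sizes(self.sizes, paths["chrom_sizes"])
        write_gene_models_bed12(self.genes, paths["genes"])
        write_cpg_bed(self.cpg_islands, paths["cpg"])
        write_reads_bed(self.reads_control, paths["reads_control"])
        write_reads_bed(self.reads_case, paths["reads_case"])
        write_expression_tsv(self.expression, paths["expression"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate the full fixture for one seed."""
    rng = np.random.default_rng(config.seed)
    sizes = ChromSizes(dict(config.genome))

    genes, amp_interval = _place_genes_and_region(config, rng, sizes)
    n_gained = round(config.gained_gene_frac * len(genes))
    n_lost = round(config.lost_gene_frac * len(genes))
    order = rng.permutation(len(genes))
    gained_ids = sorted(genes[i].gene_id for i in order[:n_gained])
    lost_ids = sorted(genes[i].gene_id for i in order[n_gained : n_gained + n_lost])

    levels: dict[str, dict[str, float]] = {}
    for g in genes:
        level = config.enriched_fold * rng.uniform(0.8, 1.25)
        if g.gene_id in gained_ids:
            levels[g.gene_id] = {"control": 0.0, "case": level}
        elif g.gene_id in lost_ids:
            levels[g.gene_id] = {"control": level, "case": 0.0}
        else:
            levels[g.gene_id] = {"control": level, "case": level}

    reads_control, _ = _sample_reads(config, rng, sizes, genes, levels, "control")
    reads_case, case_enriched_by_gene = _sample_reads(
        config, rng, sizes, genes, levels, "case"
    )

    if amp_interval is not None:
        reads_case = _amplify_region(
            reads_case, amp_interval, config.amplified_fold, "case"
        )

    if config.pcr_duplicate_frac > 0:
        reads_control = _inject_pcr_duplicates(
            reads_control, config.pcr_duplicate_frac, rng
        )
        reads_case = _inject_pcr_duplicates(reads_case, config.pcr_duplicate_frac, rng)

    true_signal = _true_tss_signal(config, sizes, genes, case_enriched_by_gene, reads_case)
    expr_values = {}
    for g in genes:
        noise = float(rng.normal(0.0, config.expression_sigma)) if config.expression_sigma > 0 else 0.0
        expr_values[g.gene_id] = max(
            0.0, config.expression_slope * true_signal[g.gene_id] + noise
        )

    cpg_islands = [
        CpGIsland(
            GenomicInterval(
                g.body.chrom, max(0, g.tss - 400), min(sizes[g.body.chrom], g.tss + 400)
            )
        )
        for g in genes
    ]

    truth = GroundTruth(
        gained_gene_ids=gained_ids,
        lost_gene_ids=lost_ids,
        amplified_region=amp_interval,
        amplified_fold=config.amplified_fold if amp_interval is not None else 0.0,
        enrichment_levels=levels,
        true_signal=true_signal,
    )
    return SimulatedData(
        config=config,
        sizes=sizes,
        genes=genes,
        cpg_islands=cpg_islands,
        reads_control=_finalize(reads_control),
        reads_case=_finalize(reads_case),
        expression=ExpressionTable(expr_values),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# placement


def _place_genes_and_region(
    config: SimulationConfig, rng: np.random.Generator, sizes: ChromSizes
) -> tuple[list[GeneModel], GenomicInterval | None]:
    """Place non-overlapping genes with guaranteed spacing, reserving a slot
    for the amplified region (treated as a blocker item so promoter windows
    cannot reach it)."""
    chroms = list(sizes)
    total = sizes.total
    # genes per chromosome, proportional to length
    alloc = [int(config.n_genes * sizes[c] / total) for c in chroms]
    i = 0
    while sum(alloc) < config.n_genes:
        alloc[i % len(chroms)] += 1
        i += 1

    auto_amp = config.amplify and config.amplified_region is None
    amp_chrom = chroms[-1] if auto_amp else None

    genes: list[GeneModel] = []
    amp_interval: GenomicInterval | None = None
    gene_idx = 0
    for chrom, n_c in zip(chroms, alloc):
        lengths = list(rng.integers(config.gene_min_len, config.gene_max_len + 1, n_c))
        items: list[tuple[str, int]] = [("gene", int(l)) for l in lengths]
        if chrom == amp_chrom:
            items.insert(len(items) // 2, ("amp", config.amplified_width))
        k = len(items)
        if k == 0:
            continue
        required = sum(l for _, l in items) + (k + 1) * config.gene_spacing
        if required > sizes[chrom]:
            raise ValueError(
                f"infeasible placement on {chrom}: need {required} bp, have "
                f"{sizes[chrom]}; enlarge the genome or reduce n_genes"
            )
        slack = sizes[chrom] - required
        weights = rng.random(k + 1)
        extras = np.floor(slack * weights / weights.sum()).astype(int)
        cursor = 0
        for (kind, length), extra in zip(items, extras):
            cursor += config.gene_spacing + int(extra)
            start, end = cursor, cursor + length
            cursor = end
            if kind == "amp":
                amp_interval = GenomicInterval(chrom, start, end)
            else:
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                genes.append(
                    _make_gene(f"gene_{gene_idx:04d}", chrom, start, end, strand, rng)
                )
                gene_idx += 1

    if config.amplify and config.amplified_region is not None:
        chrom, start, end = config.amplified_region
        amp_interval = GenomicInterval(chrom, start, end)
        margin = 6000
        for g in genes:
            if g.body.chrom == chrom and g.body.start - margin < end and start < g.body.end + margin:
                raise ValueError(
                    "amplified_region conflicts with a placed gene; "
                    "choose different coordinates or a larger genome"
                )
    return genes, amp_interval


def _make_gene(
    gene_id: str, chrom: str, start: int, end: int, strand: str, rng: np.random.Generator
) -> GeneModel:
    body = GenomicInterval(chrom, start, end, strand)
    length = end - start
    n_exons = int(rng.integers(2, 5))
    n_cuts = 2 * (n_exons - 1)
    cuts = np.sort(rng.choice(np.arange(100, length - 100), size=n_cuts, replace=False))
    bounds = [0, *cuts.tolist(), length]
    exons = tuple(
        GenomicInterval(chrom, start + bounds[i], start + bounds[i + 1], strand)
        for i in range(0, len(bounds) - 1, 2)
    )
    return GeneModel(gene_id, body, exons)


# ---------------------------------------------------------------------------
# reads


def _sample_reads(
    config: SimulationConfig,
    rng: np.random.Generator,
    sizes: ChromSizes,
    genes: list[GeneModel],
    levels: dict[str, dict[str, float]],
    sample: str,
) -> tuple[list[MappedRead], dict[str, list[GenomicInterval]]]:
    rl = config.read_length
    reads: list[MappedRead] = []

    # background: uniform 5' starts, Poisson count per chromosome per strand
    raw: list[tuple[str, int, int, str]] = []
    for chrom in sizes:
        length = sizes[chrom]
        for strand in ("+", "-"):
            n = int(rng.poisson(config.background_depth * length / 2.0))
            if strand == "+":
                starts = rng.integers(0, max(1, length - rl + 1), n).tolist()
                raw.extend((chrom, s, s + rl, "+") for s in starts)
            else:
                five = rng.integers(rl - 1, length, n).tolist()
                raw.extend((chrom, p - rl + 1, p + 1, "-") for p in five)

    # promoter enrichment: fragment centers ~ N(TSS, spread); 5' starts sit
    # 50 bp outward so center-ward shifting stacks the reads on the center
    enriched_by_gene: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        level = levels[g.gene_id][sample]
        if level <= 1.0:
            continue
        mean_reads = (level - 1.0) * config.background_depth * config.promoter_extent
        n = int(rng.poisson(mean_reads))
        centers = np.rint(rng.normal(g.tss, config.promoter_spread, n)).astype(int)
        strands = rng.integers(0, 2, n)
        length = sizes[g.body.chrom]
        placed = []
        for c, s in zip(centers, strands):
            if s == 0:
                start = c - config.shift_bp
                iv = (start, start + rl, "+")
            else:
                end = c + config.shift_bp + 1
                iv = (end - rl, end, "-")
            start = max(0, iv[0])
            end = min(length, iv[1])
            if start >= end:
                continue
            gi = GenomicInterval(g.body.chrom, start, end, iv[2])
            raw.append((g.body.chrom, start, end, iv[2]))
            placed.append(gi)
        enriched_by_gene[g.gene_id] = placed

    # unique per-sample sequence tags (distinct molecules)
    reads = [
        MappedRead(GenomicInterval(chrom, start, end, strand), sequence=f"{sample}_r{i:07d}")
        for i, (chrom, start, end, strand) in enumerate(raw)
    ]
    return reads, enriched_by_gene


def _five_prime(iv: GenomicInterval) -> int:
    return iv.start if iv.strand == "+" else iv.end - 1


def _amplify_region(
    reads: list[MappedRead], region: GenomicInterval, fold: float, sample: str
) -> list[MappedRead]:
    """Duplicate every read whose 5' start falls in the region
    ``floor(fold) - 1`` times, as genuine extra molecules."""
    extra_copies = math.floor(fold) - 1
    out = list(reads)
    tag = 0
    for r in reads:
        if r.interval.chrom != region.chrom:
            continue
        p = _five_prime(r.interval)
        if region.start <= p < region.end:
            for _ in range(extra_copies):
                out.append(MappedRead(r.interval, sequence=f"{sample}_amp{tag:07d}"))
                tag += 1
    return out


def _inject_pcr_duplicates(
    reads: list[MappedRead], frac: float, rng: np.random.Generator
) -> list[MappedRead]:
    """Append copies with IDENTICAL sequence tags (removable by dedup)."""
    n_dup = int(round(frac * len(reads)))
    idx = rng.choice(len(reads), size=n_dup, replace=True)
    return list(reads) + [reads[int(i)] for i in idx]


def _finalize(reads: list[MappedRead]) -> list[MappedRead]:
    # generation order is already deterministic for a given seed
    return reads


# ---------------------------------------------------------------------------
# ground-truth signal


def _true_tss_signal(
    config: SimulationConfig,
    sizes: ChromSizes,
    genes: list[GeneModel],
    enriched_by_gene: dict[str, list[GenomicInterval]],
    reads_case: list[MappedRead],
) -> dict[str, float]:
    """Noise-free TSS-vicinity signal per gene for the case sample.

    Background contributes its expected footprint; the enrichment part is
    the realized footprint of that gene's enriched reads (after the
    center-ward shift) inside the -0.5 kb / +1 kb window, all expressed on
    the normalized (fold-over-genome-mean) scale of the case library.
    """
    rl = config.read_length
    genome_len = sizes.total
    total_footprint = sum(r.interval.width for r in reads_case)
    genome_mean = total_footprint / genome_len if reads_case else 1.0
    bg_window = config.background_depth * rl * 1500  # expected background part
    out: dict[str, float] = {}
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss - 500, g.tss + 1000
        else:
            lo, hi = g.tss - 999, g.tss + 501
        footprint = 0.0
        for iv in enriched_by_gene.get(g.gene_id, []):
            delta = config.shift_bp if iv.strand == "+" else -config.shift_bp
            s, e = iv.start + delta, iv.end + delta
            footprint += max(0, min(e, hi) - max(s, lo))
        out[g.gene_id] = (bg_window + footprint) / genome_mean if genome_mean > 0 else 0.0
    return out
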