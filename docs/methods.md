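# Methods

## Coordinate conventions

All coordinates are 0-based, half-open `[start, end)` (BED convention)
throughout the library; GTF-lite input (1-based, inclusive) is converted at
the parsing boundary. The TSS of a minus-strand gene is the *last* base of
its interval (`end − 1`), mirroring UCSC `txEnd` semantics, and the TTS is
the opposite end. Reads are required to carry a strand; the optional BED6
name column doubles as a sequence tag used only for duplicate exclusion.

## Coverage model

The pileup follows the classical single-end ChIP-seq recipe. Each read is
translated `shift_bp` (default 50) base pairs **toward the fragment
center**: plus-strand reads move downstream, minus-strand reads upstream.
The phrase "shifted in the 5′ direction" that is sometimes used for this
correction is ambiguous — taken literally it would move the two strands'
reads *apart* — so the library implements center-ward shifting as the
default (it is what stacks the two strands' read populations onto the
fragment midpoint and produces the expected TSS peak) and exposes
`literal_5prime=True` for the literal reading. Reads are used at their
mapped length; a fixed fragment extension is available via `extend_to` but
off by default.

The raw track value at position *p* is the number of shifted reads covering
*p*. Normalization divides every value by the genome-average per-base count,
computed over **all** positions of all chromosomes including zero-coverage
bases, so the normalized track has global mean exactly 1 and a value of *f*
reads as *f*-fold over the genomic mean. An alternative normalization by
total mapped reads differs only by a constant factor and would leave every
fold-ratio and correlation in the package unchanged; the genome-average
convention was chosen because the downstream amplification criteria are
phrased as folds over genome averages. Re-normalizing a normalized track is
rejected rather than silently re-applied.

bedGraph output is run-length encoded at 6 decimal places with zero runs
omitted; reading rejects overlapping lines. Library metadata (total reads,
genome mean, normalized flag) rides in the track definition line so a
round-trip restores the full object.

## Meta-profiles

For an anchor set (TSSs, TTSs, CpG-island midpoints) and half-window *W*,
the profile value at offset *d* ∈ [−W, W) is the mean over anchors of the
track at `anchor + d` for plus-strand anchors and `anchor − d` for
minus-strand anchors, so positive offsets always point in the direction of
transcription. Windows that run past a chromosome edge contribute zeros at
the missing offsets rather than being excluded: the divisor stays the anchor
count at every offset, and the number of truncated windows is reported. The
profile is linear in the track by construction.

The CpG-island statistic is a two-sample *t*-test across islands of the
per-island mean normalized signal in a 500-bp window centered on the island
midpoint. Welch's unequal-variance form is the default (robust when the two
libraries have different dispersion); the pooled Student form is available
via `pooled=True`.

## Gain/loss classification

Peaks are counted per gene in three categories: **promoter** (strand-
oriented window around the TSS; the inclusive "distal" window of −5 kb/+1 kb
is the default, a "proximal" −250/+250 bp window is available), **exon**
(any exon; a peak spanning several exons of one gene counts once), and
**gene body** (the full gene interval). A ≥ 1 bp overlap counts; a stricter
fractional-overlap option exists. One peak may count for several categories
and several genes.

A gene is **gained** when all three categories are empty in the control and
at least one is non-empty in the case; **lost** in the mirror situation;
otherwise unchanged (present in both or absent in both). Category identity
is deliberately ignored — presence is pooled across the three categories —
because the definition is a presence/absence contrast, not a localization
contrast.

The Venn-style overlap summary counts sharing per peak (a control peak
overlapping two case peaks is one shared control peak), so the shared count
can differ between the sides; both are reported, with width statistics per
class. Whole-peak width summaries use mean and median.

The built-in caller is a deterministic threshold scanner — maximal runs of
normalized value ≥ `min_value` (default 4-fold), merged across gaps of at
most `merge_gap` (50 bp), kept if at least `min_width` (200 bp) wide. It is
**not** a model-based broad-peak caller and is provided so the pipeline is
testable end to end; real analyses should supply peaks from a dedicated
caller. The defaults were set by a run-length analysis of Poisson
background at the generator's default depth: sustained ≥ 4-fold runs of
200 bp essentially never arise from background, while simulated promoters
(≈ 10–20-fold over ≈ 400–600 bp) are always recovered.

## Amplification scan

Candidate regions are delimited by a sliding-window scan (200-bp windows,
100-bp step). A window passes when, on the normalized scale, (2) its mean is
≥ 5-fold the case genome mean, (3) its case sum is ≥ 5-fold its control
sum, and (4) its case mean, re-expressed on the control library's depth
scale, is ≥ 2-fold the control genome mean. Passing windows are merged,
bridging runs of failing windows up to `merge_gap` (250 bp) — without
bridging, sampling noise inside a genuine region fragments it, while
bridging cannot extend past a region boundary because flanking windows fail
the fold criteria by large margins. Each merged region is then **re-tested**
on its aggregate counts and kept only if it also satisfies the strict width
criterion (1), `width > 1000` bp ("more than 1 kb" read strictly). Criterion
(5), duplicate exclusion, applies upstream: reads are deduplicated by
(coordinates, strand, sequence) before the pileup, so identical molecules
(PCR duplicates) collapse while genuine co-mapping molecules with distinct
sequences survive.

Criterion (4) is interpreted as the *case* region count, depth-scaled to the
control library, versus the *control* genome average. The alternative
reading (control region count vs control average) would reject a genuine
amplification of a background region — whose control signal is, by
construction, at the control average — and is inconsistent with the
criteria forming a chain of case-signal requirements.

The p-value is the inclusive upper tail `P(X ≥ ⌈k⌉)` for X ~ Poisson(λ),
computed via the regularized lower incomplete gamma function (stable for
large k). Coverage sums are converted to approximate read counts by
dividing by the library's mean read footprint (total raw coverage / total
reads); λ is the control region's count scaled by the library-size ratio
(`--no-depth-scaling` disables the scaling), k is the case region's count.
The inclusive-tail and depth-scaling choices are documented conventions:
enrichment tests conventionally include the observed count, and an
unscaled control count conflates copy number with sequencing depth.

Genes overlapping any emitted region by ≥ 1 bp are listed as amplified with
the minimum p-value among their regions. The evidence report combines, per
marker gene, TSS-vicinity counts in both samples and their ratio (flagged
"reduced in case" when < 1 and "amplified" when in the amplified table),
the amplified-gene table and the CpG-window test; it states evidence, not a
diagnosis.

## Expression link

TSS-vicinity counts sum the normalized signal over the strand-oriented
−0.5 kb/+1 kb window around each TSS. Correlation with expression is
Pearson's r on log(1+x)-transformed values by default (both quantities are
heavy-tailed; the log makes a multiplicative coupling affine, and the raw
option is available); an intersection of at least 3 genes is required and
zero variance yields NaN with a warning. Two-gene-set comparison uses the
two-sided Wilcoxon rank-sum test by default (expression distributions are
skewed; Welch's t is available), reporting medians, means, the direction of
the difference, and the p-value.

The hand-rolled Welch, pooled-t and rank-sum statistics follow the
textbook closed forms (with `scipy.special` distribution functions) and are
verified in the test suite against `scipy.stats` to 10⁻⁸ or better; the
rank-sum uses midranks and the classical large-sample normal approximation
without tie or continuity correction.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every quantity of interest known exactly:

* **Genome** — default two chromosomes × 500 kb.
* **Genes** — default 60, placed non-overlapping with ≥ 10 kb spacing
  (sequential placement with randomized slack; infeasible configurations
  raise an error suggesting a larger genome), lengths 2–6 kb, 2–4 exons,
  random strands.
* **Background** — per strand, read 5′ starts uniform with Poisson counts at
  half the total depth (default 0.02 reads/bp overall, read length 36 bp
  → mean background coverage 0.72×).
* **Promoter enrichment** — per enriched gene, Poisson-many extra reads with
  mean `(level − 1) × depth × promoter_extent` (extent 1500 bp; level is the
  per-gene enrichment fold, drawn as 0.8–1.25 × the configured fold of 8).
  Fragment centers are Normal(TSS, 150 bp); each read's 5′ start sits 50 bp
  outward of its center so the default center-ward shift stacks reads on
  the center. A fraction of genes (default 10% each) is enriched only in
  the case (gained) or only in the control (lost); the rest in both.
* **Amplification** — one region (default 2 kb) in which every case read
  whose 5′ start falls inside is duplicated ⌊fold⌋−1 times (default fold 6)
  with **distinct** sequence tags — genuine extra molecules, distinguishable
  from PCR duplicates, which can be injected separately with identical tags
  via `pcr_duplicate_frac`. By default the region is auto-placed in the gap
  reserved during gene placement, clear of all promoter windows; explicit
  coordinates are validated against gene conflicts.
* **Expression** — `slope × true_signal + Normal(0, σ)`, floored at zero,
  where the true signal is the gene's noise-free TSS-vicinity value: the
  expected background footprint plus the realized footprint of that gene's
  enriched reads in the window, on the case library's normalized scale.
  Coupling to the case sample reflects that expression is measured in the
  condition under study.

A single `numpy` generator seeded once drives all draws; identical
configurations produce byte-identical output files (gzip members are
written with a fixed mtime).

What the generator does **not** emulate: mappability and sequence
composition biases, fragment-length variation, chromatin-input background
structure, inter-replicate variability, and realistic gene architecture.
Passing recovery tests on this fixture therefore demonstrates the
correctness of the analysis logic under its stated model, not performance
on real libraries.

## Operating points of the recovery tests

Two fixture configurations are used deliberately:

* **Gain/loss recovery** runs on the default configuration; at default depth
  the weakest simulated promoter still peaks ≈ 8-fold over the genome mean
  across ≥ 300 bp, far above the caller's operating point, while background
  cannot sustain 4-fold runs of 200 bp, so exact recovery of the implanted
  sets is the expected outcome, not luck.
* **Amplification recovery** runs on a gene-free uniform background
  (1 × 250 kb, depth 0.8 reads/bp). The fold-6 implant must clear ≥ 5-fold
  criteria, leaving a relative margin of only ~15%; the region's count noise
  is `1/√n` for `n` background reads in 2 kb, so the default depth (n ≈ 40,
  16% noise) leaves recovery near chance for *any* correct implementation,
  whereas the deep fixture (n ≈ 1600, 2.5% aggregate noise, ~8% per window)
  gives a ~4σ aggregate margin. The default-configuration fixture is
  therefore a valid study of gain/loss but an underpowered one of
  amplification; the width-exclusion check (an 800-bp implant is never
  reported) uses the same deep fixture.

## Numerical choices and degenerate inputs

* Poisson tail: λ = 0 is a point mass (tail 1 at k = 0, else 0); k = 0
  returns 1; non-integer k is rounded up.
* Welch/pooled t with two identical constant samples returns t = 0, p = 1
  (no evidence of difference) instead of 0/0.
* Fold vs control with a zero control count is +∞, which passes the
  threshold iff the case count is positive.
* Region counts over intervals clipped to nothing are 0; empty anchor sets,
  empty libraries, < 2 islands, and < 3-gene intersections raise errors.
* Peaks and regions inherit interval validation (0 ≤ start < end) from the
  shared coordinate type; readers reject malformed lines with the line
  number.

## Pipeline determinism

`histodiff run` executes simulate → pileup → profiles → diff-peaks →
amplify → report under one YAML configuration. The manifest stores, per
stage, the parameters and SHA-256 hashes of inputs and outputs using
outdir-relative paths and no timestamps, so identical runs are byte-
identical; a rerun skips ("cached") any stage whose parameters, inputs and
recorded outputs are unchanged. Run/cached statuses are reported to the
log, not stored in the manifest, since they describe the run rather than
the result.

## Known limitations

* The stand-in caller has no local background model; broad domains over
  elevated background are better handled by a dedicated caller whose output
  the package accepts as BED/broadPeak.
* The amplification scan targets focal, contiguous amplifications; it is not
  a genome-wide CNV segmentation and inherits the mark's restriction to
  marked loci.
* Read-count estimation from coverage assumes a roughly uniform read length
  within a library.
* The Poisson score treats reads as independent; duplicated molecules from
  genuine amplification violate this mildly, making the p-value an
  optimistic ranking score rather than a calibrated probability.
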