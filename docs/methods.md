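# Methods

## The measurement problem

In female human embryonic stem cells, the naive (pre-implantation-like)
state carries two active X chromosomes, one of which is coated by XIST
RNA and transcriptionally *dampened* rather than silenced. Quantifying
dampening requires distinguishing the two X haplotypes without trios or
hybrid lines: primed cells of the same line have one stably inactive X,
so SNPs expressed monoallelically in primed cells reveal which allele
sits on the previously active X (pXa). `xdamp` packages that logic and
the downstream statistics; a synthetic generator supplies every input
with planted truth so each stage is validated by parameter recovery.

## Generative model

**Genome.** Two chromosomes (a 150-Mb "chrX" and an equally sized
autosomal control, "chr7"), non-overlapping 20-kb genes placed on an
evenly slotted grid with seeded jitter, and a fixed number of exonic
SNPs per gene (2 by default; 4 in the classification presets, see
below). Coordinates are 0-based half-open internally; emitted VCF, GTF
and pileup are 1-based, bedGraph 0-based half-open.

**Variant records.** True heterozygous sites carry quality U(60, 220),
negative-binomial depth (mean 60, dispersion 10, floored at 20) and
binomial allele depths conditioned on a minor fraction ≥ 0.25, so a
fully heterozygous panel passes the downstream filter by construction.
Decoy records, when requested, violate exactly one of quality / depth /
allelic ratio, making the filter's selectivity testable.

**Allelic counts.** Each gene has a true pXi read fraction *p* per
condition; per-SNP RNA depth is negative-binomial (mean 150, dispersion
10 — the simplest overdispersed coverage model) and the pXi read count
is Binomial(depth, p). The SNP phase (whether ref or alt is the pXa
allele) is drawn once per genome from a master-seed-keyed stream and
shared by all presets, as the haplotypes of a cell line are. Counts are
emitted as mpileup-dialect text (no indel or read start/end marks) with
a deterministic forward/reverse case split, so outputs are
byte-identical for a fixed seed.

**Expression.** Per-gene total dose is pXa + pXi: autosomal genes are
diploid (dose 2), an X gene with pXi fraction *p* has dose
1 + d, d = p/(1−p). Base means are log-normal (ln-mean ln 100, σ = 1),
drawn from a genome-level stream shared across conditions so that
condition fold changes are paired; counts are Poisson around
base × dose × log-normal noise (σ = 0.2) × a per-sample library factor.
Expression level and allelic skew are independent across genes, so
aggregate-ratio recovery stays interpretable.

**Coverage and masks.** Enrichment domains (exponential lengths, uniform
folds over a flat control) with the exact merged-interval union kept as
truth; FISH masks are either a solid digital ball or single-voxel
speckles on a shell of stated radius.

**Seeding.** One master seed; each generator draws from a named child
stream (`SeedSequence(master, spawn_key=(stream, *subkeys))` with a
frozen stream table), so adding a generator never perturbs existing
streams.

## Preset catalog and calibration

Preset parameters are calibration choices that make the pipeline's
*recovered* statistics match the study conditions; the depth
distribution of real SNP coverage is not a claim, only a plausible
overdispersed model.

| preset | X SNP-genes | class mixture (true p) |
|---|---|---|
| `primed_v1` | 150 | 88 % silenced p = 0.04, 12 % escapees p = 0.30 |
| `naive_pxgl_wt_v1` | 150 | 78 % sensitive p ~ Beta(mean 0.31, sd 0.05), 22 % resistant p = 0.5 |
| `naive_ko_v1` | 150 | all p = 0.5 |
| `naive_naivecult_v1` | 150 | 87 % p ~ U(0.30, 0.50), 13 % p = 0.03 |
| `classification_v1` | 60 (4 SNPs/gene) | 47 sensitive (0.31 → 0.5 in both perturbation pairs), 13 resistant (0.5 throughout); primed reference at p = 0.04 |
| `spen_kd_v1` | 54 (4 SNPs/gene) | 41 sensitive at 0.31 in scramble: 20 rise to 0.45 in both mixes, 12 in one, 9 in neither; 13 resistant at 0.5 |

Two calibration points deserve note:

- The primed silenced class sits at p = 0.04, not at ~0: the chromosome
  ratio the pipeline reports is computed over haplotype-mapped SNPs,
  and the haplotype deliberately excludes biallelic (escapee-like)
  SNPs, so the mapped-SNP ratio measures the leaky basal expression of
  silenced genes. A chromosome-wide ratio of ~0.04 in primed cells
  therefore requires a silenced-class p of ~0.04.
- The classification presets use 4 SNPs per gene. Per-gene pooled reads
  (~4 × 150 × 3 replicates) put the binomial sampling error of a
  ratio fold change near 0.05, which keeps the probability of recovering
  the planted 47/13 and 32/41 partitions exactly above 99 % per run.

Class labels are allocated over the genome's X genes by largest
remainder (planted counts are exact, not Bernoulli) and shuffled with a
preset-keyed stream.

## Pipeline conventions

- **SNP filter**: quality ≥ 50, depth ≥ 10, minor-allele fraction
  ≥ 0.25, all inclusive ("minimum" read as ≥). The allelic-ratio
  threshold applies to the *minor* allele — a symmetric definition of
  heterozygosity. Multi-allelic records and indels are excluded; zero
  allele-depth records are skipped with a warning.
- **Biallelic call**: minor allele ≥ 25 % of ref+alt RNA reads,
  inclusive; SNPs under 10 informative RNA reads are *undetected* and
  excluded from the percent-biallelic denominator (the detection floor
  mirrors the DNA depth threshold; real pipelines rarely call allelic
  state below ~10 reads).
- **Haplotype**: monoallelic = minor fraction < 0.25 at ≥ 10 reads.
  The orchestrated pipeline pools primed replicates per SNP before the
  call (one haplotype from the combined primed evidence); for separate
  per-replicate inputs, `build_xa_haplotype` resolves conflicts by
  majority vote and drops ties. Pooling matters: with overdispersed
  depth, per-replicate calls let low-depth escapee replicates slip into
  the map and bias the primed ratio upward.
- **Chromosome-level ratio** is read-weighted (ratio of summed counts
  over mapped SNPs), not a mean of gene ratios.
- **Bases matching neither allele** at a SNP are tallied separately and
  excluded from ratios (sequencing-error tolerance).
- **X:A** uses the median over detected genes (count > 0; both choices
  configurable) of CPM values; the statistic is invariant to library
  rescaling. On a finite synthetic genome the X and autosomal median
  genes are different random draws, so single-condition X:A carries a
  gene-sampling factor that cancels in condition folds — all reported
  dosage statistics are folds or paired ratios. The dosage stage uses
  800 X / 1600 autosomal genes (the human X carries ~800 protein-coding
  genes, and median sampling error scales as 1/√n), independent of the
  150-gene SNP panels.
- **Classification**: FC is the plain quotient of ratios
  (perturbed/reference), strict > 1.2 in *every* pair for sensitivity;
  analyzed-but-not-sensitive genes are resistant; genes with undefined
  ratios (including zero reference) are not analyzed.
- **Occupancy**: bin value = length-weighted mean over the bin,
  uncovered bases contribute 0; enrichment adds a 0.01 pseudocount to
  both tracks; occupancy thresholds are inclusive and applied on the
  10-kb grid for both assay styles (the RAP-style analysis states a
  threshold but no bin size).
- **Pausing ratio**: median coverage over [TSS, TSS+300) divided by
  median over [TSS+300, TES), strand-aware; genes shorter than 1 kb are
  excluded and a zero body median is flagged undefined. The window
  sizes are implementation choices (the source analysis names only
  "TSS" and "gene body") and are configurable.
- **Dispersion score**: signal centroid as sphere centre; radius = the
  maximal centroid-to-voxel-centre distance; score = sphere volume /
  (voxel count × voxel volume); a single voxel scores 1 by definition.
  No half-voxel padding is added to the radius — padding would push a
  solid digital ball to ~1.3 instead of ~1, defeating the score's
  calibration (compact ≈ 1). The cost is that 2–3-voxel clusters can
  score below 1; the score is meaningful for signals larger than a few
  voxels. Invariant to rigid translation and uniform voxel rescaling.

## What the synthetic data does and does not show

The generator reproduces allelic sampling noise, overdispersed depth,
expression dispersion and enrichment-domain structure. It does **not**
model reference-mapping bias toward the ref allele, sequencing error
beyond an "other base" tally, correlated SNPs within reads, gene-length
effects, escapee clustering along the chromosome, or the empirical
correlation between expression level and XIST resistance (reproducible
via an optional preset flag but off by default). Passing recovery tests
therefore validates the statistical machinery and its thresholds, not
robustness to alignment artefacts.

## Problem sizes and runtime

Default panels (150 SNP-genes × 2 SNPs × 3 replicates; 100-reseed
reliability loops for the classification presets; 800-gene dosage
genomes) were chosen so the full test suite and the acceptance script
each run in well under a minute of single-core time while keeping every
recovered statistic inside its stated tolerance with comfortable
sampling margin.

## Known limitations

- The haplotype is SNP-wise; no chromosome-scale phasing is attempted,
  so a SNP with a wrong primed call would flip its contribution
  (swap symmetry r ↔ 1−r is exact and tested).
- Percent biallelism pools replicates before calling; with very few
  reads per replicate the pooled call is more liberal than a
  per-replicate consensus would be.
- bedGraph is the coverage contract; bigWig I/O is intentionally out of
  scope, as are peak calling, read alignment and variant calling.
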