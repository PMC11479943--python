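"""Synthetic data generation for the X-dampening quantification pipeline.

Every input the pipeline consumes can be generated here with planted ground
truth: a genome model (chromosomes, genes, exonic SNPs), genomic variant
records (minimal VCF), RNA pileups at heterozygous SNPs under named allelic
presets, gene x sample expression count matrices, enrichment-domain coverage
tracks with a flat control, and 3D voxel masks for RNA FISH signals.

The generative model for allelic expression is deliberately simple: each
gene carries a true pXi read fraction ``p`` (the probability that an RNA
read overlapping one of its SNPs derives from the previously inactive X
haplotype), per-SNP sequencing depth is negative-binomial, and the pXi read
count at a SNP is binomial given depth and ``p``.  Dampening presets differ
only in how ``p`` is distributed across gene classes.

All randomness flows from a single master seed through named child streams
(see :func:`child_rng`), so adding a generator never perturbs existing
streams and identical ``(inputs, seed)`` give byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .metrics import VoxelMask

__all__ = [
    "GenomeModel",
    "AllelicPreset",
    "AllelicDataset",
    "DomainSpec",
    "PRESETS",
    "get_preset",
    "child_rng",
    "build_genome",
    "simulate_variant_records",
    "write_vcf",
    "write_gtf",
    "simulate_allelic_dataset",
    "write_pileup",
    "sample_gene_ps",
    "simulate_expression_matrix",
    "simulate_coverage",
    "simulate_fish_mask",
    "write_voxel_mask",
    "read_voxel_mask",
]

_BASES = np.array(list("ACGT"))

# Fixed stream indices of the master-seed derivation scheme.  New generators
# must append, never renumber.
_STREAMS = {
    "genome": 0,
    "variants": 1,
    "allelic": 2,
    "expression": 3,
    "coverage": 4,
    "fish": 5,
}


def _crc(name: str) -> int:
    """Stable 32-bit key for a string, used as a SeedSequence spawn key."""
    return zlib.crc32(name.encode())


def child_rng(master_seed: int, stream: str, *subkeys: int) -> np.random.Generator:
    """Derive an independent child generator from the master seed.

    The child is identified by a named stream plus optional integer subkeys
    (for example a preset name hash, a condition index and a replicate
    index), implemented as a ``SeedSequence`` spawn key.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(_STREAMS[stream], *subkeys)
    )
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------


class GenomeSizingError(ValueError):
    """Raised when the requested genes cannot be placed on a chromosome."""


@dataclass
class GenomeModel:
    """Chromosomes, gene models and exon-resident SNP positions.

    ``genes`` columns: gene_id, chrom, start, end (0-based half-open),
    strand.  ``snps`` columns: chrom, pos (1-based), ref, alt, gene_id.
    """

    chromosomes: dict[str, int]
    genes: pd.DataFrame
    snps: pd.DataFrame
    x_chrom: str = "chrX"

    def __post_init__(self) -> None:
        if not any(c != self.x_chrom for c in self.chromosomes):
            raise ValueError("at least one autosomal chromosome is required")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        for _, g in self.genes.iterrows():
            if not (0 <= g.start < g.end <= self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
        merged = self.snps.merge(self.genes, on="gene_id", suffixes=("", "_g"))
        inside = (merged["pos"] - 1 >= merged["start"]) & (merged["pos"] - 1 < merged["end"])
        if not inside.all():
            raise ValueError("every SNP must lie within its gene interval")

    @property
    def x_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == self.x_chrom]

    def gene_chromosomes(self) -> pd.Series:
        return self.genes.set_index("gene_id")["chrom"]


def _place_genes(
    rng: np.random.Generator, chrom: str, length: int, n: int, gene_length: int, prefix: str
) -> pd.DataFrame:
    slot = length // n if n else 0
    if slot <= gene_length:  # genes must fit with intergenic space to spare
        raise GenomeSizingError(
            f"cannot place {n} genes of {gene_length} bp on {chrom} ({length} bp)"
        )
    starts = np.arange(n) * slot + rng.integers(0, slot - gene_length + 1, size=n)
    return pd.DataFrame(
        {
            "gene_id": [f"{prefix}{i:04d}" for i in range(n)],
            "chrom": chrom,
            "start": starts,
            "end": starts + gene_length,
            "strand": rng.choice(["+", "-"], size=n),
        }
    )


def build_genome(
    n_x_genes: int,
    n_autosomal_genes: int,
    x_length: float = 1.5e8,
    autosome_length: float = 1.5e8,
    snps_per_gene: int = 2,
    seed: int = 0,
    gene_length: int = 20_000,
    x_chrom: str = "chrX",
    autosome: str = "chr7",
) -> GenomeModel:
    """Build a two-chromosome genome with non-overlapping genes and SNPs.

    X-linked genes live on ``x_chrom``; autosomal control genes on a
    chr7-like chromosome.  Each gene carries ``snps_per_gene`` exonic SNPs
    at distinct positions.  Deterministic for a fixed seed.
    """
    if min(n_x_genes, n_autosomal_genes, snps_per_gene) <= 0:
        raise ValueError("gene and SNP counts must be positive")
    rng = child_rng(seed, "genome")
    genes = pd.concat(
        [
            _place_genes(rng, x_chrom, int(x_length), n_x_genes, gene_length, "XG"),
            _place_genes(rng, autosome, int(autosome_length), n_autosomal_genes, gene_length, "AG"),
        ],
        ignore_index=True,
    )
    rows = []
    for _, g in genes.iterrows():
        offs = rng.choice(g.end - g.start, size=snps_per_gene, replace=False)
        for off in np.sort(offs):
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((g.chrom, int(g.start + off + 1), _BASES[ref], _BASES[alt], g.gene_id))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene_id"])
    snps = snps.sort_values(["chrom", "pos"], ignore_index=True)
    return GenomeModel(
        chromosomes={x_chrom: int(x_length), autosome: int(autosome_length)},
        genes=genes,
        snps=snps,
        x_chrom=x_chrom,
    )


def write_gtf(genome: GenomeModel, path: str | Path) -> None:
    """Write gene lines (only) of the genome model as GTF (1-based, closed)."""
    with open(path, "w") as fh:
        for _, g in genome.genes.iterrows():
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\txdamp\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Genomic variant records (minimal VCF)
# ---------------------------------------------------------------------------


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial depths with the given mean and dispersion r."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_variant_records(
    genome: GenomeModel,
    het_fraction: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
    depth_mean: float = 60.0,
    depth_dispersion: float = 10.0,
) -> pd.DataFrame:
    """Simulate genomic variant records at the genome's SNP positions.

    True heterozygous sites (a ``het_fraction`` share of SNPs) are emitted
    filter-passing by construction: quality >= 50, depth >= 20 and a
    balanced allele-depth draw conditioned on minor fraction >= 0.25.  The
    remaining sites are near-homozygous and fail the allelic-ratio rule.
    ``noise`` adds that fraction of decoy records, each violating exactly
    one of {quality, depth, allelic ratio}, cycling through the three
    kinds.  The returned frame keeps a ``truth`` label per record.
    """
    if not 0 <= het_fraction <= 1:
        raise ValueError("het_fraction must be in [0, 1]")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = child_rng(seed, "variants")
    snps = genome.snps.reset_index(drop=True)
    n = len(snps)
    is_het = rng.random(n) < het_fraction
    depth = np.maximum(_nb_depth(rng, depth_mean, depth_dispersion, n), 20)
    qual = rng.uniform(60, 220, size=n)
    ad_ref = rng.binomial(depth, 0.5)
    # condition true hets on passing the downstream minor-fraction rule
    for _ in range(100):
        minor = np.minimum(ad_ref, depth - ad_ref) / depth
        bad = is_het & (minor < 0.25)
        if not bad.any():
            break
        ad_ref[bad] = rng.binomial(depth[bad], 0.5)
    hom_alt = rng.binomial(depth, 0.02)
    ad_ref = np.where(is_het, ad_ref, depth - hom_alt)
    df = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "ref": snps["ref"],
            "alt": snps["alt"],
            "qual": np.round(qual, 1),
            "depth": depth,
            "ad_ref": ad_ref,
            "ad_alt": depth - ad_ref,
            "truth": np.where(is_het, "het", "hom"),
        }
    )
    n_decoys = int(round(noise * n))
    if n_decoys:
        kinds = ["decoy_qual", "decoy_depth", "decoy_ratio"]
        pick = rng.choice(n, size=n_decoys, replace=n_decoys > n)
        rows = []
        for j, i in enumerate(pick):
            kind = kinds[j % 3]
            d = int(max(_nb_depth(rng, depth_mean, depth_dispersion, 1)[0], 20))
            q = float(np.round(rng.uniform(60, 220), 1))
            a = int(rng.binomial(d, 0.5))
            a = int(np.clip(a, int(np.ceil(0.25 * d)), d - int(np.ceil(0.25 * d))))
            if kind == "decoy_qual":
                q = float(np.round(rng.uniform(5, 49.9), 1))
            elif kind == "decoy_depth":
                d = int(rng.integers(2, 10))
                a = max(1, d // 2)
            else:  # ratio decoy: minor fraction in (0, 0.25)
                a = int(np.floor(0.25 * d)) - 1 if np.floor(0.25 * d) >= 1 else 0
                a = max(a, 0)
            base = snps.iloc[i]
            rows.append(
                (base.chrom, int(base.pos) + 1, base.ref, base.alt, q, d, d - a, a, kind)
            )
        df = pd.concat([df, pd.DataFrame(rows, columns=df.columns)], ignore_index=True)
        df = df.sort_values(["chrom", "pos"], ignore_index=True)
    return df


def write_vcf(records: pd.DataFrame, genome: GenomeModel, path: str | Path) -> None:
    """Write variant records as a minimal, header-complete VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in records.itertuples():
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:g}\t.\t.\t"
                f"GT:DP:AD\t0/1:{r.depth}:{r.ad_ref},{r.ad_alt}\n"
            )


# ---------------------------------------------------------------------------
# Allelic presets and RNA pileup simulation
# ---------------------------------------------------------------------------

#: p specification: a constant, ("beta", mean, sd) or ("uniform", lo, hi)
PSpec = float | tuple


@dataclass(frozen=True)
class AllelicPreset:
    """Named study condition set with per-gene-class true pXi fractions.

    ``classes`` gives the gene-class mixture over X SNP-genes as exact
    fractions (allocated by largest remainder, so planted counts are
    reproducible).  ``conditions`` maps each condition name to the p
    specification per class.  Autosomal genes are balanced (p = 0.5) in
    every condition.
    """

    name: str
    n_x_genes: int
    snps_per_gene: int
    classes: tuple[tuple[str, float], ...]
    conditions: Mapping[str, Mapping[str, PSpec]]
    depth_mean: float = 150.0
    depth_dispersion: float = 10.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions of preset {self.name} must sum to 1")
        if self.depth_mean <= 0:
            raise ValueError("depth mean must be positive")

    def class_counts(self, n_genes: int | None = None) -> dict[str, int]:
        """Exact per-class gene counts by largest-remainder allocation."""
        n = self.n_x_genes if n_genes is None else n_genes
        raw = {c: f * n for c, f in self.classes}
        counts = {c: int(np.floor(v)) for c, v in raw.items()}
        short = n - sum(counts.values())
        for c in sorted(raw, key=lambda c: raw[c] - np.floor(raw[c]), reverse=True)[:short]:
            counts[c] += 1
        return counts


PRESETS: dict[str, AllelicPreset] = {}


def _register(p: AllelicPreset) -> AllelicPreset:
    PRESETS[p.name] = p
    return p


# Primed cells: one X inactive.  Silenced genes keep a leaky basal p of 0.04
# from the inactive X (this is what the chromosome-wide ratio of mapped,
# monoallelically-called SNPs measures); 12% escapees express biallelically.
_register(
    AllelicPreset(
        name="primed_v1",
        n_x_genes=150,
        snps_per_gene=2,
        classes=(("silenced", 0.88), ("escapee", 0.12)),
        conditions={"primed": {"silenced": 0.04, "escapee": 0.30}},
    )
)

# Naive PXGL wild type: XIST dampens most genes to p ~ 0.31; 22% resist.
_register(
    AllelicPreset(
        name="naive_pxgl_wt_v1",
        n_x_genes=150,
        snps_per_gene=2,
        classes=(("sensitive", 0.78), ("resistant", 0.22)),
        conditions={"naive_wt": {"sensitive": ("beta", 0.31, 0.05), "resistant": 0.5}},
    )
)

# Naive XIST knockout: dampening lost, both X fully balanced.
_register(
    AllelicPreset(
        name="naive_ko_v1",
        n_x_genes=150,
        snps_per_gene=2,
        classes=(("sensitive", 0.78), ("resistant", 0.22)),
        conditions={"naive_ko": {"sensitive": 0.5, "resistant": 0.5}},
    )
)

# Naive cells in NaiveCult medium: 87% of SNP-genes broadly biallelic.
_register(
    AllelicPreset(
        name="naive_naivecult_v1",
        n_x_genes=150,
        snps_per_gene=2,
        classes=(("biallelic", 0.87), ("skewed", 0.13)),
        conditions={"naive_naivecult": {"biallelic": ("uniform", 0.30, 0.50), "skewed": 0.03}},
    )
)

# Two independent perturbation pairs (KO vs WT, Dox vs UT) over 60 analyzed
# genes with the planted 47 sensitive / 13 resistant split; a primed
# reference condition supplies the Xa haplotype.
_register(
    AllelicPreset(
        name="classification_v1",
        n_x_genes=60,
        snps_per_gene=4,
        classes=(("sensitive", 47 / 60), ("resistant", 13 / 60)),
        conditions={
            "primed_ref": {"sensitive": 0.04, "resistant": 0.04},
            "wt": {"sensitive": 0.31, "resistant": 0.5},
            "ko": {"sensitive": 0.5, "resistant": 0.5},
            "ut": {"sensitive": 0.31, "resistant": 0.5},
            "dox": {"sensitive": 0.5, "resistant": 0.5},
        },
    )
)

# SPEN knockdown: of 41 detected XIST-sensitive genes, 20 lose dampening in
# both siRNA mixes, 12 in exactly one, 9 in neither; 13 resistant genes stay
# balanced throughout.
_register(
    AllelicPreset(
        name="spen_kd_v1",
        n_x_genes=54,
        snps_per_gene=4,
        classes=(
            ("sens_both", 20 / 54),
            ("sens_one", 12 / 54),
            ("sens_none", 9 / 54),
            ("resistant", 13 / 54),
        ),
        conditions={
            "primed_ref": {"sens_both": 0.04, "sens_one": 0.04, "sens_none": 0.04, "resistant": 0.04},
            "scramble": {"sens_both": 0.31, "sens_one": 0.31, "sens_none": 0.31, "resistant": 0.5},
            "mix1": {"sens_both": 0.45, "sens_one": 0.45, "sens_none": 0.31, "resistant": 0.5},
            "mix2": {"sens_both": 0.45, "sens_one": 0.31, "sens_none": 0.31, "resistant": 0.5},
        },
    )
)


class UnknownPresetError(KeyError):
    pass


def get_preset(name: str) -> AllelicPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def _assign_classes(genome: GenomeModel, preset: AllelicPreset, seed: int) -> pd.Series:
    """Assign gene classes to the genome's X genes (seeded shuffle).

    The preset's class fractions are allocated over however many X genes
    the genome carries (exact largest-remainder counts); autosomal genes
    are labelled ``autosomal``.  Class assignment is keyed by the preset name, so different presets draw independent assignments
    on the same genome while a given preset is reproducible.
    """
    xg = genome.x_genes["gene_id"]
    rng = child_rng(seed, "allelic", _crc(preset.name), 0)
    labels: list[str] = []
    for cls, cnt in preset.class_counts(len(xg)).items():
        labels += [cls] * cnt
    labels_arr = np.array(labels)
    rng.shuffle(labels_arr)
    out = pd.Series("autosomal", index=genome.genes["gene_id"], name="class_label")
    out.loc[xg] = labels_arr
    return out


def _sample_p(rng: np.random.Generator, spec: PSpec, size: int) -> np.ndarray:
    if isinstance(spec, (int, float)):
        return np.full(size, float(spec))
    kind = spec[0]
    if kind == "beta":
        _, mean, sd = spec
        v = sd**2
        nu = mean * (1 - mean) / v - 1
        a, b = mean * nu, (1 - mean) * nu
        return np.clip(rng.beta(a, b, size=size), 0.0, 1.0)
    if kind == "uniform":
        _, lo, hi = spec
        return rng.uniform(lo, hi, size=size)
    raise ValueError(f"unknown p specification {spec!r}")


def sample_gene_ps(
    genome: GenomeModel, preset: AllelicPreset, seed: int
) -> pd.DataFrame:
    """Ground-truth table: per gene, its class and true p in each condition."""
    classes = _assign_classes(genome, preset, seed)
    truth = pd.DataFrame({"gene_id": classes.index, "class_label": classes.values})
    for ci, (cond, class_ps) in enumerate(preset.conditions.items()):
        rng = child_rng(seed, "allelic", _crc(preset.name), 1 + ci)
        p = np.full(len(truth), 0.5)  # autosomal balance
        for cls, spec in class_ps.items():
            m = truth["class_label"].to_numpy() == cls
            p[m] = _sample_p(rng, spec, int(m.sum()))
        truth[f"p_{cond}"] = p
    return truth


@dataclass
class AllelicDataset:
    """Simulated allelic counts with full ground truth.

    ``counts`` columns: chrom, pos, gene_id, condition, replicate, sample,
    depth, pxi_count, ref_count, alt_count.  ``phase`` records which allele
    (ref/alt) is the pXa haplotype at each SNP; ``truth`` holds per-gene
    class labels and true p per condition.
    """

    preset: AllelicPreset
    counts: pd.DataFrame
    phase: pd.DataFrame
    truth: pd.DataFrame

    def sample_names(self, condition: str | None = None) -> list[str]:
        s = self.counts
        if condition is not None:
            s = s[s["condition"] == condition]
        return sorted(s["sample"].unique())


def simulate_allelic_dataset(
    genome: GenomeModel, preset: AllelicPreset | str, seed: int = 0
) -> AllelicDataset:
    """Simulate per-SNP allelic RNA counts for every preset condition.

    The SNP phase (which allele sits on the pXa haplotype) is drawn from a
    genome-level stream keyed only by the master seed, so all presets
    generated with the same seed on the same genome share one phase — as
    the two haplotypes of a cell line do.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    truth = sample_gene_ps(genome, preset, seed)
    snps = genome.snps.reset_index(drop=True)
    phase_rng = child_rng(seed, "allelic", _crc("phase"))
    xa_is_ref = phase_rng.random(len(snps)) < 0.5
    phase = snps[["chrom", "pos", "gene_id"]].copy()
    phase["xa_allele"] = np.where(xa_is_ref, "ref", "alt")

    p_by_gene = truth.set_index("gene_id")
    frames = []
    for ci, cond in enumerate(preset.conditions):
        p_snp = p_by_gene.loc[snps["gene_id"], f"p_{cond}"].to_numpy()
        for rep in range(preset.n_replicates):
            rng = child_rng(seed, "allelic", _crc(preset.name), 100 + ci, rep)
            depth = _nb_depth(rng, preset.depth_mean, preset.depth_dispersion, len(snps))
            pxi = rng.binomial(depth, p_snp)
            pxa = depth - pxi
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": snps["chrom"],
                        "pos": snps["pos"],
                        "gene_id": snps["gene_id"],
                        "condition": cond,
                        "replicate": rep + 1,
                        "sample": f"{cond}_rep{rep + 1}",
                        "depth": depth,
                        "pxi_count": pxi,
                        "ref_count": np.where(xa_is_ref, pxa, pxi),
                        "alt_count": np.where(xa_is_ref, pxi, pxa),
                    }
                )
            )
    return AllelicDataset(
        preset=preset, counts=pd.concat(frames, ignore_index=True), phase=phase, truth=truth
    )


def write_pileup(
    dataset: AllelicDataset, genome: GenomeModel, sample: str, path: str | Path
) -> None:
    """Emit one sample's counts as samtools-mpileup dialect text.

    The dialect matches pileups produced with indel sequences and read
    start/end marks disabled: the base column holds only ``.``/``,`` for
    reference bases and the alt base in upper/lower case.  Forward/reverse
    split is deterministic (ceil/floor halves), so output is byte-identical
    for a fixed dataset.
    """
    sub = dataset.counts[dataset.counts["sample"] == sample]
    if sub.empty:
        raise ValueError(f"sample {sample!r} not present in dataset")
    sub = sub.merge(genome.snps, on=["chrom", "pos", "gene_id"]).sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        for r in sub.itertuples():
            bases = (
                "." * ((r.ref_count + 1) // 2)
                + "," * (r.ref_count // 2)
                + r.alt.upper() * ((r.alt_count + 1) // 2)
                + r.alt.lower() * (r.alt_count // 2)
            )
            quals = "I" * int(r.depth)
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{int(r.depth)}\t{bases}\t{quals}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def simulate_expression_matrix(
    genome: GenomeModel,
    preset: AllelicPreset | str,
    seed: int = 0,
    condition: str | None = None,
    n_replicates: int | None = None,
    log_mean: float = np.log(100.0),
    log_sigma: float = 1.0,
    noise_sigma: float = 0.2,
) -> pd.DataFrame:
    """Simulate a gene x sample count table under the dose model.

    Per-gene expression is (pXa dose + pXi dose): autosomal genes are
    diploid and undampened (dose 2); an X gene with true pXi fraction p has
    pXi dose d = p/(1-p) relative to the unit pXa dose, so its total dose
    is 1 + d.  Gene base means are log-normal and drawn from a genome-level
    stream shared across presets (the genes are the same genes), so
    condition-to-condition dose comparisons are paired.  Counts are Poisson
    around mean x dose x multiplicative log-normal noise.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if condition is None:
        condition = next(iter(preset.conditions))
    if condition not in preset.conditions:
        raise ValueError(f"condition {condition!r} not in preset {preset.name}")
    if n_replicates is None:
        n_replicates = preset.n_replicates
    truth = sample_gene_ps(genome, preset, seed)
    p = truth[f"p_{condition}"].to_numpy()
    is_x = genome.genes["chrom"].to_numpy() == genome.x_chrom
    with np.errstate(divide="ignore"):
        d = p / (1.0 - p)
    dose = np.where(is_x, 1.0 + d, 2.0)

    base_rng = child_rng(seed, "expression", 0)
    base = base_rng.lognormal(log_mean, log_sigma, size=len(truth))
    cols = {}
    ci = list(preset.conditions).index(condition)
    for rep in range(n_replicates):
        rng = child_rng(seed, "expression", _crc(preset.name), 1 + ci, rep)
        noise = rng.lognormal(0.0, noise_sigma, size=len(truth))
        lib = rng.uniform(0.7, 1.3)
        cols[f"{condition}_rep{rep + 1}"] = rng.poisson(base * dose * noise * lib)
    return pd.DataFrame(cols, index=pd.Index(truth["gene_id"], name="gene_id"))


# ---------------------------------------------------------------------------
# Coverage tracks with planted enrichment domains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainSpec:
    """Planted enrichment-domain structure for one chromosome."""

    n_domains: int = 10
    length_mean: float = 2e6
    fold_range: tuple[float, float] = (2.0, 8.0)
    background: float = 1.0
    control_level: float = 1.0
    chromosome: str = "chrX"

    def __post_init__(self) -> None:
        if self.length_mean <= 0 or self.background < 0 or self.control_level <= 0:
            raise ValueError("domain lengths and levels must be positive")
        if min(self.fold_range) < 0:
            raise ValueError("enrichment folds must be >= 0")


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def simulate_coverage(
    genome: GenomeModel, spec: DomainSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate target and control bedGraph tracks with planted domains.

    Returns (target, control, truth): bedGraph-style frames with columns
    chrom/start/end/value (0-based half-open) and a truth dict holding the
    merged domain intervals and their union length per chromosome.
    """
    rng = child_rng(seed, "coverage")
    L = genome.chromosomes[spec.chromosome]
    domains: list[tuple[int, int]] = []
    for _ in range(spec.n_domains):
        length = int(min(max(rng.exponential(spec.length_mean), 10_000), L))
        start = int(rng.integers(0, L - length + 1))
        domains.append((start, start + length))
    merged = _merge_intervals(domains)
    folds = rng.uniform(*spec.fold_range, size=len(merged))

    rows = []
    cursor = 0
    for (s, e), f in zip(merged, folds):
        if s > cursor:
            rows.append((spec.chromosome, cursor, s, spec.background * spec.control_level))
        rows.append((spec.chromosome, s, e, f * spec.control_level))
        cursor = e
    if cursor < L:
        rows.append((spec.chromosome, cursor, L, spec.background * spec.control_level))
    target = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    control = pd.DataFrame(
        [(spec.chromosome, 0, L, spec.control_level)],
        columns=["chrom", "start", "end", "value"],
    )
    truth = {
        "chromosome": spec.chromosome,
        "intervals": merged,
        "union_length": sum(e - s for s, e in merged),
        "folds": folds.tolist(),
    }
    return target, control, truth


# ---------------------------------------------------------------------------
# FISH voxel masks
# ---------------------------------------------------------------------------


def simulate_fish_mask(kind: str, params: dict | None = None, seed: int = 0) -> VoxelMask:
    """Simulate a 3D FISH signal mask.

    ``kind='compact'`` plants one solid digital ball (radius in voxels);
    ``kind='dispersed'`` scatters ``n_speckles`` single-voxel signals on a
    shell of ``bounding_radius`` voxels around the volume centre.
    """
    params = dict(params or {})
    shape = tuple(params.pop("shape", (64, 64, 64)))
    voxel_size = tuple(params.pop("voxel_size", (1.0, 1.0, 1.0)))
    rng = child_rng(seed, "fish", _crc(kind))
    data = np.zeros(shape, dtype=bool)
    center = (np.array(shape) - 1) / 2.0
    if kind == "compact":
        radius = float(params.pop("radius", 10.0))
        zz, yy, xx = np.indices(shape)
        dist2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        data[dist2 <= radius**2] = True
    elif kind == "dispersed":
        k = int(params.pop("n_speckles", 8))
        radius = float(params.pop("bounding_radius", 20.0))
        for _ in range(k):
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * radius
            idx = np.clip(np.round(center + v).astype(int), 0, np.array(shape) - 1)
            data[tuple(idx)] = True
    else:
        raise ValueError(f"unknown mask kind {kind!r}; use 'compact' or 'dispersed'")
    if params:
        raise ValueError(f"unused mask parameters: {sorted(params)}")
    return VoxelMask(data=data, voxel_size=voxel_size)


def write_voxel_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as a plain-text voxel list with shape/voxel-size header."""
    z, y, x = np.nonzero(mask.data)
    with open(path, "w") as fh:
        fh.write(f"# shape: {' '.join(map(str, mask.data.shape))}\n")
        fh.write(f"# voxel_size_um: {' '.join(f'{v:g}' for v in mask.voxel_size)}\n")
        for zi, yi, xi in zip(z, y, x):
            fh.write(f"{zi}\t{yi}\t{xi}\n")


def read_voxel_mask(path: str | Path) -> VoxelMask:
    shape: tuple[int, ...] | None = None
    voxel: tuple[float, ...] = (1.0, 1.0, 1.0)
    coords = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# shape:"):
                shape = tuple(int(v) for v in line.split(":")[1].split())
            elif line.startswith("# voxel_size_um:"):
                voxel = tuple(float(v) for v in line.split(":")[1].split())
            elif line:
                coords.append(tuple(int(v) for v in line.split()))
    if shape is None:
        raise ValueError(f"{path}: missing '# shape:' header")
    data = np.zeros(shape, dtype=bool)
    for c in coords:
        data[c] = True
    return VoxelMask(data=data, voxel_size=voxel)
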