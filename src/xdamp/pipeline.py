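"""Configuration and end-to-end orchestration.

This module wires the stages together: synthetic inputs -> informative-SNP
genotyping -> allelic counts -> haplotype -> pXi ratios / biallelism ->
dosage -> classification -> coverage / pausing / dispersion summaries.  It
also exposes the parameter-recovery drivers used to check that the
pipeline recovers the statistics each preset plants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic, classes, coverage, dosage, genotyping, metrics, synthetic
from .synthetic import (
    AllelicDataset,
    DomainSpec,
    GenomeModel,
    get_preset,
    child_rng,
)

logger = logging.getLogger("xdamp.pipeline")

__all__ = [
    "RunConfig",
    "validate_config",
    "run_all",
    "chromosome_ratio",
    "biallelic_percent",
    "xa_ratio_fold",
    "classification_counts",
    "spen_dependence_counts",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All stage parameters with the method's stated defaults.

    DNA filter 50/10/0.25; biallelic minor fraction 0.25; classification
    fold threshold 1.2; coverage bins 10 kb with occupancy thresholds 1.2
    (over IgG) and 10 (over input); TSS flank 5 kb.
    """

    seed: int = 0
    outdir: str = "xdamp_out"
    presets: tuple[str, ...] = ("primed_v1", "naive_pxgl_wt_v1", "naive_ko_v1")
    # genome
    n_x_genes: int = 150
    n_autosomal_genes: int = 300
    x_length: float = 1.5e8
    autosome_length: float = 1.5e8
    snps_per_gene: int = 2
    gene_length: int = 20_000
    # DNA SNP filter
    min_quality: float = 50.0
    min_depth: int = 10
    min_allelic_ratio: float = 0.25
    # RNA allelic calls
    biallelic_min_minor: float = 0.25
    rna_min_depth: int = 10
    # classification
    fc_threshold: float = 1.2
    # coverage
    bin_width: int = 10_000
    cutrun_occupancy_fc: float = 1.2
    rap_occupancy_fc: float = 10.0
    tss_flank: int = 5000
    n_domains: int = 8
    domain_length_mean: float = 2e6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        if "presets" in raw:
            raw["presets"] = tuple(raw["presets"])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable problems (empty when valid)."""
    errs = []
    for name in ("min_quality", "min_depth", "min_allelic_ratio", "fc_threshold",
                 "bin_width", "cutrun_occupancy_fc", "rap_occupancy_fc",
                 "rna_min_depth", "tss_flank"):
        if getattr(config, name) <= 0:
            errs.append(f"{name} must be positive")
    for name in ("min_allelic_ratio", "biallelic_min_minor"):
        if not 0 < getattr(config, name) <= 0.5:
            errs.append(f"{name} must be in (0, 0.5]")
    for p in config.presets:
        if p not in synthetic.PRESETS:
            errs.append(
                f"unknown preset {p!r}; available: {', '.join(sorted(synthetic.PRESETS))}"
            )
    if config.n_x_genes <= 0 or config.n_autosomal_genes <= 0:
        errs.append("gene counts must be positive")
    return errs


# ---------------------------------------------------------------------------
# Stage plumbing shared by the drivers
# ---------------------------------------------------------------------------


def _build_genome_for(preset_name: str, seed: int, config: RunConfig | None = None) -> GenomeModel:
    cfg = config or RunConfig()
    preset = get_preset(preset_name)
    n_x = max(preset.n_x_genes, cfg.n_x_genes) if preset.n_x_genes == cfg.n_x_genes else preset.n_x_genes
    return synthetic.build_genome(
        n_x_genes=n_x,
        n_autosomal_genes=cfg.n_autosomal_genes if preset.n_x_genes == cfg.n_x_genes else max(60, preset.n_x_genes),
        x_length=cfg.x_length,
        autosome_length=cfg.autosome_length,
        snps_per_gene=preset.snps_per_gene,
        seed=seed,
        gene_length=cfg.gene_length,
    )


def _informative_snps(
    genome: GenomeModel, seed: int, config: RunConfig, workdir: Path | None
) -> pd.DataFrame:
    records = synthetic.simulate_variant_records(genome, het_fraction=1.0, seed=seed)
    if workdir is not None:
        vcf_path = workdir / "variants.vcf"
        synthetic.write_vcf(records, genome, vcf_path)
        records = genotyping.read_vcf_minimal(vcf_path)
    return genotyping.filter_heterozygous(
        records,
        genes=genome.genes,
        min_quality=config.min_quality,
        min_depth=config.min_depth,
        min_allelic_ratio=config.min_allelic_ratio,
    )


def _condition_counts(
    dataset: AllelicDataset,
    genome: GenomeModel,
    info: pd.DataFrame,
    condition: str,
    workdir: Path | None,
) -> pd.DataFrame:
    """Counts at informative SNPs for one condition (all replicates).

    With a workdir the counts make a full round trip through mpileup text
    via :func:`xdamp.allelic.parse_pileup`; otherwise the generator's
    count table is filtered to the informative set directly.
    """
    if workdir is not None:
        frames = []
        for sample in dataset.sample_names(condition):
            path = workdir / f"{sample}.pileup"
            synthetic.write_pileup(dataset, genome, sample, path)
            frames.append(allelic.parse_pileup(path, info, sample=sample))
        return pd.concat(frames, ignore_index=True)
    sub = dataset.counts[dataset.counts["condition"] == condition]
    keep = sub.merge(info[["chrom", "pos"]], on=["chrom", "pos"])
    return keep[["chrom", "pos", "gene_id", "sample", "ref_count", "alt_count"]].copy()


def _haplotype_from(
    dataset: AllelicDataset,
    genome: GenomeModel,
    info: pd.DataFrame,
    condition: str,
    config: RunConfig,
    workdir: Path | None,
) -> pd.DataFrame:
    counts = _condition_counts(dataset, genome, info, condition, workdir)
    counts = counts[counts["chrom"] == genome.x_chrom]
    # one Xa haplotype from the combined primed evidence: pool replicates
    # per SNP before the monoallelic call
    pooled = counts.groupby(["chrom", "pos"], as_index=False)[["ref_count", "alt_count"]].sum()
    return allelic.build_xa_haplotype(
        pooled,
        mono_max_minor=config.biallelic_min_minor,
        min_rna_depth=config.rna_min_depth,
    )


def _gene_ratio_matrix(
    dataset: AllelicDataset,
    genome: GenomeModel,
    info: pd.DataFrame,
    haplotype: pd.DataFrame,
    conditions: list[str],
    workdir: Path | None = None,
) -> pd.DataFrame:
    """Gene x condition matrix of pooled pXi allelic ratios (X genes only)."""
    cols = {}
    for cond in conditions:
        counts = _condition_counts(dataset, genome, info, cond, workdir)
        summary = allelic.pxi_allelic_ratio(counts, haplotype, level="gene")
        cols[cond] = summary.set_index("gene_id")["ratio"]
    mat = pd.DataFrame(cols)
    x_genes = set(genome.x_genes["gene_id"])
    return mat.loc[[g for g in mat.index if g in x_genes]]


# ---------------------------------------------------------------------------
# Parameter-recovery drivers
# ---------------------------------------------------------------------------


def chromosome_ratio(
    preset_name: str,
    seed: int,
    haplotype_preset: str = "primed_v1",
    condition: str | None = None,
    config: RunConfig | None = None,
    workdir: str | Path | None = None,
) -> dict:
    """Chromosome-wide pXi allelic ratio for a preset's measured condition.

    Runs the full chain: simulated variant records -> heterozygous SNP
    filter -> primed Xa haplotype -> read-weighted ratio of pooled
    replicate counts over all mapped X SNPs.  The haplotype comes from
    ``haplotype_preset`` (or from the preset's own ``primed_ref``
    condition when it has one).
    """
    cfg = config or RunConfig(seed=seed)
    workdir = Path(workdir) if workdir is not None else None
    preset = get_preset(preset_name)
    genome = _build_genome_for(preset_name, seed, cfg)
    info = _informative_snps(genome, seed, cfg, workdir)
    ds = synthetic.simulate_allelic_dataset(genome, preset, seed)
    if "primed_ref" in preset.conditions:
        hap_ds, hap_cond = ds, "primed_ref"
    elif haplotype_preset == preset_name:
        hap_ds, hap_cond = ds, next(iter(preset.conditions))
    else:
        hap_ds = synthetic.simulate_allelic_dataset(genome, get_preset(haplotype_preset), seed)
        hap_cond = next(iter(hap_ds.preset.conditions))
    hap = _haplotype_from(hap_ds, genome, info, hap_cond, cfg, workdir)
    cond = condition or next(c for c in preset.conditions if c != "primed_ref")
    counts = _condition_counts(ds, genome, info, cond, workdir)
    summary = allelic.pxi_allelic_ratio(counts, hap, level="chromosome")
    row = summary[summary["chrom"] == genome.x_chrom].iloc[0]
    return {
        "preset": preset_name,
        "condition": cond,
        "ratio": float(row["ratio"]),
        "n_snps": int(row["n_snps"]),
        "n_mapped": len(hap),
    }


def biallelic_percent(
    preset_name: str,
    seed: int,
    chromosome: str | None = None,
    config: RunConfig | None = None,
    workdir: str | Path | None = None,
) -> dict:
    """Percent of informative SNPs called biallelic on one chromosome."""
    cfg = config or RunConfig(seed=seed)
    workdir = Path(workdir) if workdir is not None else None
    preset = get_preset(preset_name)
    genome = _build_genome_for(preset_name, seed, cfg)
    chromosome = chromosome or genome.x_chrom
    info = _informative_snps(genome, seed, cfg, workdir)
    ds = synthetic.simulate_allelic_dataset(genome, preset, seed)
    cond = next(c for c in preset.conditions if c != "primed_ref")
    counts = _condition_counts(ds, genome, info, cond, workdir)
    pct = allelic.percent_biallelic(
        counts,
        chromosome,
        min_minor_fraction=cfg.biallelic_min_minor,
        min_rna_depth=cfg.rna_min_depth,
    )
    n = int((info["chrom"] == chromosome).sum())
    return {"preset": preset_name, "chromosome": chromosome, "percent_biallelic": pct, "n_snps": n}


def xa_ratio_fold(
    seed: int,
    wt_preset: str = "naive_pxgl_wt_v1",
    ko_preset: str = "naive_ko_v1",
    n_x_genes: int = 800,
    n_autosomal_genes: int = 1600,
    config: RunConfig | None = None,
) -> dict:
    """X:A expression-ratio fold change KO / WT from simulated count tables.

    The dosage stage uses a gene complement sized like a whole-
    transcriptome analysis (hundreds of expressed X genes, twice as many
    autosomal controls), independent of the smaller SNP-gene panels used
    for allelic ratios: the X:A statistic is a median over all detected
    genes, and its sampling error scales with 1/sqrt(n genes).
    """
    cfg = config or RunConfig(seed=seed)
    genome = synthetic.build_genome(
        n_x_genes, n_autosomal_genes, cfg.x_length, cfg.autosome_length,
        cfg.snps_per_gene, seed, cfg.gene_length,
    )
    chrom_map = genome.gene_chromosomes()
    per_condition = {}
    for name in (wt_preset, ko_preset):
        tab = synthetic.simulate_expression_matrix(genome, name, seed)
        cpm = dosage.cpm_normalize(tab)
        per_condition[name] = float(
            dosage.x_to_autosome_ratio(cpm, chrom_map, x_chrom=genome.x_chrom).mean()
        )
    fold = dosage.ratio_fold_change(per_condition[ko_preset], per_condition[wt_preset])
    return {
        "xa_wt": per_condition[wt_preset],
        "xa_ko": per_condition[ko_preset],
        "fold": fold,
        "n_genes": len(genome.genes),
    }


def classification_counts(
    seed: int, config: RunConfig | None = None, workdir: str | Path | None = None
) -> dict:
    """Recover XIST-sensitive/resistant counts on the classification preset."""
    cfg = config or RunConfig(seed=seed)
    workdir = Path(workdir) if workdir is not None else None
    preset = get_preset("classification_v1")
    genome = _build_genome_for("classification_v1", seed, cfg)
    info = _informative_snps(genome, seed, cfg, workdir)
    ds = synthetic.simulate_allelic_dataset(genome, preset, seed)
    hap = _haplotype_from(ds, genome, info, "primed_ref", cfg, workdir)
    ratios = _gene_ratio_matrix(ds, genome, info, hap, ["wt", "ko", "ut", "dox"], workdir)
    calls = classes.classify_xist_sensitivity(
        ratios, pairs=[("ko", "wt"), ("dox", "ut")], fc_threshold=cfg.fc_threshold
    )
    vc = calls["class"].value_counts()
    return {
        "n_sensitive": int(vc.get("sensitive", 0)),
        "n_resistant": int(vc.get("resistant", 0)),
        "n_analyzed": int(len(calls) - vc.get("not_analyzed", 0)),
        "calls": calls,
    }


def spen_dependence_counts(
    seed: int, config: RunConfig | None = None, workdir: str | Path | None = None
) -> dict:
    """Recover the SPEN-dependent gene count among detected sensitive genes."""
    cfg = config or RunConfig(seed=seed)
    workdir = Path(workdir) if workdir is not None else None
    preset = get_preset("spen_kd_v1")
    genome = _build_genome_for("spen_kd_v1", seed, cfg)
    info = _informative_snps(genome, seed, cfg, workdir)
    ds = synthetic.simulate_allelic_dataset(genome, preset, seed)
    hap = _haplotype_from(ds, genome, info, "primed_ref", cfg, workdir)
    ratios = _gene_ratio_matrix(ds, genome, info, hap, ["scramble", "mix1", "mix2"], workdir)
    sensitive = ds.truth.loc[
        ds.truth["class_label"].str.startswith("sens"), "gene_id"
    ]
    detected = [g for g in sensitive if g in ratios.index and ratios.loc[g].notna().all()]
    cats = classes.classify_spen_dependence(
        ratios.loc[detected, "scramble"],
        ratios.loc[detected, "mix1"],
        ratios.loc[detected, "mix2"],
        fc_threshold=cfg.fc_threshold,
    )
    n_dep = int(cats["spen_category"].isin(["one_mix", "both_mixes"]).sum())
    return {
        "n_spen_dependent": n_dep,
        "n_detected_sensitive": len(detected),
        "categories": cats,
    }


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------


def run_all(config: RunConfig) -> dict:
    """Run every stage on the configured presets; write TSVs and a summary.

    Deterministic for a fixed seed.  The summary echoes every stated-
    default parameter for auditability and records a config digest.
    """
    errs = validate_config(config)
    if errs:
        raise ValueError("invalid configuration: " + "; ".join(errs))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    summary: dict = {
        "seed": seed,
        "config_digest": config.digest(),
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }

    # allelic ratios and biallelism per preset
    ratios = {}
    biallelism = {}
    for name in config.presets:
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        try:
            r = chromosome_ratio(name, seed, config=config, workdir=stage_dir)
        except Exception as exc:  # noqa: BLE001 - stage name in the error
            raise RuntimeError(f"stage allelic_ratio[{name}] failed: {exc}") from exc
        ratios[name] = {k: v for k, v in r.items() if k != "calls"}
        bx = biallelic_percent(name, seed, config=config)
        b7 = biallelic_percent(name, seed, chromosome="chr7", config=config)
        biallelism[name] = {
            "chrX": bx["percent_biallelic"],
            "chr7": b7["percent_biallelic"],
        }
    summary["stages"]["pxi_allelic_ratio"] = ratios
    summary["stages"]["percent_biallelic"] = biallelism
    pd.DataFrame(ratios).T.to_csv(out / "chromosome_ratios.tsv", sep="\t")
    pd.DataFrame(biallelism).T.to_csv(out / "percent_biallelic.tsv", sep="\t")

    # dosage
    fold = xa_ratio_fold(seed, config=config)
    summary["stages"]["x_to_autosome"] = fold

    # classification presets (always run; they carry their own genomes)
    cls = classification_counts(seed, config=config)
    cls["calls"].to_csv(out / "xist_sensitivity_calls.tsv", sep="\t")
    summary["stages"]["xist_sensitivity"] = {
        k: v for k, v in cls.items() if k != "calls"
    }
    spen = spen_dependence_counts(seed, config=config)
    spen["categories"].to_csv(out / "spen_dependence.tsv", sep="\t")
    summary["stages"]["spen_dependence"] = {
        k: v for k, v in spen.items() if k != "categories"
    }

    # coverage occupancy demo on a planted-domain track
    genome = synthetic.build_genome(
        config.n_x_genes, config.n_autosomal_genes, config.x_length,
        config.autosome_length, config.snps_per_gene, seed, config.gene_length,
    )
    spec = DomainSpec(n_domains=config.n_domains, length_mean=config.domain_length_mean)
    target, control, truth = synthetic.simulate_coverage(genome, spec, seed)
    tgt = coverage.bin_track(target, genome.chromosomes, config.bin_width)
    ctl = coverage.bin_track(control, genome.chromosomes, config.bin_width)
    fc = coverage.enrichment_over_control(tgt, ctl)
    occ = coverage.percent_occupancy(fc, config.cutrun_occupancy_fc)
    coverage.write_bedgraph(fc, out / "enrichment_fc.bedgraph")
    summary["stages"]["occupancy"] = {
        "percent": occ,
        "truth_percent": 100.0 * truth["union_length"] / genome.chromosomes[spec.chromosome],
        "threshold": config.cutrun_occupancy_fc,
    }

    # pausing demo: planted promoter-proximal pileup on X genes
    rng = child_rng(seed, "coverage", 999)
    pause = {}
    for g in genome.x_genes["gene_id"].head(20):
        strand = genome.genes.set_index("gene_id").loc[g, "strand"]
        cov = rng.poisson(10, size=config.gene_length).astype(float)
        cov[:300] += rng.poisson(30, size=300)
        if strand == "-":
            cov = cov[::-1]
        pause[g] = (strand, cov)
    ptab = metrics.pausing_table(pause)
    ptab.to_csv(out / "pausing_ratios.tsv", sep="\t", index=False)
    summary["stages"]["pausing"] = {
        "median_ratio": float(ptab["pausing_ratio"].median()),
        "n_genes": len(ptab),
    }

    # FISH dispersion demo
    compact = synthetic.simulate_fish_mask("compact", {"radius": 10}, seed)
    dispersed = synthetic.simulate_fish_mask("dispersed", {"n_speckles": 8, "bounding_radius": 20}, seed)
    summary["stages"]["fish_dispersion"] = {
        "compact": metrics.fish_dispersion(compact),
        "dispersed": metrics.fish_dispersion(dispersed),
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("wrote %s", out / "summary.json")
    return summary
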