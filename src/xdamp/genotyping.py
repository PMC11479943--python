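"""Selection of informative heterozygous SNPs from genomic variant records.

A genomic SNP is *informative* for allele-specific expression when the DNA
evidence supports heterozygosity: quality score >= 50, read coverage >= 10
and a minor-allele fraction of at least 0.25 (all thresholds inclusive,
interpreting "minimum threshold" as >=).  Multi-allelic sites and indels
are excluded; only biallelic SNPs are analyzed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("xdamp.genotyping")

__all__ = ["read_vcf_minimal", "annotate_genes", "filter_heterozygous"]

_RECORD_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "depth", "ad_ref", "ad_alt"]


class VcfParseError(ValueError):
    pass


def read_vcf_minimal(path: str | Path) -> pd.DataFrame:
    """Read variant records from a VCF with per-sample DP and AD fields.

    Returns a frame with columns chrom, pos (1-based), ref, alt, qual,
    depth, ad_ref, ad_alt, in file order.  Multi-allelic sites and indels
    are skipped (with a logged count); records lacking DP or AD raise a
    parse error naming the site.
    """
    rows = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            sample = rec.samples[0]
            dp = sample.get("DP")
            ad = sample.get("AD")
            if dp is None or ad is None or any(a is None for a in ad):
                raise VcfParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} is missing DP or AD"
                )
            rows.append(
                (rec.chrom, rec.pos, rec.ref, alts[0], rec.qual or 0.0, dp, ad[0], ad[1])
            )
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel records", n_skipped)
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def annotate_genes(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach a gene_id to each SNP by interval lookup (0-based half-open genes).

    SNPs falling in no gene are dropped with a logged count; the gene
    models are assumed non-overlapping, so each SNP maps to at most one.
    """
    out = snps.copy()
    out["gene_id"] = pd.NA
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        m = out["chrom"] == chrom
        pos0 = out.loc[m, "pos"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        vals = np.where(ok, sub["gene_id"].to_numpy()[np.clip(idx, 0, None)], None)
        out.loc[m, "gene_id"] = vals
    dropped = out["gene_id"].isna().sum()
    if dropped:
        logger.info("dropped %d SNPs outside any gene model", dropped)
    return out.dropna(subset=["gene_id"]).reset_index(drop=True)


def filter_heterozygous(
    records: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    min_quality: float = 50.0,
    min_depth: int = 10,
    min_allelic_ratio: float = 0.25,
) -> pd.DataFrame:
    """Retain informative heterozygous SNPs.

    A record is retained iff quality >= min_quality AND depth >= min_depth
    AND min(ad_ref, ad_alt) / (ad_ref + ad_alt) >= min_allelic_ratio, with
    the allelic ratio read as the minor-allele fraction (a symmetric
    definition of heterozygosity).  Records with ad_ref + ad_alt == 0 are
    skipped with a warning rather than an error.  When gene models are
    given the retained SNPs are annotated with gene ids.
    """
    if min_quality <= 0 or min_depth <= 0:
        raise ValueError("thresholds must be positive")
    if not 0 < min_allelic_ratio <= 0.5:
        raise ValueError("min_allelic_ratio must be in (0, 0.5]")
    ad_total = records["ad_ref"] + records["ad_alt"]
    zero = ad_total == 0
    if zero.any():
        logger.warning("skipping %d records with zero allele depths", int(zero.sum()))
    with np.errstate(invalid="ignore"):
        minor = np.minimum(records["ad_ref"], records["ad_alt"]) / ad_total
    keep = (
        ~zero
        & (records["qual"] >= min_quality)
        & (records["depth"] >= min_depth)
        & (minor >= min_allelic_ratio)
    )
    out = records.loc[keep, _RECORD_COLUMNS].reset_index(drop=True)
    out["minor_fraction"] = (
        np.minimum(out["ad_ref"], out["ad_alt"]) / (out["ad_ref"] + out["ad_alt"])
    )
    logger.info("retained %d of %d records as informative SNPs", len(out), len(records))
    if genes is not None:
        out = annotate_genes(out, genes)
    return out
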