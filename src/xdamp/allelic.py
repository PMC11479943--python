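"""Allele-specific expression from RNA pileups at informative SNPs.

The chain implemented here mirrors allelic analysis of X dampening in
hybrid-free settings: count reads per allele at informative heterozygous
SNPs, call each expressed SNP biallelic or monoallelic (minor allele >=
25% of reads), construct the putative Xa haplotype from SNPs expressed
monoallelically in primed cells (where one X is inactive), and aggregate
haplotype-assigned reads into pXi allelic ratios per gene or chromosome.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("xdamp.allelic")

__all__ = [
    "parse_pileup",
    "call_biallelic",
    "percent_biallelic",
    "build_xa_haplotype",
    "pxi_allelic_ratio",
]


class PileupParseError(ValueError):
    pass


def parse_pileup(
    path: str | Path, informative_snps: pd.DataFrame, sample: str = "sample"
) -> pd.DataFrame:
    """Count per-allele reads at informative SNPs from mpileup-dialect text.

    The pileup must follow the dialect produced with indel sequences and
    read start/end marks disabled: the base column holds only ``.``/``,``
    (reference) and base letters.  Reference count = ``.`` + ``,``; alt
    count = occurrences of the expected alt base (case-insensitive); bases
    matching neither are tallied as ``other_count`` and logged (sequencing
    errors are excluded from allelic ratios).  Informative SNPs absent
    from the pileup get zero counts.
    """
    key = informative_snps.set_index(["chrom", "pos"])
    counts: dict[tuple, tuple[int, int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise PileupParseError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
            chrom, pos_s, _ref, _depth, bases = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise PileupParseError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            if (chrom, pos) not in key.index:
                continue
            alt = str(key.loc[(chrom, pos), "alt"]).upper()
            ref_n = bases.count(".") + bases.count(",")
            alt_n = bases.upper().count(alt)
            other = sum(c.isalpha() for c in bases) - alt_n
            if other:
                logger.debug("%s:%d: %d bases match neither ref nor alt", chrom, pos, other)
            counts[(chrom, pos)] = (ref_n, alt_n, other)
    out = informative_snps[["chrom", "pos"] + (["gene_id"] if "gene_id" in informative_snps else [])].copy()
    triples = [counts.get((c, p), (0, 0, 0)) for c, p in zip(out["chrom"], out["pos"])]
    out[["ref_count", "alt_count", "other_count"]] = pd.DataFrame(triples, index=out.index)
    out["sample"] = sample
    return out


def call_biallelic(
    counts: pd.DataFrame, min_minor_fraction: float = 0.25, min_rna_depth: int = 10
) -> pd.Series:
    """Flag each SNP as biallelic / monoallelic / undetected.

    A SNP is undetected below ``min_rna_depth`` informative RNA reads;
    otherwise biallelic iff the minor allele carries at least
    ``min_minor_fraction`` of ref+alt reads (inclusive, per the "at least
    25% of reads from the second allele" rule).
    """
    if not 0 < min_minor_fraction <= 0.5:
        raise ValueError("min_minor_fraction must be in (0, 0.5]")
    total = counts["ref_count"] + counts["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(counts["ref_count"], counts["alt_count"]) / total
    flag = np.where(
        total < min_rna_depth,
        "undetected",
        np.where(minor >= min_minor_fraction, "biallelic", "monoallelic"),
    )
    return pd.Series(flag, index=counts.index, name="allelic_call")


def percent_biallelic(counts: pd.DataFrame, chromosome: str, **call_kwargs) -> float:
    """Percentage of detected SNPs on a chromosome called biallelic.

    Counts for the same SNP across samples/replicates are pooled before
    calling.  Undetected SNPs are excluded from the denominator; if no SNP
    is detected the percentage is undefined (NaN, flagged by a warning).
    """
    sub = counts[counts["chrom"] == chromosome]
    pooled = sub.groupby(["chrom", "pos"], as_index=False)[["ref_count", "alt_count"]].sum()
    flags = call_biallelic(pooled, **call_kwargs)
    detected = flags != "undetected"
    if not detected.any():
        logger.warning("no detected SNPs on %s; percent biallelic undefined", chromosome)
        return float("nan")
    return 100.0 * float((flags == "biallelic").sum()) / float(detected.sum())


def build_xa_haplotype(
    primed_counts: pd.DataFrame,
    mono_max_minor: float = 0.25,
    min_rna_depth: int = 10,
) -> pd.DataFrame:
    """Construct the putative Xa haplotype from primed-cell RNA counts.

    SNPs expressed monoallelically in primed cells (minor fraction <
    ``mono_max_minor`` at depth >= ``min_rna_depth``) assign their
    majority allele to the previously active X (pXa) and the other allele
    to the previously inactive X (pXi).  Biallelic (escapee-like) and
    undetected SNPs are excluded.  With several primed replicates
    (distinguished by the ``sample`` column) the per-replicate assignments
    are combined by majority vote and unresolved ties dropped.

    Returns a frame with columns chrom, pos, xa_allele, pxi_allele
    (values ``ref``/``alt``).  Raises if no SNP can be mapped.
    """
    votes = []
    for _, sub in primed_counts.groupby("sample") if "sample" in primed_counts else [("s", primed_counts)]:
        total = sub["ref_count"] + sub["alt_count"]
        with np.errstate(invalid="ignore", divide="ignore"):
            minor = np.minimum(sub["ref_count"], sub["alt_count"]) / total
        mono = (total >= min_rna_depth) & (minor < mono_max_minor)
        v = sub.loc[mono, ["chrom", "pos"]].copy()
        v["xa_allele"] = np.where(
            sub.loc[mono, "ref_count"] >= sub.loc[mono, "alt_count"], "ref", "alt"
        )
        votes.append(v)
    allv = pd.concat(votes, ignore_index=True) if votes else pd.DataFrame(columns=["chrom", "pos", "xa_allele"])
    if allv.empty:
        raise ValueError("no monoallelically expressed SNPs: cannot build Xa haplotype")
    tally = (
        allv.groupby(["chrom", "pos", "xa_allele"]).size().unstack(fill_value=0)
    )
    for col in ("ref", "alt"):
        if col not in tally:
            tally[col] = 0
    ties = tally["ref"] == tally["alt"]
    if ties.any():
        logger.info("dropping %d SNPs with tied haplotype votes", int(ties.sum()))
    tally = tally[~ties]
    if tally.empty:
        raise ValueError("no monoallelically expressed SNPs: cannot build Xa haplotype")
    hap = tally.reset_index()[["chrom", "pos"]]
    hap["xa_allele"] = np.where(tally["ref"].to_numpy() > tally["alt"].to_numpy(), "ref", "alt")
    hap["pxi_allele"] = np.where(hap["xa_allele"] == "ref", "alt", "ref")
    logger.info("Xa haplotype maps %d SNPs", len(hap))
    return hap


def _assign_counts(counts: pd.DataFrame, haplotype: pd.DataFrame) -> pd.DataFrame:
    merged = counts.merge(haplotype, on=["chrom", "pos"], how="inner")
    xa_ref = merged["xa_allele"] == "ref"
    merged["pxa_reads"] = np.where(xa_ref, merged["ref_count"], merged["alt_count"])
    merged["pxi_reads"] = np.where(xa_ref, merged["alt_count"], merged["ref_count"])
    return merged


def pxi_allelic_ratio(
    counts: pd.DataFrame, haplotype: pd.DataFrame, level: str = "gene"
) -> pd.DataFrame:
    """pXi allelic ratios from haplotype-assigned read counts.

    ``counts`` rows (possibly several samples/replicates; they are pooled)
    must carry chrom/pos/ref_count/alt_count and, for gene-level ratios, a
    gene_id column.  Only SNPs covered by the haplotype map are used.

    * level="gene": one row per gene with pxi_reads, pxa_reads,
      ratio = pxi/(pxi+pxa), n_snps and a ``defined`` flag (False when no
      reads were assigned; such genes are excluded from aggregates).
    * level="chromosome": one row per chromosome with the read-weighted
      ratio (ratio of summed counts over all mapped SNPs).
    """
    merged = _assign_counts(counts, haplotype)
    if level == "gene":
        grp = merged.groupby("gene_id", as_index=False).agg(
            chrom=("chrom", "first"),
            pxi_reads=("pxi_reads", "sum"),
            pxa_reads=("pxa_reads", "sum"),
            n_snps=("pos", "nunique"),
        )
    elif level == "chromosome":
        grp = merged.groupby("chrom", as_index=False).agg(
            pxi_reads=("pxi_reads", "sum"),
            pxa_reads=("pxa_reads", "sum"),
            n_snps=("pos", "nunique"),
        )
    else:
        raise ValueError("level must be 'gene' or 'chromosome'")
    total = grp["pxi_reads"] + grp["pxa_reads"]
    grp["defined"] = total > 0
    with np.errstate(invalid="ignore"):
        grp["ratio"] = np.where(grp["defined"], grp["pxi_reads"] / total.replace(0, np.nan), np.nan)
    n_undef = int((~grp["defined"]).sum())
    if n_undef:
        logger.info("%d %s-level ratios undefined (zero assigned reads)", n_undef, level)
    return grp
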