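"""Library-size normalization and X:A dosage statistics."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("xdamp.dosage")

__all__ = ["cpm_normalize", "x_to_autosome_ratio", "ratio_fold_change"]


def cpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization of a gene x sample table."""
    if (table < 0).any().any():
        raise ValueError("counts must be >= 0")
    sums = table.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"all-zero samples cannot be CPM-normalized: {bad}")
    return table * 1e6 / sums


def x_to_autosome_ratio(
    table: pd.DataFrame,
    gene_chrom: pd.Series,
    x_chrom: str = "chrX",
    detected_only: bool = True,
    statistic: str = "median",
) -> pd.Series:
    """X:A expression ratio per sample.

    Ratio of the median (or mean, switchable) expression of X-linked genes
    to that of autosomal genes, computed per sample after removing
    nondetected genes (value 0).  Input is typically CPM; the ratio is
    invariant to per-sample library rescaling.
    """
    agg = {"median": np.median, "mean": np.mean}[statistic]
    chrom = gene_chrom.reindex(table.index)
    if chrom.isna().any():
        raise ValueError("every gene must be mapped to a chromosome")
    is_x = (chrom == x_chrom).to_numpy()
    out = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        det = (v > 0) if detected_only else np.ones_like(v, bool)
        xs, aus = v[det & is_x], v[det & ~is_x]
        if len(xs) == 0 or len(aus) == 0:
            logger.warning("sample %s: empty detected gene set; X:A undefined", col)
            out[col] = float("nan")
        else:
            out[col] = float(agg(xs)) / float(agg(aus))
    return pd.Series(out, name="x_to_autosome")


def ratio_fold_change(value_a: float, value_b: float) -> float:
    """Plain fold change value_a / value_b (value_b must be > 0)."""
    if value_b <= 0:
        raise ValueError("denominator must be > 0")
    return float(value_a) / float(value_b)
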