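"""Gene classification by fold changes of the pXi allelic ratio.

XIST sensitivity: a gene is *sensitive* when the fold change of its pXi
allelic ratio (perturbed / reference) exceeds 1.2 in every independent
perturbation dataset pair; genes analyzed in all pairs but failing the
rule are *resistant* (their ratio stays ~0.5 regardless of XIST); genes
with any undefined ratio are *not_analyzed*.

SPEN dependence: among XIST-sensitive genes, the same FC > 1.2 rule is
applied to two knockdown mixes against a scramble control, yielding
``both_mixes`` / ``one_mix`` / ``none`` (or ``not_tested`` when a
condition is missing).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("xdamp.classes")

__all__ = ["classify_xist_sensitivity", "classify_spen_dependence"]


def _fold(perturbed: pd.Series, reference: pd.Series) -> pd.Series:
    ref = reference.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = perturbed.astype(float) / ref
    fc[ref == 0] = np.nan  # undefined fold; gene cannot be analyzed
    return fc


def classify_xist_sensitivity(
    ratios: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    fc_threshold: float = 1.2,
) -> pd.DataFrame:
    """Call genes XIST-sensitive or XIST-resistant.

    ``ratios`` is a gene x condition frame of pXi allelic ratios (NaN for
    undefined); ``pairs`` lists (perturbed, reference) condition column
    pairs.  Sensitive iff FC > fc_threshold (strict) in *every* pair;
    analyzed-but-not-sensitive genes are resistant; genes with any
    undefined ratio or fold are not_analyzed.  Calls are invariant to the
    order of the pairs.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    if not pairs:
        raise ValueError("at least one (perturbed, reference) pair is required")
    out = pd.DataFrame(index=ratios.index)
    for i, (pert, ref) in enumerate(pairs, start=1):
        out[f"fc_pair{i}"] = _fold(ratios[pert], ratios[ref])
    fcs = out.to_numpy(dtype=float)
    analyzed = ~np.isnan(fcs).any(axis=1)
    sensitive = analyzed & (fcs > fc_threshold).all(axis=1)
    out["class"] = np.where(
        sensitive, "sensitive", np.where(analyzed, "resistant", "not_analyzed")
    )
    n_na = int((~analyzed).sum())
    if n_na:
        logger.info("%d genes not analyzed (undefined ratio or fold)", n_na)
    return out


def classify_spen_dependence(
    ratios_scr: pd.Series,
    ratios_mix1: pd.Series,
    ratios_mix2: pd.Series,
    fc_threshold: float = 1.2,
) -> pd.DataFrame:
    """SPEN-dependence category per gene from scramble and two KD mixes.

    ``both_mixes`` when FC(mix/scr) > fc_threshold in both mixes,
    ``one_mix`` in exactly one, ``none`` otherwise; genes with any missing
    condition are ``not_tested``.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    df = pd.DataFrame({"scr": ratios_scr, "mix1": ratios_mix1, "mix2": ratios_mix2})
    fc1 = _fold(df["mix1"], df["scr"])
    fc2 = _fold(df["mix2"], df["scr"])
    tested = df.notna().all(axis=1) & fc1.notna() & fc2.notna()
    n_up = (fc1 > fc_threshold).astype(int) + (fc2 > fc_threshold).astype(int)
    cat = np.select(
        [~tested, n_up == 2, n_up == 1], ["not_tested", "both_mixes", "one_mix"], "none"
    )
    return pd.DataFrame(
        {"fc_mix1": fc1, "fc_mix2": fc2, "spen_category": cat}, index=df.index
    )
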