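"""Allelic-imbalance statistic, Fisher exact testing and FDR screening.

The screen's statistic per (variant, construct) is the mutant/wild-type
splice ratio

    ratio = log2( (mo / mi) / (wo / wi) )

where ``mo``/``wo`` count mutant/wild-type spliced output and ``mi``/``wi``
the corresponding input abundances.  Input normalisation cancels synthesis
bias between alleles.  Significance comes from a two-sided Fisher exact
test on the 2x2 table (alleles x output/input), adjusted per construct by
Benjamini-Hochberg; a hit needs an adjusted p below 0.05 and at least a
1.5-fold allelic ratio in either direction.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "allelic_imbalance",
    "allelic_imbalance_array",
    "fisher_two_sided",
    "adjust_fdr",
    "call_significant",
    "imbalance_table",
    "FOLD_THRESHOLD",
    "Q_THRESHOLD",
    "PSEUDOCOUNT",
]

FOLD_THRESHOLD = 1.5
Q_THRESHOLD = 0.05
PSEUDOCOUNT = 0.5


def allelic_imbalance(
    mo: float, mi: float, wo: float, wi: float, pseudocount: float = PSEUDOCOUNT
) -> float:
    """log2((mo/mi)/(wo/wi)) with Haldane-Anscombe zero handling.

    The pseudocount is added to all four counts only when any of them is
    zero, leaving nonzero tables untouched.  An all-zero row yields NaN
    (flagged, not raised).
    """
    if min(mo, mi, wo, wi) < 0:
        raise ValueError("counts must be non-negative")
    if mo == mi == wo == wi == 0:
        return math.nan
    if min(mo, mi, wo, wi) == 0:
        mo, mi, wo, wi = (x + pseudocount for x in (mo, mi, wo, wi))
    if min(mi, wi) == 0:
        return math.nan
    return math.log2((mo / mi) / (wo / wi))


def allelic_imbalance_array(
    mo, mi, wo, wi, pseudocount: float = PSEUDOCOUNT
) -> np.ndarray:
    """Vectorised :func:`allelic_imbalance`."""
    mo, mi, wo, wi = (np.asarray(x, dtype=float) for x in (mo, mi, wo, wi))
    any_zero = (mo == 0) | (mi == 0) | (wo == 0) | (wi == 0)
    pc = np.where(any_zero, pseudocount, 0.0)
    mo, mi, wo, wi = mo + pc, mi + pc, wo + pc, wi + pc
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2((mo / mi) / (wo / wi))
    out[(mi == 0) | (wi == 0)] = np.nan
    return out


def fisher_two_sided(mo: int, mi: int, wo: int, wi: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[mo, mi], [wo, wi]]."""
    return float(sps.fisher_exact([[mo, mi], [wo, wi]], alternative="two-sided")[1])


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (R's p.adjust method='fdr')."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    return multipletests(p, method="fdr_bh")[1]


def imbalance_table(
    counts: pd.DataFrame, pseudocount: float = PSEUDOCOUNT
) -> pd.DataFrame:
    """Add the splice ratio and Fisher p to a four-count table.

    Expects columns (variant, construct, mo, mi, wo, wi); rows with zero
    input on both alleles get a NaN ratio and p = 1.
    """
    df = counts.copy()
    df["ratio"] = allelic_imbalance_array(
        df["mo"], df["mi"], df["wo"], df["wi"], pseudocount
    )
    df["p"] = [
        fisher_two_sided(int(r.mo), int(r.mi), int(r.wo), int(r.wi))
        for r in df.itertuples(index=False)
    ]
    return df


def call_significant(
    results: pd.DataFrame,
    fold_threshold: float = FOLD_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Apply BH adjustment and the screen's significance rule.

    The FDR family is all variants within one construct.  A construct-level
    hit requires q < ``q_threshold`` and |ratio| >= log2(``fold_threshold``)
    (two-sided: both loss and gain of inclusion count).  Per variant, the
    table gains the mean ratio across constructs, the number of constructs
    called significant, and the screen-level flag (significant in >= 1
    construct).
    """
    df = results.copy()
    log_fold = math.log2(fold_threshold)
    df["q"] = np.nan
    for _, idx in df.groupby("construct").groups.items():
        df.loc[idx, "q"] = adjust_fdr(df.loc[idx, "p"].to_numpy())
    df["significant"] = (
        (df["q"] < q_threshold)
        & df["ratio"].notna()
        & (df["ratio"].abs() >= log_fold)
    )
    per_variant = df.groupby("variant").agg(
        mean_ratio=("ratio", "mean"),
        n_constructs_significant=("significant", "sum"),
    )
    per_variant["screen_hit"] = per_variant["n_constructs_significant"] >= 1
    df = df.merge(per_variant, left_on="variant", right_index=True, how="left")
    df["n_constructs_significant"] = df["n_constructs_significant"].astype(int)
    return df
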