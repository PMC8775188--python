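"""Hexamer enhancer-index (EI) scoring of exons.

Every overlapping hexamer of an exon, at a step of one nucleotide, is
looked up in an empirically determined enhancer-index table (one score
per 6-mer, positive = enhancing, negative = silencing); the exon's score
is the mean over its L-5 windows.  The per-variant change is the
wild-type exon mean minus the mutant exon mean, so a positive delta
means loss of enhancer signal.  Because the alleles differ at a single
base, at most the six windows overlapping the variant contribute to the
difference.

The EI table is user-supplied (TSV: hexamer <tab> score).  For tests and
demos a synthetic, seeded stand-in table over all 4096 hexamers is
provided; it has the right shape but no biological content.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "read_ei_table",
    "synthetic_ei_table",
    "exon_mean_ei",
    "delta_ei",
    "ei_scores_table",
    "correlate_delta_ei_with_imbalance",
]

_DNA = frozenset("ACGT")


def read_ei_table(path: str | Path) -> dict[str, float]:
    """Read a hexamer score table (TSV: hexamer, score; header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if str(df.iloc[0, 0]).upper() in {"HEXAMER", "HEX"}:
        df = df.iloc[1:]
    table: dict[str, float] = {}
    for hexamer, score in zip(df.iloc[:, 0], df.iloc[:, 1]):
        h = str(hexamer).upper()
        if len(h) != 6 or not set(h) <= _DNA:
            raise ValueError(f"invalid hexamer {hexamer!r} in {path}")
        if h in table:
            raise ValueError(f"duplicate hexamer {h} in {path}")
        table[h] = float(score)
    return table


def synthetic_ei_table(seed: int = 2021) -> dict[str, float]:
    """Synthetic stand-in EI table: standard-normal scores for all 4096
    hexamers, fixed by ``seed``.  For testing and demos only."""
    rng = np.random.default_rng(seed)
    hexamers = ["".join(h) for h in itertools.product("ACGT", repeat=6)]
    return dict(zip(hexamers, rng.normal(0.0, 1.0, len(hexamers))))


def exon_mean_ei(exon_seq: str, table: Mapping[str, float]) -> float:
    """Mean EI over the (L-5) overlapping hexamers of an exon.

    Raises on sequences shorter than 6 nt, non-ACGT characters, or a
    hexamer missing from the table (named in the error).
    """
    seq = exon_seq.upper()
    if len(seq) < 6:
        raise ValueError(f"exon of length {len(seq)} has no hexamer window")
    if not set(seq) <= _DNA:
        raise ValueError("exon sequence contains non-ACGT characters")
    total = 0.0
    n = len(seq) - 5
    for i in range(n):
        hexamer = seq[i : i + 6]
        try:
            total += table[hexamer]
        except KeyError:
            raise KeyError(f"hexamer {hexamer} absent from EI table") from None
    return total / n


def delta_ei(wt_exon: str, mut_exon: str, table: Mapping[str, float]) -> float:
    """Wild-type minus mutant mean EI for a single-substitution exon pair.

    Positive values indicate loss of enhancer elements.
    """
    if len(wt_exon) != len(mut_exon):
        raise ValueError("wild-type and mutant exons must have equal length")
    return exon_mean_ei(wt_exon, table) - exon_mean_ei(mut_exon, table)


def ei_scores_table(
    exon_pairs: Mapping[str, tuple[str, str]], table: Mapping[str, float]
) -> pd.DataFrame:
    """Score a set of variants: ``exon_pairs`` maps variant id ->
    (wt_exon, mut_exon).  Returns columns (variant, ei_wt, ei_mut, delta_ei).
    """
    rows = []
    for vid, (wt, mut) in exon_pairs.items():
        ei_wt = exon_mean_ei(wt, table)
        ei_mut = exon_mean_ei(mut, table)
        rows.append(
            {"variant": vid, "ei_wt": ei_wt, "ei_mut": ei_mut, "delta_ei": ei_wt - ei_mut}
        )
    return pd.DataFrame(rows, columns=["variant", "ei_wt", "ei_mut", "delta_ei"])


def correlate_delta_ei_with_imbalance(
    ei_scores: pd.DataFrame,
    imbalance: pd.DataFrame,
    n_bins: int = 8,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of delta-EI against mean allelic imbalance.

    ``imbalance`` needs columns (variant, mean_ratio) — one row per variant
    is taken.  Returns (rho, p, binned summary) where the summary holds the
    mean imbalance per delta-EI bin for plotting.  Loss of enhancers
    (positive delta) is expected to associate with more negative imbalance,
    i.e. a negative rho.
    """
    imb = imbalance.drop_duplicates("variant")[["variant", "mean_ratio"]]
    joined = ei_scores.merge(imb, on="variant").dropna(
        subset=["delta_ei", "mean_ratio"]
    )
    if len(joined) < 3:
        raise ValueError("need at least 3 joined variants for a correlation")
    rho, p = sps.spearmanr(joined["delta_ei"], joined["mean_ratio"])
    bins = pd.cut(joined["delta_ei"], n_bins)
    summary = (
        joined.groupby(bins, observed=True)
        .agg(
            n=("variant", "size"),
            mean_delta_ei=("delta_ei", "mean"),
            mean_imbalance=("mean_ratio", "mean"),
            sem_imbalance=("mean_ratio", "sem"),
        )
        .reset_index(names="delta_ei_bin")
    )
    return float(rho), float(p), summary
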