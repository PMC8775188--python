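"""Convenience orchestration of the full screen.

Thin compositions of the stage modules: design the library for a cohort,
simulate sequencing, quantify, and screen.  The CLI and the demo are
wrappers over these functions.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import design, quantify, simulate, stats
from .variants import ExonContext, Variant, filter_eligible

__all__ = [
    "design_library",
    "screen_counts",
    "simulate_screen_counts",
]


def design_library(
    variants: list[Variant],
    contexts: Mapping[str, ExonContext],
    constructs: Mapping[str, design.ConstructDef] | None = None,
    arms: tuple[str, str] | None = None,
):
    """Design oligos and enumerate species for every eligible variant.

    Returns (eligible variants, oligo pairs by variant id, species
    catalogs keyed (variant id, construct name)).
    """
    if constructs is None:
        constructs = design.default_constructs()
    eligible = filter_eligible(variants, contexts)
    oligos = {
        v.id: design.design_oligo(v, contexts[v.id], arms) for v in eligible
    }
    catalogs = {
        (vid, cname): design.enumerate_species(oligo, cdef)
        for vid, oligo in oligos.items()
        for cname, cdef in constructs.items()
    }
    return eligible, oligos, catalogs


def screen_counts(
    counts: pd.DataFrame,
    pseudocount: float = stats.PSEUDOCOUNT,
    fold_threshold: float = stats.FOLD_THRESHOLD,
    q_threshold: float = stats.Q_THRESHOLD,
) -> pd.DataFrame:
    """Counts -> ratios, Fisher p, per-construct BH q and screen calls."""
    return stats.call_significant(
        stats.imbalance_table(counts, pseudocount),
        fold_threshold=fold_threshold,
        q_threshold=q_threshold,
    )


def simulate_screen_counts(
    config: simulate.SimConfig,
    constructs: Mapping[str, design.ConstructDef] | None = None,
    variant_ids=None,
    effects=None,
    counts_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample a truth table, realise counts, and screen them.

    Returns (truth, counts, results).  ``counts_seed`` defaults to a value
    derived from the config seed.
    """
    truth = simulate.sample_truth(
        config, constructs=constructs, variant_ids=variant_ids, effects=effects
    )
    if counts_seed is None:
        counts_seed = (config.seed * 69069 + 12345) % 2**31
    counts = simulate.simulate_counts(truth, counts_seed)
    return truth, counts, screen_counts(counts)
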