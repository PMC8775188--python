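"""Proband-versus-sibling cohort comparisons.

Screen-level calls are compared between affected probands and their
unaffected siblings: proportions of splice-disrupting variants by
consequence class, mean |imbalance| per role, external splicing-score
burden restricted to gene sets, and summaries of hit genes against a
primary association database plus curated paralog annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .variants import GeneSet, Variant

__all__ = [
    "proportions_by_class",
    "mann_whitney",
    "kruskal_wallis",
    "geneset_burden",
    "summarize_genes",
    "tabulate_screen",
    "GeneSummary",
]

ROLES = ("proband", "sibling")
CLASSES = ("synonymous", "missense", "nonsense")


def _variants_frame(variants: Iterable[Variant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": v.id,
                "gene": v.gene.upper(),
                "consequence": v.consequence,
                "role": v.role,
            }
            for v in variants
        ]
    )


def proportions_by_class(
    variants: Iterable[Variant], calls: Mapping[str, bool] | pd.DataFrame
) -> pd.DataFrame:
    """Counts and proportions of screen-level hits per role x class.

    ``calls`` maps variant id -> screen-level hit flag (or is a results
    frame with columns variant, screen_hit).  Every variant must have a
    call.  Rows for each (role, consequence) pair plus a per-role
    ``overall`` row are returned with n_assayed, n_significant, proportion.
    """
    if isinstance(calls, pd.DataFrame):
        calls = (
            calls.drop_duplicates("variant")
            .set_index("variant")["screen_hit"]
            .to_dict()
        )
    df = _variants_frame(variants)
    missing = [v for v in df["variant"] if v not in calls]
    if missing:
        raise ValueError(f"no screen call for variants {missing[:5]}")
    df["hit"] = df["variant"].map(calls).astype(bool)
    rows = []
    for role in ROLES:
        sub = df[df["role"] == role]
        for cls in CLASSES + ("overall",):
            part = sub if cls == "overall" else sub[sub["consequence"] == cls]
            n = len(part)
            k = int(part["hit"].sum())
            rows.append(
                {
                    "role": role,
                    "consequence": cls,
                    "n_assayed": n,
                    "n_significant": k,
                    "proportion": k / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction and continuity.

    When every value is identical across both samples the rank test is
    degenerate; (U = n_a*n_b/2, p = 1.0) is returned rather than raising.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return len(a) * len(b) / 2.0, 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H across groups (chi-square approximation).

    Degenerate input (all values identical) returns (0.0, 1.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("groups must be non-empty")
    if np.unique(np.concatenate(arrays)).size == 1:
        return 0.0, 1.0
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def geneset_burden(
    variants: Iterable[Variant],
    scores: Mapping[str, float],
    geneset: GeneSet,
) -> dict:
    """Compare an external per-variant splicing score between roles within
    one gene set.

    Restricts to variants whose gene is in the set and that have a score;
    returns per-role mean, s.e.m. and n, plus the two-sided Mann-Whitney p.
    Empty sides are flagged (``empty`` lists the roles without data) and
    leave the test statistics NaN.
    """
    df = _variants_frame(variants)
    df = df[df["gene"].isin(geneset.genes)]
    df = df.assign(score=df["variant"].map(scores)).dropna(subset=["score"])
    out: dict = {"geneset": geneset.name, "empty": []}
    samples = {}
    for role in ROLES:
        vals = df.loc[df["role"] == role, "score"].to_numpy()
        samples[role] = vals
        out[f"n_{role}"] = len(vals)
        out[f"mean_{role}"] = float(vals.mean()) if len(vals) else np.nan
        out[f"sem_{role}"] = (
            float(sps.sem(vals)) if len(vals) > 1 else np.nan
        )
        if len(vals) == 0:
            out["empty"].append(role)
    if out["empty"]:
        out["U"], out["p"] = np.nan, np.nan
    else:
        out["U"], out["p"] = mann_whitney(samples["proband"], samples["sibling"])
    return out


@dataclass(frozen=True)
class GeneSummary:
    """Partition of significant proband hit genes against a primary gene
    set and a curated paralog map: in-set, paralog-of-set, remainder."""

    genes: frozenset
    in_set: frozenset
    paralog_of_set: frozenset
    remainder: frozenset
    per_gene_variants: dict


def summarize_genes(
    calls: Mapping[str, bool] | pd.DataFrame,
    variants: Iterable[Variant],
    primary_set: GeneSet,
    paralog_map: Mapping[str, Iterable[str]],
) -> GeneSummary:
    """Summarise the genes carrying significant proband hits.

    Only synonymous and missense proband hits are counted (nonsense
    variants disrupt the protein regardless of splicing).  A gene outside
    the primary set is a paralog-of-set member when the paralog map lists
    at least one paralog inside the set.
    """
    if isinstance(calls, pd.DataFrame):
        calls = (
            calls.drop_duplicates("variant")
            .set_index("variant")["screen_hit"]
            .to_dict()
        )
    pmap = {g.upper(): {p.upper() for p in ps} for g, ps in paralog_map.items()}
    per_gene: dict[str, list[str]] = {}
    for v in variants:
        if (
            v.role == "proband"
            and v.consequence in {"synonymous", "missense"}
            and bool(calls.get(v.id, False))
        ):
            per_gene.setdefault(v.gene.upper(), []).append(v.id)
    genes = frozenset(per_gene)
    in_set = frozenset(g for g in genes if g in primary_set.genes)
    rest = genes - in_set
    paralog_of_set = frozenset(
        g for g in rest if pmap.get(g, set()) & primary_set.genes
    )
    return GeneSummary(
        genes=genes,
        in_set=in_set,
        paralog_of_set=paralog_of_set,
        remainder=rest - paralog_of_set,
        per_gene_variants=per_gene,
    )


def tabulate_screen(
    variants: Iterable[Variant],
    calls: Mapping[str, bool] | pd.DataFrame,
    primary_set: GeneSet | None = None,
    paralog_map: Mapping[str, Iterable[str]] | None = None,
) -> dict:
    """Headline tabulation of a screen: assayed counts, hit counts and
    proportions per role, and (when gene annotations are supplied) the
    unique proband hit genes with their primary-set / paralog overlap."""
    variants = list(variants)
    props = proportions_by_class(variants, calls)
    overall = props[props["consequence"] == "overall"].set_index("role")
    out = {
        "n_assayed": int(overall["n_assayed"].sum()),
        "n_significant": int(overall["n_significant"].sum()),
    }
    for role in ROLES:
        out[f"n_assayed_{role}"] = int(overall.loc[role, "n_assayed"])
        out[f"n_significant_{role}"] = int(overall.loc[role, "n_significant"])
        out[f"proportion_{role}"] = float(overall.loc[role, "proportion"])
    if primary_set is not None and paralog_map is not None:
        gs = summarize_genes(calls, variants, primary_set, paralog_map)
        out["n_hit_genes_proband"] = len(gs.genes)
        out["n_hit_genes_in_set"] = len(gs.in_set)
        out["n_hit_genes_paralog_of_set"] = len(gs.paralog_of_set)
    return out
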