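"""Variant tables, exon contexts, gene sets and external score tables.

The screen operates on de novo single-nucleotide variants identified in
simplex families: each child (affected proband or unaffected sibling)
contributes coding SNVs annotated with a consequence class.  A variant is
identified by a ``chrom:pos:ref:alt`` string with a 1-based position, e.g.
``17:76067246:G:A``.  Every variant carries an exon context — the test exon
plus flanking intronic sequence — stored in transcript orientation (contexts
for minus-strand genes are reverse-complemented before they reach this
layer, and the reader verifies the strand-adjusted reference allele).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Variant",
    "ExonContext",
    "GeneSet",
    "read_variants",
    "read_contexts",
    "filter_eligible",
    "read_gene_sets",
    "read_external_scores",
    "MAX_EXON_LEN",
    "MIN_UPSTREAM_INTRON",
    "DOWNSTREAM_FLANK_LEN",
]

CONSEQUENCES = frozenset({"synonymous", "missense", "nonsense"})
ROLES = frozenset({"proband", "sibling"})
_DNA = frozenset("ACGT")

#: eligibility bounds of the oligo design (exon length and minimum
#: retained upstream intron) and the fixed downstream flank length
MAX_EXON_LEN = 115
MIN_UPSTREAM_INTRON = 50
DOWNSTREAM_FLANK_LEN = 15

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


_ID_RE = re.compile(r"^([^:]+):(\d+):([ACGT]):([ACGT])$")


@dataclass(frozen=True)
class Variant:
    """One de novo coding SNV with its cohort annotations."""

    id: str
    gene: str
    consequence: str
    role: str
    family_id: str
    chrom: str = field(init=False)
    pos: int = field(init=False)
    ref: str = field(init=False)
    alt: str = field(init=False)

    def __post_init__(self) -> None:
        m = _ID_RE.match(self.id)
        if m is None:
            raise ValueError(
                f"variant id {self.id!r} does not parse as chrom:pos:ref:alt "
                "with a single-nucleotide ref/alt over ACGT"
            )
        chrom, pos, ref, alt = m.groups()
        if ref == alt:
            raise ValueError(f"variant id {self.id!r} has ref == alt")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", int(pos))
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r} for {self.id} "
                f"(expected one of {sorted(CONSEQUENCES)})"
            )
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role {self.role!r} for {self.id} "
                f"(expected one of {sorted(ROLES)})"
            )


@dataclass(frozen=True)
class ExonContext:
    """Test-exon sequence context in transcript orientation.

    ``variant_offset`` is the 0-based offset of the variant inside
    ``exon_seq``; for minus-strand genes the stored sequences are already
    reverse-complemented, so the base at that offset equals the complement
    of the genomic reference allele.
    """

    exon_seq: str
    upstream_intron_seq: str
    downstream_flank_seq: str
    strand: str
    variant_offset: int

    def __post_init__(self) -> None:
        for name in ("exon_seq", "upstream_intron_seq", "downstream_flank_seq"):
            seq = getattr(self, name).upper()
            if not set(seq) <= _DNA:
                raise ValueError(f"{name} contains non-ACGT characters")
            object.__setattr__(self, name, seq)
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.variant_offset < len(self.exon_seq):
            raise ValueError(
                f"variant_offset {self.variant_offset} outside exon of length "
                f"{len(self.exon_seq)}"
            )

    def expected_exon_base(self, ref: str) -> str:
        """Strand-adjusted reference base expected at ``variant_offset``."""
        return ref if self.strand == "+" else ref.translate(COMPLEMENT)

    def check_ref(self, variant: Variant) -> None:
        want = self.expected_exon_base(variant.ref)
        have = self.exon_seq[self.variant_offset]
        if have != want:
            raise ValueError(
                f"context for {variant.id}: exon base {have!r} at offset "
                f"{self.variant_offset} does not match strand-adjusted ref {want!r}"
            )

    def is_eligible(self) -> bool:
        return (
            len(self.exon_seq) <= MAX_EXON_LEN
            and len(self.upstream_intron_seq) >= MIN_UPSTREAM_INTRON
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def read_variants(path: str | Path) -> list[Variant]:
    """Read a variant table (TSV/CSV with header id, gene, consequence, role,
    family_id) into validated :class:`Variant` records, preserving row order.

    Malformed ids, unknown consequence/role values and duplicate ids raise
    ``ValueError`` naming the offending row.
    """
    df = _read_table(path)
    required = ["id", "gene", "consequence", "role", "family_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: list[Variant] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            v = Variant(
                id=str(row.id).strip(),
                gene=str(row.gene).strip(),
                consequence=str(row.consequence).strip().lower(),
                role=str(row.role).strip().lower(),
                family_id=str(row.family_id).strip(),
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from None
        if v.id in seen:
            raise ValueError(f"{path}, line {i}: duplicate variant id {v.id}")
        seen.add(v.id)
        out.append(v)
    return out


def read_contexts(path: str | Path) -> dict[str, ExonContext]:
    """Read exon contexts keyed by variant id.

    Two on-disk layouts are accepted: a TSV with columns (id, exon_seq,
    upstream_intron_seq, downstream_flank_seq, strand, variant_offset), or a
    FASTA whose record sequence is upstream_intron + exon + flank and whose
    description carries ``up=N exon=N flank=N strand=S offset=N``.
    """
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        return _read_contexts_fasta(path)
    df = _read_table(path)
    required = [
        "id",
        "exon_seq",
        "upstream_intron_seq",
        "downstream_flank_seq",
        "strand",
        "variant_offset",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: dict[str, ExonContext] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        vid = str(row.id).strip()
        if vid in out:
            raise ValueError(f"{path}, line {i}: duplicate context for {vid}")
        out[vid] = ExonContext(
            exon_seq=str(row.exon_seq),
            upstream_intron_seq=str(row.upstream_intron_seq),
            downstream_flank_seq=str(row.downstream_flank_seq),
            strand=str(row.strand).strip(),
            variant_offset=int(row.variant_offset),
        )
    return out


_DESC_RE = re.compile(
    r"up=(\d+)\s+exon=(\d+)\s+flank=(\d+)\s+strand=([+-])\s+offset=(\d+)"
)


def _read_contexts_fasta(path: Path) -> dict[str, ExonContext]:
    out: dict[str, ExonContext] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _DESC_RE.search(rec.description)
        if m is None:
            raise ValueError(
                f"{path}: record {rec.id} lacks 'up= exon= flank= strand= offset=' "
                "part lengths in its description"
            )
        n_up, n_exon, n_flank, strand, offset = m.groups()
        n_up, n_exon, n_flank = int(n_up), int(n_exon), int(n_flank)
        seq = str(rec.seq).upper()
        if len(seq) != n_up + n_exon + n_flank:
            raise ValueError(
                f"{path}: record {rec.id} length {len(seq)} != up+exon+flank "
                f"{n_up + n_exon + n_flank}"
            )
        out[rec.id] = ExonContext(
            exon_seq=seq[n_up : n_up + n_exon],
            upstream_intron_seq=seq[:n_up],
            downstream_flank_seq=seq[n_up + n_exon :],
            strand=strand,
            variant_offset=int(offset),
        )
    return out


def write_contexts_fasta(contexts: Mapping[str, ExonContext], path: str | Path) -> None:
    with open(path, "w") as fh:
        for vid, ctx in contexts.items():
            desc = (
                f"up={len(ctx.upstream_intron_seq)} exon={len(ctx.exon_seq)} "
                f"flank={len(ctx.downstream_flank_seq)} strand={ctx.strand} "
                f"offset={ctx.variant_offset}"
            )
            seq = ctx.upstream_intron_seq + ctx.exon_seq + ctx.downstream_flank_seq
            fh.write(f">{vid} {desc}\n{seq}\n")


def filter_eligible(
    variants: Iterable[Variant], contexts: Mapping[str, ExonContext]
) -> list[Variant]:
    """Apply the screen's eligibility filter: test exon <= 115 nt and at
    least 50 nt of retained upstream intron.  Order-preserving; every
    variant must have a context."""
    out = []
    for v in variants:
        if v.id not in contexts:
            raise ValueError(f"no exon context for variant {v.id}")
        ctx = contexts[v.id]
        ctx.check_ref(v)
        if ctx.is_eligible():
            out.append(v)
    return out


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a two-column TSV (set_name, gene) or a GMT file."""
    path = Path(path)
    sets: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets.setdefault(parts[0], set()).update(
                    g for g in parts[2:] if g
                )
    else:
        df = _read_table(path)
        if not {"set_name", "gene"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns set_name, gene")
        for name, grp in df.groupby("set_name", sort=False):
            sets[str(name)] = set(grp["gene"].astype(str))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return [GeneSet(name=n, genes=frozenset(g)) for n, g in sets.items()]


def read_external_scores(path: str | Path) -> dict[str, float]:
    """Read an externally computed per-variant score table (TSV: id, score).

    Variants listed more than once are averaged to a single value, matching
    how duplicated splicing-model predictions are collapsed.
    """
    df = _read_table(path)
    if not {"id", "score"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns id, score")
    df = df.assign(score=pd.to_numeric(df["score"], errors="raise"))
    return df.groupby("id", sort=False)["score"].mean().to_dict()
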