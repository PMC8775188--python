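"""Oligo library and three-exon minigene reporter design.

Each eligible variant yields a wild-type/mutant pair of 230-mer oligos:
a 180-nt genomic insert (upstream intron, test exon, 15-nt downstream
flank) bracketed by 25-nt primer arms.  Each oligo is cloned into three
reporter backbones whose first exons differ in 5' splice-site strength
(MaxEntScan scores stored as metadata): a strong, an intermediate and a
weak donor, all sharing one terminal exon.  The spliced products the
assay can read out are enumerated per allele: the unspliced pre-mRNA
(input), the three-exon inclusion product, and the two-exon skipping
product.

The primer arms and the reporter backbone sequences shipped here are
synthetic stand-ins generated from a fixed seed (the real plasmid
sequences are not part of this package); every coordinate downstream is
derived from the recorded part map, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np

from .variants import (
    COMPLEMENT,
    DOWNSTREAM_FLANK_LEN,
    ExonContext,
    Variant,
)

__all__ = [
    "OligoPair",
    "ConstructDef",
    "Species",
    "SpeciesCatalog",
    "DualReference",
    "OLIGO_LEN",
    "INSERT_LEN",
    "ARM_LEN",
    "default_primer_arms",
    "default_constructs",
    "design_oligo",
    "build_construct",
    "enumerate_species",
    "build_dual_reference",
    "write_library_fasta",
    "write_part_map",
]

OLIGO_LEN = 230
INSERT_LEN = 180
ARM_LEN = 25

INPUT = "INPUT"
INCLUSION = "INCLUSION"
SKIP = "SKIP"

_FIXTURE_SEED = 20210915  # fixed: backbone/arm stand-ins are deterministic


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@lru_cache(maxsize=1)
def default_primer_arms() -> tuple[str, str]:
    """Synthetic 25-nt left/right primer arms (fixed seed)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    return _rand_dna(rng, ARM_LEN), _rand_dna(rng, ARM_LEN)


@dataclass(frozen=True)
class ConstructDef:
    """One minigene reporter backbone.

    ``five_prime_ss_score`` is the MaxEntScan strength of the first exon's
    donor site, carried as metadata (the score model itself is not part of
    this package).  ``skip_odds_boost`` is the simulator's multiplier on the
    skipping odds of the test exon in this backbone: stronger upstream
    donors favour skipping of the downstream test exon, so the strong
    construct gets the largest boost.
    """

    name: str
    first_exon_label: str
    five_prime_ss_score: float
    first_exon_seq: str
    intron1_seq: str  # partial intron downstream of the first exon
    intron2_seq: str  # partial intron upstream of the terminal exon
    terminal_exon_label: str
    terminal_exon_seq: str
    skip_odds_boost: float = 1.0


@lru_cache(maxsize=1)
def default_constructs() -> dict[str, ConstructDef]:
    """The three shipped reporter backbones.

    Donor strengths: strong = VCP exon 15 (10.15), intermediate = EMC7
    exon 3 (8.35), weak = VCP exon 10 (6.66).  Backbone sequences are
    synthetic, seeded stand-ins; the shared terminal exon is ACTN4 exon 16.
    """
    rng = np.random.default_rng(_FIXTURE_SEED + 1)
    terminal = _rand_dna(rng, 85)
    meta = [
        ("strong", "VCP exon 15", 10.15, 96, 2.5),
        ("intermediate", "EMC7 exon 3", 8.35, 90, 1.6),
        ("weak", "VCP exon 10", 6.66, 84, 1.0),
    ]
    out = {}
    for name, label, score, e1_len, boost in meta:
        out[name] = ConstructDef(
            name=name,
            first_exon_label=label,
            five_prime_ss_score=score,
            first_exon_seq=_rand_dna(rng, e1_len),
            intron1_seq=_rand_dna(rng, 60),
            intron2_seq=_rand_dna(rng, 50),
            terminal_exon_label="ACTN4 exon 16",
            terminal_exon_seq=terminal,
            skip_odds_boost=boost,
        )
    return out


@dataclass(frozen=True)
class OligoPair:
    """WT and mutant 230-mers plus the part map of the insert.

    ``layout`` maps part name -> (start, end) 0-based half-open spans over
    the 230-mer; ``variant_pos`` is the variant's offset in the oligo.
    """

    variant_id: str
    wt_seq: str
    mut_seq: str
    layout: dict[str, tuple[int, int]]
    variant_pos: int

    def __post_init__(self) -> None:
        if len(self.wt_seq) != OLIGO_LEN or len(self.mut_seq) != OLIGO_LEN:
            raise ValueError("oligo sequences must be 230 nt")
        diffs = [
            i for i, (a, b) in enumerate(zip(self.wt_seq, self.mut_seq)) if a != b
        ]
        if diffs != [self.variant_pos]:
            raise ValueError(
                f"{self.variant_id}: WT/mutant oligos must differ exactly at "
                f"variant_pos {self.variant_pos}, found diffs at {diffs}"
            )
        lo, hi = self.layout["exon"]
        if not lo <= self.variant_pos < hi:
            raise ValueError(f"{self.variant_id}: variant outside the exon span")

    def part(self, name: str, allele: str = "W") -> str:
        seq = self.wt_seq if allele == "W" else self.mut_seq
        lo, hi = self.layout[name]
        return seq[lo:hi]


def design_oligo(
    variant: Variant,
    context: ExonContext,
    arms: tuple[str, str] | None = None,
) -> OligoPair:
    """Assemble the WT/mutant oligo pair for one variant.

    The 180-nt insert is upstream intron + exon + 15-nt downstream flank;
    the upstream intron is trimmed from its distal (5') end so the three
    parts total exactly 180 nt.  An exon longer than 115 nt cannot fit and
    raises ``ValueError``.
    """
    left, right = arms if arms is not None else default_primer_arms()
    if len(left) != ARM_LEN or len(right) != ARM_LEN:
        raise ValueError("primer arms must be 25 nt")
    context.check_ref(variant)
    exon = context.exon_seq
    flank = context.downstream_flank_seq
    if len(flank) < DOWNSTREAM_FLANK_LEN:
        raise ValueError(
            f"{variant.id}: downstream flank shorter than {DOWNSTREAM_FLANK_LEN} nt"
        )
    flank = flank[:DOWNSTREAM_FLANK_LEN]
    need_intron = INSERT_LEN - len(exon) - DOWNSTREAM_FLANK_LEN
    up = context.upstream_intron_seq
    if need_intron < 50 or len(up) < need_intron:
        raise ValueError(
            f"{variant.id}: insert parts cannot fit {INSERT_LEN} nt "
            f"(exon {len(exon)} nt, upstream intron {len(up)} nt)"
        )
    up = up[len(up) - need_intron :]

    insert = up + exon + flank
    wt = left + insert + right
    exon_start = ARM_LEN + len(up)
    pos = exon_start + context.variant_offset
    alt = (
        variant.alt
        if context.strand == "+"
        else variant.alt.translate(COMPLEMENT)
    )
    mut = wt[:pos] + alt + wt[pos + 1 :]
    layout = {
        "left_arm": (0, ARM_LEN),
        "upstream_intron": (ARM_LEN, exon_start),
        "exon": (exon_start, exon_start + len(exon)),
        "downstream_flank": (
            exon_start + len(exon),
            exon_start + len(exon) + DOWNSTREAM_FLANK_LEN,
        ),
        "right_arm": (OLIGO_LEN - ARM_LEN, OLIGO_LEN),
    }
    return OligoPair(
        variant_id=variant.id,
        wt_seq=wt,
        mut_seq=mut,
        layout=layout,
        variant_pos=pos,
    )


# reporter part names in 5'->3' order; the middle parts come from the oligo
_REPORTER_PARTS = (
    "first_exon",
    "construct_intron1",
    "left_arm",
    "upstream_intron",
    "test_exon",
    "downstream_flank",
    "right_arm",
    "construct_intron2",
    "terminal_exon",
)
_EXON_PARTS = ("first_exon", "test_exon", "terminal_exon")


@dataclass(frozen=True)
class Reporter:
    """A full reporter pre-mRNA for one allele, with an ordered part map."""

    variant_id: str
    construct: str
    allele: str
    seq: str
    parts: tuple[tuple[str, int, int], ...]

    def span(self, name: str) -> tuple[int, int]:
        for pname, lo, hi in self.parts:
            if pname == name:
                return lo, hi
        raise KeyError(name)

    def part_seq(self, name: str) -> str:
        lo, hi = self.span(name)
        return self.seq[lo:hi]


def build_construct(
    oligo: OligoPair, cdef: ConstructDef
) -> tuple[Reporter, Reporter]:
    """Concatenate a reporter pre-mRNA for each allele of an oligo pair."""
    out = []
    for allele, oseq in (("W", oligo.wt_seq), ("M", oligo.mut_seq)):
        segs = {
            "first_exon": cdef.first_exon_seq,
            "construct_intron1": cdef.intron1_seq,
            "left_arm": oligo.part("left_arm", allele),
            "upstream_intron": oligo.part("upstream_intron", allele),
            "test_exon": oligo.part("exon", allele),
            "downstream_flank": oligo.part("downstream_flank", allele),
            "right_arm": oligo.part("right_arm", allele),
            "construct_intron2": cdef.intron2_seq,
            "terminal_exon": cdef.terminal_exon_seq,
        }
        parts = []
        pos = 0
        for name in _REPORTER_PARTS:
            parts.append((name, pos, pos + len(segs[name])))
            pos += len(segs[name])
        out.append(
            Reporter(
                variant_id=oligo.variant_id,
                construct=cdef.name,
                allele=allele,
                seq="".join(segs[n] for n in _REPORTER_PARTS),
                parts=tuple(parts),
            )
        )
    return out[0], out[1]


@dataclass(frozen=True)
class Species:
    """One transcript species: its sequence, exon-exon junction positions
    (offsets in the species sequence where two exons abut) and, where the
    species retains the test exon, the variant's offset."""

    variant_id: str
    construct: str
    allele: str
    name: str  # INPUT | INCLUSION | SKIP
    seq: str
    junctions: tuple[int, ...]
    variant_pos: int | None


@dataclass(frozen=True)
class SpeciesCatalog:
    variant_id: str
    construct: str
    species: tuple[Species, ...]

    def get(self, allele: str, name: str) -> Species:
        for sp in self.species:
            if sp.allele == allele and sp.name == name:
                return sp
        raise KeyError((allele, name))

    def per_allele(self, allele: str) -> list[Species]:
        return [sp for sp in self.species if sp.allele == allele]


def enumerate_species(oligo: OligoPair, cdef: ConstructDef) -> SpeciesCatalog:
    """Enumerate the {input, inclusion, skip} species for both alleles.

    Inclusion and skip sequences are obtained by excising the annotated
    introns from the reporter part map; the species universe is fixed to
    these three (cryptic events are out of scope).
    """
    reporters = build_construct(oligo, cdef)
    species: list[Species] = []
    for rep in reporters:
        e1 = rep.part_seq("first_exon")
        ex = rep.part_seq("test_exon")
        e3 = rep.part_seq("terminal_exon")
        exon_lo, _ = rep.span("test_exon")
        var_off_in_exon = oligo.variant_pos - oligo.layout["exon"][0]
        species.append(
            Species(
                rep.variant_id,
                rep.construct,
                rep.allele,
                INPUT,
                rep.seq,
                junctions=(),
                variant_pos=exon_lo + var_off_in_exon,
            )
        )
        species.append(
            Species(
                rep.variant_id,
                rep.construct,
                rep.allele,
                INCLUSION,
                e1 + ex + e3,
                junctions=(len(e1), len(e1) + len(ex)),
                variant_pos=len(e1) + var_off_in_exon,
            )
        )
        species.append(
            Species(
                rep.variant_id,
                rep.construct,
                rep.allele,
                SKIP,
                e1 + e3,
                junctions=(len(e1),),
                variant_pos=None,
            )
        )
    return SpeciesCatalog(oligo.variant_id, cdef.name, tuple(species))


@dataclass(frozen=True)
class DualReference:
    """Reference and variant-substituted sequences spanning the exon
    upstream of the variant exon through the exon downstream of it, for
    amplicon-validation alignment."""

    reference_seq: str
    variant_substituted_seq: str

    def __post_init__(self) -> None:
        diffs = [
            i
            for i, (a, b) in enumerate(
                zip(self.reference_seq, self.variant_substituted_seq)
            )
            if a != b
        ]
        if len(self.reference_seq) != len(self.variant_substituted_seq) or len(
            diffs
        ) != 1:
            raise ValueError(
                "dual reference sequences must be equal length and differ at "
                "exactly one position"
            )


def build_dual_reference(span_seq: str, variant_pos: int, ref: str, alt: str) -> DualReference:
    """Build the reference / variant-substituted sequence pair for one SNV.

    ``variant_pos`` is 0-based within ``span_seq``; the base there must
    equal ``ref``.
    """
    span_seq = span_seq.upper()
    if not 0 <= variant_pos < len(span_seq):
        raise ValueError(
            f"variant position {variant_pos} outside supplied span of length "
            f"{len(span_seq)}"
        )
    if span_seq[variant_pos] != ref.upper():
        raise ValueError(
            f"span base {span_seq[variant_pos]!r} at {variant_pos} does not "
            f"match stated ref allele {ref!r}"
        )
    alt_seq = span_seq[:variant_pos] + alt.upper() + span_seq[variant_pos + 1 :]
    return DualReference(span_seq, alt_seq)


def write_library_fasta(oligos: Iterable[OligoPair], path: str | Path) -> None:
    """Write the designed oligo library (one record per allele)."""
    with open(path, "w") as fh:
        for o in oligos:
            fh.write(f">{o.variant_id}|W\n{o.wt_seq}\n")
            fh.write(f">{o.variant_id}|M\n{o.mut_seq}\n")


def write_part_map(reporters: Iterable[Reporter], path: str | Path) -> None:
    """BED-like TSV of part spans (0-based half-open) per reporter."""
    with open(path, "w") as fh:
        fh.write("reporter\tpart\tstart\tend\n")
        for rep in reporters:
            rid = f"{rep.variant_id}|{rep.construct}|{rep.allele}"
            for name, lo, hi in rep.parts:
                fh.write(f"{rid}\t{name}\t{lo}\t{hi}\n")
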