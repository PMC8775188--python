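"""Read-to-species assignment and four-count tabulation.

The counting scheme treats each variant's wild-type/mutant species pair as
its own reference unit.  Classification is exact-window scanning with
mismatch counting against the enumerated species sequences — no heuristic
aligner is involved, which is adequate because the species are short and
fully enumerated.  Input-library reads may only be assigned to the
unspliced pre-mRNA species (split/junction reads in the input are
discarded with an explicit reason); spliced-output reads may only be
assigned to the inclusion or skipping products.

Uniqueness mirrors unique-mapping filters: a read is assigned only when
its best-scoring window beats every runner-up window by at least one
mismatch.  Reads that cannot resolve the allele (for example a read lying
entirely inside the shared terminal exon) are ambiguous.  The skipping
product carries no insert-derived sequence at all, so skip reads resolve
the species but neither the allele nor the variant; they are tallied per
construct as diagnostics and never enter the four counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import INCLUSION, INPUT, SKIP, SpeciesCatalog
from .variants import revcomp

__all__ = [
    "RefRecord",
    "PairedReference",
    "SpeciesIndex",
    "ReadAssignment",
    "build_paired_reference",
    "classify_read",
    "classify_fastq",
    "count_species",
    "count_libraries",
    "count_screen",
    "QuantResult",
]

AMBIGUOUS = "ambiguous"
TOO_MANY_MISMATCHES = "too_many_mismatches"
SPLIT_IN_INPUT = "split_in_input"
NO_JUNCTION_SUPPORT = "no_junction_support"

DEFAULT_MAX_MISMATCHES = 3

_VALID_SPECIES = {"input": {INPUT}, "output": {INCLUSION, SKIP}}


@dataclass(frozen=True)
class RefRecord:
    """One reference species record; ``ref_id`` round-trips through FASTA."""

    variant: str
    construct: str
    allele: str
    species: str
    seq: str

    @property
    def ref_id(self) -> str:
        return f"{self.variant}|{self.construct}|{self.allele}|{self.species}"

    @classmethod
    def parse_id(cls, ref_id: str, seq: str) -> "RefRecord":
        parts = ref_id.split("|")
        if len(parts) != 4:
            raise ValueError(f"malformed reference id {ref_id!r}")
        return cls(*parts, seq=seq)


class PairedReference:
    """All species records, grouped into per-(variant, construct) units."""

    def __init__(self, records: Sequence[RefRecord]):
        self.records = list(records)
        self.units: dict[tuple[str, str], list[RefRecord]] = {}
        seen_ids = set()
        for rec in self.records:
            if rec.ref_id in seen_ids:
                raise ValueError(f"duplicate reference record {rec.ref_id}")
            seen_ids.add(rec.ref_id)
            self.units.setdefault((rec.variant, rec.construct), []).append(rec)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.units)

    @property
    def constructs(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.construct)
        return list(seen)

    def subset(self, construct: str) -> "PairedReference":
        """Records of one reporter construct (each construct is sequenced
        as its own library, so classification is scoped per construct)."""
        recs = [r for r in self.records if r.construct == construct]
        if not recs:
            raise KeyError(f"no records for construct {construct!r}")
        return PairedReference(recs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.ref_id}\n{rec.seq}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "PairedReference":
        records = []
        with open(path) as fh:
            rid, chunks = None, []
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if rid is not None:
                        records.append(RefRecord.parse_id(rid, "".join(chunks)))
                    rid, chunks = line[1:].split()[0], []
                else:
                    chunks.append(line)
            if rid is not None:
                records.append(RefRecord.parse_id(rid, "".join(chunks)))
        return cls(records)


def build_paired_reference(
    catalogs: Iterable[SpeciesCatalog],
) -> PairedReference:
    """Collect every enumerated species into one paired reference."""
    records = []
    seen = set()
    for cat in catalogs:
        key = (cat.variant_id, cat.construct)
        if key in seen:
            raise ValueError(f"duplicate catalog for {key}")
        seen.add(key)
        for sp in cat.species:
            records.append(
                RefRecord(sp.variant_id, sp.construct, sp.allele, sp.name, sp.seq)
            )
    return PairedReference(records)


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of classifying one read (or read pair).

    ``reason`` is ``None`` for assigned reads.  For skip-product reads the
    species is resolved but ``variant`` and ``allele`` are ``None`` — the
    product contains no allele-tagging sequence.
    """

    read_id: str
    library: str
    variant: str | None
    construct: str | None
    allele: str | None
    species: str | None
    mismatches: int | None
    reason: str | None

    @property
    def assigned(self) -> bool:
        return self.reason is None


class SpeciesIndex:
    """K-mer seeded exact-window classifier over a paired reference.

    Identical sequences (the skip products of every variant in a
    construct) are collapsed into one indexed entry whose record list
    preserves all contributing species records.  Seeds tile the read; a
    seed whose hit list exceeds ``max_seed_hits`` (a k-mer from shared
    backbone sequence) is uninformative and skipped unless no informative
    seed exists.
    """

    def __init__(
        self,
        reference: PairedReference,
        k: int = 25,
        max_seed_hits: int = 64,
    ):
        self.reference = reference
        self.k = k
        self.max_seed_hits = max_seed_hits
        self.seqs: list[str] = []
        self.seq_bytes: list[np.ndarray] = []
        self.rec_lists: list[list[RefRecord]] = []
        by_seq: dict[str, int] = {}
        for rec in reference.records:
            uid = by_seq.get(rec.seq)
            if uid is None:
                uid = len(self.seqs)
                by_seq[rec.seq] = uid
                self.seqs.append(rec.seq)
                self.seq_bytes.append(
                    np.frombuffer(rec.seq.encode(), dtype=np.uint8)
                )
                self.rec_lists.append([])
            self.rec_lists[uid].append(rec)
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for uid, seq in enumerate(self.seqs):
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append((uid, pos))
        # species is constant within a collapsed entry (lengths/contents
        # differ between species kinds), so cache it per uid
        self.uid_species = [recs[0].species for recs in self.rec_lists]

    def _seed_offsets(self, read_len: int) -> list[int]:
        offs = list(range(0, read_len - self.k + 1, self.k))
        if offs and offs[-1] != read_len - self.k:
            offs.append(read_len - self.k)
        return offs

    def _candidates(self, seq: str) -> set[tuple[int, int]]:
        k = self.k
        cands: set[tuple[int, int]] = set()
        fallback: list[tuple[int, int]] | None = None
        fallback_off = 0
        for off in self._seed_offsets(len(seq)):
            hits = self.kmers.get(seq[off : off + k])
            if not hits:
                continue
            if len(hits) > self.max_seed_hits:
                if fallback is None or len(hits) < len(fallback):
                    fallback, fallback_off = hits, off
                continue
            for uid, pos in hits:
                start = pos - off
                if 0 <= start <= len(self.seqs[uid]) - len(seq):
                    cands.add((uid, start))
        if not cands and fallback is not None:
            for uid, pos in fallback:
                start = pos - fallback_off
                if 0 <= start <= len(self.seqs[uid]) - len(seq):
                    cands.add((uid, start))
        return cands

    def _mismatches(
        self, seq: str, read_arr: np.ndarray | None, uid: int, start: int
    ) -> tuple[int, np.ndarray | None]:
        window = self.seqs[uid][start : start + len(seq)]
        if window == seq:
            return 0, read_arr
        if read_arr is None:
            read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        ref = self.seq_bytes[uid][start : start + len(seq)]
        return int(np.count_nonzero(read_arr != ref)), read_arr

    def classify(
        self,
        seq: str,
        library: str,
        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    ) -> tuple[str | None, str | None, str | None, str | None, int | None, str | None]:
        """Classify one read; returns (variant, construct, allele, species,
        mismatches, reason)."""
        valid = _VALID_SPECIES[library]
        cands = self._candidates(seq)
        read_arr: np.ndarray | None = None
        best = None  # (mm, uid, start)
        second_mm = None
        invalid_hit = False
        for uid, start in cands:
            if self.uid_species[uid] not in valid:
                mm, read_arr = self._mismatches(seq, read_arr, uid, start)
                if mm <= max_mismatches:
                    invalid_hit = True
                continue
            mm, read_arr = self._mismatches(seq, read_arr, uid, start)
            if best is None or mm < best[0]:
                second_mm = None if best is None else best[0]
                best = (mm, uid, start)
            elif second_mm is None or mm < second_mm:
                second_mm = mm
        if best is None or best[0] > max_mismatches:
            if invalid_hit:
                reason = SPLIT_IN_INPUT if library == "input" else NO_JUNCTION_SUPPORT
            elif best is None and not cands:
                reason = TOO_MANY_MISMATCHES
            else:
                reason = TOO_MANY_MISMATCHES
            return None, None, None, None, None, reason
        if second_mm is not None and second_mm - best[0] < 1:
            return None, None, None, None, None, AMBIGUOUS
        recs = self.rec_lists[best[1]]
        variants = {r.variant for r in recs}
        alleles = {r.allele for r in recs}
        species = recs[0].species
        construct = recs[0].construct
        variant = recs[0].variant if len(variants) == 1 else None
        allele = recs[0].allele if len(alleles) == 1 else None
        if species != SKIP and (variant is None or allele is None):
            return None, None, None, None, None, AMBIGUOUS
        return variant, construct, allele, species, best[0], None


def classify_read(
    read_seq: str,
    unit_records: Sequence[RefRecord],
    library: str = "output",
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    read_id: str = "read",
) -> ReadAssignment:
    """Classify one read against a single reference unit by brute-force
    scanning of every window of every species record.

    This is the reference semantics of the classifier; the
    :class:`SpeciesIndex` path is the scalable equivalent over all units.
    """
    valid = _VALID_SPECIES[library]
    arr = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    L = len(read_seq)
    scored: list[tuple[int, int, RefRecord]] = []  # (best_mm, n_best_windows, rec)
    invalid_hit = False
    for rec in unit_records:
        if L > len(rec.seq):
            continue
        ref = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        wins = np.lib.stride_tricks.sliding_window_view(ref, L)
        mism = (wins != arr).sum(axis=1)
        best_mm = int(mism.min())
        if rec.species not in valid:
            if best_mm <= max_mismatches:
                invalid_hit = True
            continue
        scored.append((best_mm, int((mism == best_mm).sum()), rec))

    def unassigned(reason):
        return ReadAssignment(read_id, library, None, None, None, None, None, reason)

    if not scored or min(s[0] for s in scored) > max_mismatches:
        if invalid_hit:
            return unassigned(
                SPLIT_IN_INPUT if library == "input" else NO_JUNCTION_SUPPORT
            )
        return unassigned(TOO_MANY_MISMATCHES)
    best_mm = min(s[0] for s in scored)
    best = [s for s in scored if s[0] == best_mm]
    if any(n > 1 for _, n, _ in best):
        return unassigned(AMBIGUOUS)  # repeated best window within one species
    # identical sequences (the two alleles' skip products) are one hit
    best_seqs = {rec.seq for _, _, rec in best}
    if len(best_seqs) > 1:
        return unassigned(AMBIGUOUS)
    runner = [s[0] for s in scored if s[2].seq not in best_seqs]
    if runner and min(runner) - best_mm < 1:
        return unassigned(AMBIGUOUS)
    recs = [rec for _, _, rec in best]
    variants = {r.variant for r in recs}
    alleles = {r.allele for r in recs}
    species = recs[0].species
    variant = recs[0].variant if len(variants) == 1 else None
    allele = recs[0].allele if len(alleles) == 1 else None
    if species != SKIP and (variant is None or allele is None):
        return unassigned(AMBIGUOUS)
    return ReadAssignment(
        read_id, library, variant, recs[0].construct, allele, species, best_mm, None
    )


def _merge_pair(a1: ReadAssignment, a2: ReadAssignment) -> ReadAssignment:
    """Reconcile mate assignments: both mates must agree where both resolve."""
    if a1.assigned and a2.assigned:
        same = (
            a1.variant == a2.variant
            and a1.construct == a2.construct
            and a1.allele == a2.allele
            and a1.species == a2.species
        )
        if same:
            return ReadAssignment(
                a1.read_id,
                a1.library,
                a1.variant,
                a1.construct,
                a1.allele,
                a1.species,
                (a1.mismatches or 0) + (a2.mismatches or 0),
                None,
            )
        return ReadAssignment(
            a1.read_id, a1.library, None, None, None, None, None, AMBIGUOUS
        )
    if a1.assigned and a2.reason == AMBIGUOUS:
        return a1
    if a2.assigned and a1.reason == AMBIGUOUS:
        return ReadAssignment(
            a1.read_id,
            a1.library,
            a2.variant,
            a2.construct,
            a2.allele,
            a2.species,
            a2.mismatches,
            None,
        )
    return a1 if not a1.assigned else a2


def classify_fastq(
    path: str | Path,
    library: str,
    index: SpeciesIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    mate_path: str | Path | None = None,
) -> Iterator[ReadAssignment]:
    """Stream a FASTQ library (optionally with a mate file) through the
    classifier, yielding one :class:`ReadAssignment` per fragment."""
    with open(path) as fh1:
        reads1 = FastqGeneralIterator(fh1)
        if mate_path is None:
            for rid, seq, _ in reads1:
                yield ReadAssignment(
                    rid.split()[0],
                    library,
                    *index.classify(seq.upper(), library, max_mismatches),
                )
        else:
            with open(mate_path) as fh2:
                for (rid, s1, _), (rid2, s2, _) in zip(
                    reads1, FastqGeneralIterator(fh2)
                ):
                    rid = rid.split()[0]
                    if rid != rid2.split()[0]:
                        raise ValueError(
                            f"mate files out of sync at {rid} vs {rid2}"
                        )
                    a1 = ReadAssignment(
                        rid,
                        library,
                        *index.classify(s1.upper(), library, max_mismatches),
                    )
                    a2 = ReadAssignment(
                        rid,
                        library,
                        *index.classify(
                            revcomp(s2.upper()), library, max_mismatches
                        ),
                    )
                    yield _merge_pair(a1, a2)


@dataclass
class QuantResult:
    """Four-count table plus diagnostics from classifying both libraries."""

    counts: pd.DataFrame  # variant, construct, mo, mi, wo, wi
    skip_counts: pd.DataFrame  # construct, skip (allele/variant unresolvable)
    unassigned: pd.DataFrame  # library, reason, n

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def count_species(
    assignments: Iterable[ReadAssignment],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> QuantResult:
    """Tabulate assignments into the four counts per (variant, construct).

    ``mo``/``wo`` are allele-resolved inclusion-product counts from the
    output library; ``mi``/``wi`` are allele-resolved input counts.  Skip
    reads and unassigned reads are tallied separately.  ``pairs`` seeds
    zero rows so unobserved units still appear.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    if pairs is not None:
        for p in pairs:
            counts[tuple(p)] = [0, 0, 0, 0]
    skip: dict[str, int] = {}
    unassigned: dict[tuple[str, str], int] = {}
    for a in assignments:
        if not a.assigned:
            key = (a.library, a.reason)
            unassigned[key] = unassigned.get(key, 0) + 1
            continue
        if a.species == SKIP:
            skip[a.construct] = skip.get(a.construct, 0) + 1
            continue
        row = counts.setdefault((a.variant, a.construct), [0, 0, 0, 0])
        if a.library == "output" and a.species == INCLUSION:
            row[0 if a.allele == "M" else 2] += 1
        elif a.library == "input" and a.species == INPUT:
            row[1 if a.allele == "M" else 3] += 1
    counts_df = pd.DataFrame(
        [
            {"variant": v, "construct": c, "mo": r[0], "mi": r[1], "wo": r[2], "wi": r[3]}
            for (v, c), r in counts.items()
        ],
        columns=["variant", "construct", "mo", "mi", "wo", "wi"],
    )
    skip_df = pd.DataFrame(
        [{"construct": c, "skip": n} for c, n in sorted(skip.items())],
        columns=["construct", "skip"],
    )
    un_df = pd.DataFrame(
        [
            {"library": lib, "reason": reason, "n": n}
            for (lib, reason), n in sorted(unassigned.items())
        ],
        columns=["library", "reason", "n"],
    )
    return QuantResult(counts_df, skip_df, un_df)


def count_libraries(
    index: SpeciesIndex,
    input_fastq: str | Path,
    output_fastq: str | Path,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    input_mate: str | Path | None = None,
    output_mate: str | Path | None = None,
) -> QuantResult:
    """Classify one construct's input/output libraries and tabulate,
    streaming (no assignment list is materialised — suitable for
    multi-million-read libraries)."""
    def stream():
        yield from classify_fastq(
            input_fastq, "input", index, max_mismatches, input_mate
        )
        yield from classify_fastq(
            output_fastq, "output", index, max_mismatches, output_mate
        )

    return count_species(stream(), pairs=index.reference.pairs)


def count_screen(
    reference: PairedReference,
    libraries: Mapping[str, Mapping[str, str | Path]],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    k: int = 25,
) -> QuantResult:
    """Quantify a whole screen: one input/output library pair per
    construct, each classified against that construct's records only
    (insert sequence is shared across backbones, so a mixed reference
    could not attribute insert-interior reads to a construct).

    ``libraries`` maps construct name -> dict with keys ``input`` and
    ``output`` (optionally ``input_R2`` / ``output_R2`` for mates).
    """
    parts: list[QuantResult] = []
    for cname, paths in libraries.items():
        index = SpeciesIndex(reference.subset(cname), k=k)
        parts.append(
            count_libraries(
                index,
                paths["input"],
                paths["output"],
                max_mismatches=max_mismatches,
                input_mate=paths.get("input_R2"),
                output_mate=paths.get("output_R2"),
            )
        )
    counts = pd.concat([p.counts for p in parts], ignore_index=True)
    skip = pd.concat([p.skip_counts for p in parts], ignore_index=True)
    un = (
        pd.concat([p.unassigned for p in parts], ignore_index=True)
        .groupby(["library", "reason"], as_index=False)["n"]
        .sum()
        if any(len(p.unassigned) for p in parts)
        else parts[0].unassigned
    )
    return QuantResult(counts, skip, un)
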