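"""Paired-reference construction and junction-aware read classification."""

import numpy as np
import pandas as pd
import pytest

from mapsy import pipeline, quantify, simulate
from mapsy.design import default_constructs
from mapsy.quantify import (
    AMBIGUOUS,
    NO_JUNCTION_SUPPORT,
    PairedReference,
    RefRecord,
    SPLIT_IN_INPUT,
    SpeciesIndex,
    build_paired_reference,
    classify_read,
    count_species,
)


@pytest.fixture(scope="module")
def reference(small_library):
    _, _, catalogs = small_library
    return build_paired_reference(catalogs.values())


@pytest.fixture(scope="module")
def strong_unit(small_library, reference):
    (vid, _), = [k for k in reference.units if k[1] == "strong"][:1],
    return vid, reference.units[(vid, "strong")]


class TestPairedReference:
    def test_record_arithmetic(self, small_library, reference):
        _, oligos, _ = small_library
        n_var = len(oligos)
        # 3 constructs x 2 alleles x 3 species per variant
        assert len(reference.records) == n_var * 18
        assert len(reference.units) == n_var * 3

    def test_id_round_trip(self, reference, tmp_path):
        p = tmp_path / "ref.fasta"
        reference.to_fasta(p)
        back = PairedReference.from_fasta(p)
        assert back.records == reference.records

    def test_allele_pairs_differ_at_one_position(self, reference):
        for (vid, cname), recs in reference.units.items():
            by = {(r.allele, r.species): r.seq for r in recs}
            for species in ("INPUT", "INCLUSION"):
                w, m = by[("W", species)], by[("M", species)]
                assert sum(a != b for a, b in zip(w, m)) == 1
            assert by[("W", "SKIP")] == by[("M", "SKIP")]

    def test_duplicate_catalog_rejected(self, small_library):
        _, _, catalogs = small_library
        cats = list(catalogs.values())
        with pytest.raises(ValueError, match="duplicate"):
            build_paired_reference(cats + cats[:1])

    def test_subset_by_construct(self, reference):
        sub = reference.subset("weak")
        assert {r.construct for r in sub.records} == {"weak"}
        with pytest.raises(KeyError):
            reference.subset("nonexistent")


def _exact_read(species, start, length=150):
    return species.seq[start : start + length]


class TestClassifyRead:
    def test_skip_junction_read_assigned_to_skip(self, small_library, reference):
        _, _, catalogs = small_library
        (vid, cname) = next(iter(catalogs))
        cat = catalogs[(vid, cname)]
        skip = cat.get("W", "SKIP")
        j = skip.junctions[0]
        read = _exact_read(skip, max(0, j - 60), 120)
        a = classify_read(read, reference.units[(vid, cname)], "output")
        assert a.assigned and a.species == "SKIP"
        assert a.allele is None  # no allele information in the skip product

    def test_terminal_exon_read_ambiguous(self, small_library, reference):
        _, _, catalogs = small_library
        (vid, cname) = next(iter(catalogs))
        cat = catalogs[(vid, cname)]
        inp = cat.get("W", "INPUT")
        read = inp.seq[-60:]  # entirely inside the shared terminal exon
        a = classify_read(read, reference.units[(vid, cname)], "input")
        assert not a.assigned and a.reason == AMBIGUOUS

    def test_variant_covering_read_resolves_allele(self, small_library, reference):
        _, _, catalogs = small_library
        for (vid, cname), cat in list(catalogs.items())[:4]:
            for allele in "WM":
                sp = cat.get(allele, "INPUT")
                start = max(0, sp.variant_pos - 75)
                read = _exact_read(sp, start)
                a = classify_read(read, reference.units[(vid, cname)], "input")
                assert a.assigned and (a.allele, a.species) == (allele, "INPUT")
                assert a.mismatches == 0

    def test_junction_read_in_input_is_split(self, small_library, reference):
        _, _, catalogs = small_library
        (vid, cname) = next(iter(catalogs))
        inc = catalogs[(vid, cname)].get("W", "INCLUSION")
        read = _exact_read(inc, max(0, inc.variant_pos - 75))
        a = classify_read(read, reference.units[(vid, cname)], "input")
        assert a.reason == SPLIT_IN_INPUT

    def test_unspliced_read_in_output_lacks_junction_support(
        self, small_library, reference
    ):
        _, _, catalogs = small_library
        (vid, cname) = next(iter(catalogs))
        inp = catalogs[(vid, cname)].get("W", "INPUT")
        read = _exact_read(inp, max(0, inp.variant_pos - 75))
        a = classify_read(read, reference.units[(vid, cname)], "output")
        assert a.reason == NO_JUNCTION_SUPPORT

    def test_mismatch_tolerance_boundary(self, small_library, reference):
        _, _, catalogs = small_library
        (vid, cname) = next(iter(catalogs))
        sp = catalogs[(vid, cname)].get("M", "INPUT")
        start = max(0, sp.variant_pos - 75)
        read = list(_exact_read(sp, start))
        # 4 substitutions away from the variant column exceeds the default 3
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        positions = [i for i in (5, 20, 35, 50) if start + i != sp.variant_pos]
        for i in positions[:4]:
            read[i] = flip[read[i]]
        a = classify_read("".join(read), reference.units[(vid, cname)], "input")
        assert a.reason == quantify.TOO_MANY_MISMATCHES

    def test_index_agrees_with_brute_force(self, small_library, reference, rng):
        """The seeded index and exhaustive per-unit scanning give identical
        assignments on reads sampled from every species."""
        _, _, catalogs = small_library
        for cname in default_constructs():
            index = SpeciesIndex(reference.subset(cname))
            for (vid, cn), cat in catalogs.items():
                if cn != cname:
                    continue
                for sp in cat.species:
                    start = (
                        max(0, sp.variant_pos - 75)
                        if sp.variant_pos is not None
                        else int(rng.integers(0, len(sp.seq) - 150 + 1))
                    )
                    read = _exact_read(sp, start)
                    for lib in ("input", "output"):
                        brute = classify_read(read, reference.units[(vid, cn)], lib)
                        fast = index.classify(read, lib)
                        assert (brute.species, brute.reason) == (fast[3], fast[5])
                        if brute.species != "SKIP":
                            # the skip product is shared across variants, so
                            # the global index cannot attribute it; allele-
                            # bearing species must agree exactly
                            assert (brute.variant, brute.allele) == (
                                fast[0], fast[2]
                            )


class TestCounting:
    def test_empty_assignments_zero_table(self, reference):
        res = count_species([], pairs=reference.pairs)
        assert len(res.counts) == len(reference.pairs)
        assert (res.counts[["mo", "mi", "wo", "wi"]] == 0).all().all()

    def test_hand_built_eight_reads(self):
        mk = lambda lib, allele, species: quantify.ReadAssignment(
            f"r{lib}{allele}{species}", lib, "v1", "weak", allele, species, 0, None
        )
        assignments = []
        for allele in "WM":
            assignments += [mk("input", allele, "INPUT")] * 2
            assignments += [mk("output", allele, "INCLUSION")] * 2
        res = count_species(assignments)
        row = res.counts.iloc[0]
        assert (row.mo, row.mi, row.wo, row.wi) == (2, 2, 2, 2)

    def test_conservation_and_order_invariance(self, small_library, tmp_path):
        variants, contexts = simulate.synthetic_cohort(4, seed=77)
        cfg = simulate.SimConfig(
            n_variants=4, depth_input=150, depth_output=150,
            error_rate=0.002, seed=77,
        )
        _, _, catalogs = pipeline.design_library(variants, contexts)
        truth = simulate.sample_truth(cfg, variant_ids=[v.id for v in variants])
        paths = simulate.simulate_reads(truth, catalogs, cfg, tmp_path)
        ref = build_paired_reference(catalogs.values())
        assignments = []
        for cname, lib in paths["libraries"].items():
            index = SpeciesIndex(ref.subset(cname))
            assignments += list(
                quantify.classify_fastq(lib["input"], "input", index)
            )
            assignments += list(
                quantify.classify_fastq(lib["output"], "output", index)
            )
        n_sidecar = sum(1 for _ in open(paths["sidecar"])) - 1
        assert len(assignments) == n_sidecar  # every read appears exactly once
        res1 = count_species(assignments, pairs=ref.pairs)
        rng = np.random.default_rng(0)
        shuffled = list(assignments)
        rng.shuffle(shuffled)
        res2 = count_species(shuffled, pairs=ref.pairs)
        key = ["variant", "construct"]
        pd.testing.assert_frame_equal(
            res1.counts.sort_values(key).reset_index(drop=True),
            res2.counts.sort_values(key).reset_index(drop=True),
        )
        total = (
            res1.counts[["mo", "mi", "wo", "wi"]].to_numpy().sum()
            + res1.skip_counts["skip"].sum()
            + (res1.unassigned["n"].sum() if len(res1.unassigned) else 0)
        )
        assert total == n_sidecar

    def test_error_free_round_trip_matches_sidecar_exactly(self, tmp_path):
        variants, contexts = simulate.synthetic_cohort(6, seed=88)
        cfg = simulate.SimConfig(
            n_variants=6, depth_input=200, depth_output=200,
            error_rate=0.0, seed=88,
        )
        _, _, catalogs = pipeline.design_library(variants, contexts)
        truth = simulate.sample_truth(cfg, variant_ids=[v.id for v in variants])
        paths = simulate.simulate_reads(truth, catalogs, cfg, tmp_path)
        ref = build_paired_reference(catalogs.values())
        res = quantify.count_screen(ref, paths["libraries"])
        sc = pd.read_csv(paths["sidecar"], sep="\t")
        got = res.counts.set_index(["variant", "construct"]).sort_index()
        inp = (
            sc[sc.species == "INPUT"]
            .groupby(["variant", "construct", "allele"])
            .size()
            .unstack(fill_value=0)
        )
        inc = (
            sc[sc.species == "INCLUSION"]
            .groupby(["variant", "construct", "allele"])
            .size()
            .unstack(fill_value=0)
        )
        assert (got["mi"] == inp["M"].reindex(got.index, fill_value=0)).all()
        assert (got["wi"] == inp["W"].reindex(got.index, fill_value=0)).all()
        assert (got["mo"] == inc["M"].reindex(got.index, fill_value=0)).all()
        assert (got["wo"] == inc["W"].reindex(got.index, fill_value=0)).all()
        skip_truth = sc[sc.species == "SKIP"].groupby("construct").size()
        got_skip = res.skip_counts.set_index("construct")["skip"]
        assert got_skip.sort_index().equals(skip_truth.sort_index())

    def test_sidecar_agreement_with_errors(self, tmp_path):
        """With sequencing errors, assigned reads still agree with the
        truth sidecar except where an error hits the variant column."""
        variants, contexts = simulate.synthetic_cohort(4, seed=99)
        cfg = simulate.SimConfig(
            n_variants=4, depth_input=400, depth_output=400,
            error_rate=0.003, seed=99,
        )
        _, _, catalogs = pipeline.design_library(variants, contexts)
        truth = simulate.sample_truth(cfg, variant_ids=[v.id for v in variants])
        paths = simulate.simulate_reads(truth, catalogs, cfg, tmp_path)
        ref = build_paired_reference(catalogs.values())
        sc = pd.read_csv(paths["sidecar"], sep="\t").set_index("read_id")
        n = agree = 0
        for cname, lib in paths["libraries"].items():
            index = SpeciesIndex(ref.subset(cname))
            for key in ("input", "output"):
                for a in quantify.classify_fastq(lib[key], key, index):
                    if not a.assigned or a.species == "SKIP":
                        continue
                    row = sc.loc[a.read_id]
                    n += 1
                    agree += (
                        a.variant == row.variant and a.allele == row.allele
                        and a.species == row.species
                    )
        # per-read misassignment needs an error at the variant column:
        # rate error_rate * (prob the error changes ref into the other
        # allele's base) -- far below 1%
        assert n > 0
        assert agree / n > 0.99


class TestPairedEnd:
    def test_paired_reads_round_trip(self, tmp_path):
        variants, contexts = simulate.synthetic_cohort(3, seed=13)
        cfg = simulate.SimConfig(
            n_variants=3, depth_input=120, depth_output=120,
            error_rate=0.0, paired=True, seed=13,
        )
        _, _, catalogs = pipeline.design_library(variants, contexts)
        truth = simulate.sample_truth(cfg, variant_ids=[v.id for v in variants])
        paths = simulate.simulate_reads(truth, catalogs, cfg, tmp_path)
        ref = build_paired_reference(catalogs.values())
        res = quantify.count_screen(ref, paths["libraries"])
        sc = pd.read_csv(paths["sidecar"], sep="\t")
        n_inout = len(sc[sc.species != "SKIP"])
        assert res.counts[["mo", "mi", "wo", "wi"]].to_numpy().sum() == n_inout

    def test_disagreeing_mates_ambiguous(self):
        a1 = quantify.ReadAssignment("r", "output", "v1", "weak", "W", "INCLUSION", 0, None)
        a2 = quantify.ReadAssignment("r", "output", "v1", "weak", "M", "INCLUSION", 0, None)
        merged = quantify._merge_pair(a1, a2)
        assert merged.reason == AMBIGUOUS
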