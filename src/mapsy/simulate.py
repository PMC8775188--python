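"""Synthetic-data generation for the splicing-reporter screen.

Ground truth is expressed per (variant, construct) as the exon-inclusion
fraction of each allele among spliced output (``psi_wt``, ``psi_mut``), a
library-synthesis abundance bias between alleles, and a construct-dependent
multiplier on the skipping odds that emulates the observation that a strong
upstream donor amplifies skipping of the downstream test exon.  Counts are
drawn multinomially at fixed library size, so read totals are conserved
exactly per simulation; reads are drawn from the enumerated species
sequences with uniform substitution-only sequencing error.

The closed-form expected allelic imbalance under this model is
``log2(psi'_mut / psi'_wt)`` where ``psi' = psi / (psi + (1 - psi) * boost)``
is the inclusion fraction after the construct's skipping-odds boost; the
synthesis bias cancels because output counts are normalised by input counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    INCLUSION,
    INPUT,
    SKIP,
    ConstructDef,
    SpeciesCatalog,
    default_constructs,
)
from .variants import COMPLEMENT, ExonContext, Variant

__all__ = [
    "SimConfig",
    "sample_truth",
    "simulate_counts",
    "simulate_reads",
    "library_paths",
    "effective_inclusion",
    "true_imbalance",
    "synthetic_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    ``depth_input`` / ``depth_output`` are total reads per (variant,
    construct) per library; the default 4,000 corresponds to 2,000 reads
    per allele at unit synthesis bias.  ``effect_size`` is the magnitude of
    the log2 inclusion shift given to affected variants (mutant inclusion
    is lowered: splice-disrupting).  ``bias`` fixes the mutant:wildtype
    synthesis ratio; when ``None`` it is sampled log-normally with
    ``bias_sigma`` on the natural-log scale.  The seed fully determines
    every output.
    """

    n_variants: int = 200
    effect_fraction: float = 0.1
    effect_size: float = 1.0
    psi_wt_range: tuple[float, float] = (0.5, 0.9)
    bias: float | None = None
    bias_sigma: float = 0.25
    depth_input: int = 4000
    depth_output: int = 4000
    error_rate: float = 0.001
    read_length: int = 150
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        lo, hi = self.psi_wt_range
        if not (0 < lo <= hi < 1):
            raise ValueError("psi_wt_range must satisfy 0 < lo <= hi < 1")
        if self.bias is not None and self.bias <= 0:
            raise ValueError("bias must be positive")
        if min(self.depth_input, self.depth_output) < 0:
            raise ValueError("depths must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def effective_inclusion(psi: np.ndarray | float, boost: np.ndarray | float):
    """Inclusion fraction after multiplying the skipping odds by ``boost``."""
    return psi / (psi + (1.0 - psi) * boost)


def true_imbalance(psi_wt, psi_mut, boost):
    """Closed-form expected log2 mutant/wild-type splice ratio."""
    return np.log2(
        effective_inclusion(psi_mut, boost) / effective_inclusion(psi_wt, boost)
    )


def sample_truth(
    config: SimConfig,
    constructs: Mapping[str, ConstructDef] | None = None,
    variant_ids: Sequence[str] | None = None,
    effects: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Draw a ground-truth table, one row per (variant, construct).

    A ``config.effect_fraction`` share of variants is splice-disrupting:
    their mutant inclusion is lowered by ``effect_size`` on the log2 scale
    (clipped into (0, 1)).  Passing ``effects`` overrides the per-variant
    log2 shifts explicitly (positive = loss of inclusion), e.g. to couple
    effects to enhancer-score changes.
    """
    if constructs is None:
        constructs = default_constructs()
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    if variant_ids is None:
        variant_ids = [f"v{i + 1:05d}" for i in range(n)]
    elif len(variant_ids) != n:
        raise ValueError("variant_ids length must equal config.n_variants")
    lo, hi = config.psi_wt_range
    psi_wt = rng.uniform(lo, hi, n)
    if effects is None:
        affected = rng.random(n) < config.effect_fraction
        shift = np.where(affected, config.effect_size, 0.0)
    else:
        shift = np.asarray(effects, dtype=float)
        if shift.shape != (n,):
            raise ValueError("effects must have one value per variant")
    psi_mut = np.clip(psi_wt * np.power(2.0, -shift), 1e-6, 1 - 1e-6)
    if config.bias is not None:
        bias = np.full(n, float(config.bias))
    else:
        bias = np.exp(rng.normal(0.0, config.bias_sigma, n))

    rows = []
    for cname, cdef in constructs.items():
        rows.append(
            pd.DataFrame(
                {
                    "variant": variant_ids,
                    "construct": cname,
                    "psi_wt": psi_wt,
                    "psi_mut": psi_mut,
                    "bias": bias,
                    "skip_boost": cdef.skip_odds_boost,
                    "depth_input": config.depth_input,
                    "depth_output": config.depth_output,
                    "true_effect": psi_mut != psi_wt,
                }
            )
        )
    truth = pd.concat(rows, ignore_index=True)
    truth["true_imbalance"] = true_imbalance(
        truth["psi_wt"].to_numpy(),
        truth["psi_mut"].to_numpy(),
        truth["skip_boost"].to_numpy(),
    )
    return truth


def _allele_shares(bias: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pm = bias / (1.0 + bias)
    return pm, 1.0 - pm


def simulate_counts(truth: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Realise the four-count table from a truth table.

    Input reads are split between alleles by the synthesis bias at fixed
    library size; output reads are a single multinomial over
    (mutant-inclusion, mutant-skip, wildtype-inclusion, wildtype-skip).
    """
    rng = np.random.default_rng(seed)
    bias = truth["bias"].to_numpy(float)
    boost = truth["skip_boost"].to_numpy(float)
    pm, pw = _allele_shares(bias)
    psi_m = effective_inclusion(truth["psi_mut"].to_numpy(float), boost)
    psi_w = effective_inclusion(truth["psi_wt"].to_numpy(float), boost)
    d_in = truth["depth_input"].to_numpy(int)
    d_out = truth["depth_output"].to_numpy(int)

    mi = rng.binomial(d_in, pm)
    wi = d_in - mi
    m_out = rng.binomial(d_out, pm)
    w_out = d_out - m_out
    mo = rng.binomial(m_out, psi_m)
    wo = rng.binomial(w_out, psi_w)
    out = truth[["variant", "construct"]].copy()
    out["mo"] = mo
    out["mi"] = mi
    out["wo"] = wo
    out["wi"] = wi
    out["skip_m"] = m_out - mo
    out["skip_w"] = w_out - wo
    return out


def _mutate(windows: np.ndarray, rng: np.random.Generator, error_rate: float) -> np.ndarray:
    """Apply uniform substitution errors in place (coded 2-bit alphabet)."""
    if error_rate <= 0 or windows.size == 0:
        return windows
    mask = rng.random(windows.shape) < error_rate
    n_err = int(mask.sum())
    if n_err:
        shift = rng.integers(1, 4, n_err, dtype=np.uint8)
        codes = _CODE[windows[mask]]
        windows[mask] = _BASES[(codes + shift) % 4]
    return windows


def _draw_windows(
    seq: str,
    n: int,
    length: int,
    variant_pos: int | None,
    rng: np.random.Generator,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` read windows from a species sequence.

    For allele-bearing species the fragment is constrained to cover the
    variant site (amplicon-style coverage of the informative position);
    skip-product fragments start uniformly.
    """
    s_len = len(seq)
    if length > s_len:
        raise ValueError(
            f"read_length {length} exceeds species length {s_len}"
        )
    if variant_pos is None:
        lo, hi = 0, s_len - length
    else:
        lo = max(0, variant_pos - length + 1)
        hi = min(variant_pos, s_len - length)
    starts = rng.integers(lo, hi + 1, n)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    windows = arr[starts[:, None] + np.arange(length)]
    return starts, _mutate(windows, rng, error_rate)


_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _RC[_a] = _b


def library_paths(
    out_dir: str | Path, constructs: Sequence[str], paired: bool = False
) -> dict[str, dict[str, Path]]:
    """Per-construct FASTQ paths under ``out_dir`` (the naming scheme
    :func:`simulate_reads` writes)."""
    out_dir = Path(out_dir)
    mate_keys = ("input_R2", "output_R2") if paired else ()
    libs: dict[str, dict[str, Path]] = {}
    for cname in constructs:
        libs[cname] = {}
        for key in ("input", "output", *mate_keys):
            stem = key.replace("_R2", "") + f"_{cname}"
            suffix = "_R2" if key.endswith("_R2") else ("_R1" if paired else "")
            libs[cname][key] = out_dir / f"{stem}{suffix}.fastq"
    return libs


def simulate_reads(
    truth: pd.DataFrame,
    catalogs: Mapping[tuple[str, str], SpeciesCatalog],
    config: SimConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Write per-construct input/output FASTQ libraries plus a
    ground-truth sidecar.

    Each construct is sequenced as its own library pair, mirroring the
    assay's separate transfections.  Returns ``{"sidecar": path,
    "libraries": {construct: {"input": path, "output": path, ...}}}``
    (with ``input_R2``/``output_R2`` mates when ``config.paired``).  Read
    names are opaque serials; fixed seeds give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = config.read_length
    constructs = list(dict.fromkeys(truth["construct"]))
    libraries = library_paths(out_dir, constructs, config.paired)
    handles: dict[tuple[str, str], object] = {}
    for cname, paths in libraries.items():
        for key, path in paths.items():
            handles[(cname, key)] = open(path, "w")
    sidecar_path = out_dir / "truth_sidecar.tsv"
    qual = "I" * L
    serial = {"in": 0, "out": 0}
    sc = open(sidecar_path, "w")
    try:
        sc.write("read_id\tlibrary\tvariant\tconstruct\tallele\tspecies\tstart\n")

        def emit(lib: str, catalog: SpeciesCatalog, allele: str, species_name: str, n: int):
            if n == 0:
                return
            sp = catalog.get(allele, species_name)
            starts, windows = _draw_windows(
                sp.seq, n, L, sp.variant_pos, rng, config.error_rate
            )
            tag = "in" if lib == "input" else "out"
            base = serial[tag]
            serial[tag] += n
            ids = [f"{tag}.{base + i:08d}" for i in range(n)]
            handles[(sp.construct, lib)].write(
                "".join(
                    f"@{rid}\n{row.tobytes().decode()}\n+\n{qual}\n"
                    for rid, row in zip(ids, windows)
                )
            )
            if config.paired:
                mates = np.ascontiguousarray(_RC[windows[:, ::-1]])
                _mutate(mates, rng, config.error_rate)
                handles[(sp.construct, lib + "_R2")].write(
                    "".join(
                        f"@{rid}\n{row.tobytes().decode()}\n+\n{qual}\n"
                        for rid, row in zip(ids, mates)
                    )
                )
            sc.write(
                "".join(
                    f"{rid}\t{lib}\t{sp.variant_id}\t{sp.construct}\t{allele}"
                    f"\t{species_name}\t{start}\n"
                    for rid, start in zip(ids, starts)
                )
            )

        counts = simulate_counts(truth, int(rng.integers(0, 2**31)))
        for row in counts.itertuples(index=False):
            catalog = catalogs[(row.variant, row.construct)]
            emit("input", catalog, "M", INPUT, int(row.mi))
            emit("input", catalog, "W", INPUT, int(row.wi))
            emit("output", catalog, "M", INCLUSION, int(row.mo))
            emit("output", catalog, "W", INCLUSION, int(row.wo))
            emit("output", catalog, "M", SKIP, int(row.skip_m))
            emit("output", catalog, "W", SKIP, int(row.skip_w))
    finally:
        sc.close()
        for fh in handles.values():
            fh.close()
    return {"sidecar": sidecar_path, "libraries": libraries}


# ---------------------------------------------------------------------------
# synthetic cohorts


def synthetic_cohort(
    n_variants: int,
    seed: int,
    proband_fraction: float = 447 / 725,
    class_probs: Mapping[str, float] | None = None,
    exon_len_range: tuple[int, int] = (45, 115),
    upstream_intron_len: int = 130,
) -> tuple[list[Variant], dict[str, ExonContext]]:
    """Generate a cohort of synthetic de novo SNVs with exon contexts.

    Defaults mirror the screened cohort's composition: 447/725 of variants
    come from probands and consequence classes are roughly 30% synonymous,
    62% missense, 8% nonsense.  Sequences are uniform random DNA; exon
    lengths are uniform over the eligible range.
    """
    if class_probs is None:
        class_probs = {"synonymous": 0.30, "missense": 0.62, "nonsense": 0.08}
    rng = np.random.default_rng(seed)
    classes = list(class_probs)
    probs = np.array([class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    alphabet = np.array(list("ACGT"))

    variants: list[Variant] = []
    contexts: dict[str, ExonContext] = {}
    for i in range(n_variants):
        exon_len = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        exon = "".join(alphabet[rng.integers(0, 4, exon_len)])
        up = "".join(alphabet[rng.integers(0, 4, upstream_intron_len)])
        flank = "".join(alphabet[rng.integers(0, 4, 15)])
        offset = int(rng.integers(0, exon_len))
        strand = "+" if rng.random() < 0.5 else "-"
        base = exon[offset]
        ref = base if strand == "+" else base.translate(COMPLEMENT)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        chrom = str(int(rng.integers(1, 23)))
        pos = 1_000_000 + i * 1000 + int(rng.integers(0, 1000))
        vid = f"{chrom}:{pos}:{ref}:{alt}"
        role = "proband" if rng.random() < proband_fraction else "sibling"
        variants.append(
            Variant(
                id=vid,
                gene=f"GENE{i + 1:04d}",
                consequence=str(rng.choice(classes, p=probs)),
                role=role,
                family_id=f"F{i + 1:04d}",
            )
        )
        contexts[vid] = ExonContext(
            exon_seq=exon,
            upstream_intron_seq=up,
            downstream_flank_seq=flank,
            strand=strand,
            variant_offset=offset,
        )
    return variants, contexts
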