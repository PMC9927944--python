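"""Synthetic MPRA study generator with a known truth table.

Emulates the study's inputs end to end so every pipeline stage is testable
offline: a random genomic region with clustered common variants, the
permuted fragment catalog, a barcode dictionary with a high-coverage
barcodes-per-fragment distribution (target: >98% of fragments with >= 12
tags), paired association reads, and pDNA/cDNA count tables whose counts
follow a negative binomial (Poisson-like at low means, overdispersed when
asked) with injected allelic effects of known size.  Block-structured
haplotypes with tunable within-block r^2 feed the LD stage.

Two profiles are bundled: ``default`` is a desk-scale study (~30 variants,
~30 barcodes per fragment) roughly 100x smaller than the assay it mimics;
``full-scale`` reproduces the full geometry (~300 variants in ~58 kb,
~900 barcodes per fragment, around 1.5 million barcodes overall).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    DesignParams,
    FragmentCatalog,
    VariantRecord,
    build_fragments,
    dedupe_and_catalog,
)
from .ld import HaplotypeMatrix

__all__ = [
    "TruthTable",
    "RegionSpec",
    "SyntheticLibraries",
    "PROFILES",
    "gen_region",
    "gen_mpra_libraries",
    "gen_haplotypes",
    "design_catalog",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RegionSpec:
    """Geometry of the synthetic genomic region and its variant clusters."""

    length: int = 6000
    n_variants: int = 30
    chrom: str = "synthChr"
    min_spacing: int = 160  # between clusters, > one fragment window
    close_fraction: float = 0.35  # fraction of clusters with 2-3 variants
    cluster_span: int = 60  # extra variants fall within this many bp
    edge_margin: int = 80  # keep windows clear of the reference ends


@dataclass(frozen=True)
class TruthTable:
    """Ground truth and noise model for the synthetic libraries.

    ``effects`` maps variant id -> true allelic effect delta (log2 units);
    effects are additive across the non-reference alleles of a fragment.
    ``baseline_activity`` mu is the log2 activity of the all-reference
    fragment; ``barcode_noise_sd`` sigma is per-barcode biological noise.
    ``nb_dispersion`` is the negative binomial size parameter (larger =
    closer to Poisson).
    """

    effects: dict[str, float] = field(default_factory=dict)
    baseline_activity: float = 0.0
    barcode_noise_sd: float = 0.3
    barcodes_per_fragment_mean: float = 30.0
    pdna_mean_depth: float = 100.0  # mean pDNA reads per barcode
    nb_dispersion: float = 20.0
    barcode_length: int = 16
    reads_per_barcode: int = 3  # association-library read pairs per barcode
    read_error_rate: float = 0.0

    def delta_of(self, fragment, variants: dict[str, VariantRecord]) -> float:
        """Summed allelic effect of a fragment's non-reference alleles."""
        total = 0.0
        for vid, allele in fragment.allele_assignment.items():
            if allele != variants[vid].ref:
                total += self.effects.get(vid, 0.0)
        return total


PROFILES: dict[str, dict] = {
    "default": {
        "region": RegionSpec(),
        "truth": TruthTable(),
    },
    "full-scale": {
        "region": RegionSpec(length=58000, n_variants=300),
        "truth": TruthTable(barcodes_per_fragment_mean=900.0),
    },
}


@dataclass
class SyntheticLibraries:
    """Everything the downstream pipeline consumes, plus the truth."""

    barcode_map: dict[str, str]  # barcode -> fragment_id
    counts: pd.DataFrame  # barcodes x {pDNA, cDNA}
    read_pairs: list[tuple[str, str]]  # (mate1, mate2) association reads
    fragment_truth: pd.DataFrame  # fragment_id, true_activity, n_barcodes
    truth: TruthTable


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def gen_region(
    spec: RegionSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[str, list[VariantRecord]]:
    """Generate a random reference sequence and clustered SNVs.

    Variant clusters are spaced at least ``min_spacing`` apart so windows
    of different clusters never overlap; a ``close_fraction`` of clusters
    receive 2-3 variants within ``cluster_span`` bp to force combinatorial
    multi-variant fragments, mirroring real fragments that carry
    additional variants near the central one.
    """
    spec = spec or RegionSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    reference = _random_dna(rng, spec.length)

    positions: list[int] = []
    cursor = spec.edge_margin
    while len(positions) < spec.n_variants:
        cursor += int(rng.integers(spec.min_spacing, spec.min_spacing + 60))
        if cursor > spec.length - spec.edge_margin:
            raise ValueError(
                f"infeasible spacing: could only place {len(positions)} of "
                f"{spec.n_variants} variants in {spec.length} bp"
            )
        cluster = [cursor]
        if rng.random() < spec.close_fraction:
            extra = int(rng.integers(1, 3))  # cluster of 2 or 3
            offsets = rng.choice(
                np.arange(4, spec.cluster_span), size=extra, replace=False
            )
            cluster += [cursor + int(o) for o in sorted(offsets)]
            cursor = cluster[-1]
        for pos in cluster:
            if len(positions) < spec.n_variants:
                positions.append(pos)

    variants = []
    for i, pos in enumerate(sorted(positions)):
        ref_base = reference[pos - 1]
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        variants.append(
            VariantRecord(
                id=f"rsS{i + 1:04d}",
                chrom=spec.chrom,
                pos=pos,
                ref=ref_base,
                alts=(alt_base,),
            )
        )
    return reference, variants


def design_catalog(
    reference: str,
    variants: list[VariantRecord],
    params: DesignParams | None = None,
) -> FragmentCatalog:
    """Run the design stage on a synthetic region."""
    fragments = build_fragments(variants, reference, params)
    catalog, _ = dedupe_and_catalog(fragments, params or DesignParams())
    return catalog


def _draw_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct random tags, sampled until collision-free."""
    if n > 4 ** length:
        raise ValueError("barcode space exhausted")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        for code in rng.integers(0, 4, size=(n - len(out), length)):
            bc = _BASES[code].tobytes().decode()
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def gen_mpra_libraries(
    catalog: FragmentCatalog,
    variants: list[VariantRecord],
    truth: TruthTable | None = None,
    seed: int | np.random.Generator = 0,
) -> SyntheticLibraries:
    """Simulate the barcode dictionary, association reads, and count tables.

    Per fragment: a Poisson number of barcodes (mean
    ``barcodes_per_fragment_mean``, floor 1).  Per barcode: pDNA count ~
    NB(mean depth, dispersion); the barcode's true activity is
    mu + sum(delta) + Normal(0, sigma) and its cDNA mean is the pDNA draw
    scaled by 2^activity, sampled NB again.  Association reads carry the
    barcode on mate 1 and the fragment sequence on mate 2, with optional
    substitution errors.
    """
    truth = truth or TruthTable()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vmap = {v.id: v for v in variants}

    n_per_fragment = np.maximum(
        rng.poisson(truth.barcodes_per_fragment_mean, size=len(catalog.entries)), 1
    )
    barcodes = _draw_barcodes(rng, int(n_per_fragment.sum()), truth.barcode_length)

    barcode_map: dict[str, str] = {}
    rows = []
    truth_rows = []
    read_pairs: list[tuple[str, str]] = []
    cursor = 0
    for entry, n_bc in zip(catalog.entries, n_per_fragment):
        activity_true = truth.baseline_activity + truth.delta_of(entry, vmap)
        truth_rows.append(
            {
                "fragment_id": entry.fragment_id,
                "true_activity": activity_true,
                "n_barcodes": int(n_bc),
                "is_reference": entry.is_reference,
            }
        )
        frag_barcodes = barcodes[cursor: cursor + n_bc]
        cursor += n_bc
        pdna = _nb(rng, np.full(n_bc, truth.pdna_mean_depth), truth.nb_dispersion)
        noise = rng.normal(0.0, truth.barcode_noise_sd, size=n_bc)
        cdna_mean = np.maximum(pdna, 1) * np.exp2(activity_true + noise)
        cdna = _nb(rng, cdna_mean, truth.nb_dispersion)
        for bc, p_count, c_count in zip(frag_barcodes, pdna, cdna):
            barcode_map[bc] = entry.fragment_id
            rows.append({"barcode": bc, "pDNA": int(p_count), "cDNA": int(c_count)})
            for _ in range(truth.reads_per_barcode):
                read_pairs.append(
                    (
                        _mutate(rng, bc, truth.read_error_rate),
                        _mutate(rng, entry.sequence, truth.read_error_rate),
                    )
                )

    counts = pd.DataFrame(rows).set_index("barcode")
    return SyntheticLibraries(
        barcode_map=barcode_map,
        counts=counts,
        read_pairs=read_pairs,
        fragment_truth=pd.DataFrame(truth_rows),
        truth=truth,
    )


def gen_haplotypes(
    n_haplotypes: int,
    block_spec: list[tuple[int, float]],
    seed: int | np.random.Generator = 0,
    variant_ids: list[str] | None = None,
) -> HaplotypeMatrix:
    """Block-structured haplotypes with a target within-block r^2.

    ``block_spec`` is a list of (n_variants, target_r2) blocks.  Within a
    block each column copies a common ancestor haplotype with independent
    flips at rate eps = (1 - r2^(1/4)) / 2, which sets the expected
    pairwise r^2 to the target at allele frequency 0.5 (exact at r2 = 1);
    columns of different blocks are independent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _, r2 in block_spec:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"target r2 must lie in [0, 1], got {r2}")
    columns = []
    for n_vars, r2 in block_spec:
        ancestor = rng.integers(0, 2, size=n_haplotypes, dtype=np.int8)
        eps = (1.0 - r2 ** 0.25) / 2.0
        for _ in range(n_vars):
            flips = (rng.random(n_haplotypes) < eps).astype(np.int8)
            columns.append(ancestor ^ flips)
    total = sum(n for n, _ in block_spec)
    ids = variant_ids or [f"rsS{i + 1:04d}" for i in range(total)]
    if len(ids) != total:
        raise ValueError("variant_ids length does not match block spec")
    return HaplotypeMatrix(np.column_stack(columns), ids)


def simulate_study(
    region: RegionSpec | None = None,
    truth: TruthTable | None = None,
    seed: int = 0,
    effect_fraction: float = 0.15,
    effect_size: float = 1.0,
    params: DesignParams | None = None,
):
    """Convenience wrapper: region + catalog + libraries with injected effects.

    A random ``effect_fraction`` of variants receive a true allelic effect
    of ``effect_size`` log2 units (unless ``truth.effects`` is already
    set).  Returns (reference, variants, catalog, libraries).
    """
    rng = np.random.default_rng(seed)
    region = region or RegionSpec()
    reference, variants = gen_region(region, rng)
    catalog = design_catalog(reference, variants, params)
    truth = truth or TruthTable()
    if not truth.effects and effect_fraction > 0:
        n_hits = max(1, round(effect_fraction * len(variants)))
        hit_ids = rng.choice([v.id for v in variants], size=n_hits, replace=False)
        truth = replace(truth, effects={vid: effect_size for vid in hit_ids})
    libraries = gen_mpra_libraries(catalog, variants, truth, rng)
    return reference, variants, catalog, libraries
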