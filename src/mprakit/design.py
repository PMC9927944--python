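"""Design of MPRA oligo fragments by allelic permutation.

Each tested variant is placed at the center of a fixed-length fragment
window (default 137 bp: the variant base flanked by 68 reference bases on
each side).  When additional variants fall inside the same window, the full
Cartesian product of allele combinations is enumerated so that every
haplotype of the window is represented by its own fragment.  Fragments with
identical variable-region sequences are collapsed into a unique catalog,
and cloning adaptors are appended to form the synthesizable oligos.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "VariantRecord",
    "DesignParams",
    "FragmentDesign",
    "OligoRecord",
    "FragmentCatalog",
    "DesignError",
    "enumerate_allele_combinations",
    "build_fragments",
    "dedupe_and_catalog",
]

_DNA = set("ACGT")


class DesignError(ValueError):
    """Raised when a fragment design request is invalid."""


@dataclass(frozen=True)
class VariantRecord:
    """A candidate variant in reference coordinates (1-based ``pos``)."""

    id: str
    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alts: tuple[str, ...]
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DesignError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise DesignError(f"variant {self.id}: empty REF allele")
        if not self.alts:
            raise DesignError(f"variant {self.id}: at least one ALT allele required")
        for alt in self.alts:
            if alt == self.ref:
                raise DesignError(f"variant {self.id}: ALT equals REF ({alt})")
        object.__setattr__(self, "alts", tuple(self.alts))

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the reference allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def alleles(self) -> tuple[str, ...]:
        """Reference allele first, then alternates in input order."""
        return (self.ref,) + self.alts


@dataclass(frozen=True)
class DesignParams:
    """Geometry and guards for fragment construction.

    ``fragment_length`` is the length of the variable region for SNV-only
    windows; ``flank`` is the number of reference bases on each side of the
    centered variant, so fragment_length = 2*flank + len(center ref allele)
    for SNVs.  Adaptor sequences are cloning-arm placeholders supplied by
    the user; they are configuration, not biology.
    """

    fragment_length: int = 137
    flank: int = 68
    adaptor_5p: str = "ACTGGCCGCTTGACG"
    adaptor_3p: str = "CACTGCGGCTCCTGC"
    strict_snv: bool = True
    max_variants_per_window: int = 6

    def __post_init__(self) -> None:
        if self.fragment_length <= 0 or self.flank < 0:
            raise DesignError("fragment_length must be > 0 and flank >= 0")
        if self.fragment_length != 2 * self.flank + 1:
            raise DesignError(
                "fragment_length must equal 2*flank + 1 for an SNV center "
                f"(got L={self.fragment_length}, F={self.flank})"
            )


@dataclass(frozen=True)
class FragmentDesign:
    """One allele combination of one fragment window."""

    fragment_id: str
    chrom: str
    window: tuple[int, int]  # 0-based half-open, reference coordinates
    center_variant: str
    allele_assignment: dict  # variant id -> allele carried by this fragment
    sequence: str
    is_reference: bool

    @property
    def window_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.window[0], self.window[1])

    def n_variant_sites(self, variants: dict[str, VariantRecord]) -> int:
        """Number of sites carrying a non-reference allele."""
        return sum(
            1 for vid, allele in self.allele_assignment.items()
            if allele != variants[vid].ref
        )


@dataclass(frozen=True)
class OligoRecord:
    """A synthesizable oligo: adaptors wrapped around the variable region."""

    fragment_id: str
    full_sequence: str


def enumerate_allele_combinations(
    variants_in_window: list[VariantRecord],
) -> list[dict]:
    """Enumerate every allele combination over the window's variants.

    Returns the full Cartesian product over {ref} union alts per variant as
    a list of ``{variant_id: allele}`` maps, ordered deterministically:
    variants sorted by (position, id), the reference allele first within
    each variant.  The first returned assignment is therefore all-reference.

    Raises
    ------
    DesignError
        If two variants' reference spans overlap (their alleles would
        collide on the same base).
    """
    ordered = sorted(variants_in_window, key=lambda v: (v.pos, v.id))
    for a, b in itertools.combinations(ordered, 2):
        if a.span[1] > b.span[0] and b.span[1] > a.span[0]:
            raise DesignError(
                f"variants {a.id} and {b.id} overlap at reference "
                f"position {max(a.span[0], b.span[0]) + 1}"
            )
    choices = [v.alleles() for v in ordered]
    ids = [v.id for v in ordered]
    return [dict(zip(ids, combo)) for combo in itertools.product(*choices)]


def _window_for(center: VariantRecord, params: DesignParams) -> tuple[int, int]:
    start = center.pos - 1 - params.flank
    end = center.pos - 1 + len(center.ref) + params.flank
    return (start, end)


def _apply_alleles(
    ref_slice: str,
    window_start: int,
    members: list[VariantRecord],
    assignment: dict,
) -> str:
    # substitute right-to-left so earlier coordinates stay valid for indels
    seq = list(ref_slice)
    for v in sorted(members, key=lambda v: -v.pos):
        rel = v.pos - 1 - window_start
        seq[rel: rel + len(v.ref)] = assignment[v.id]
    return "".join(seq)


def build_fragments(
    variant_set: list[VariantRecord],
    reference: str,
    params: DesignParams | None = None,
) -> list[FragmentDesign]:
    """Build one fragment window per variant, expanded over allele combos.

    For each center variant a window of ``params.fragment_length`` is taken
    from the reference (the variant centered, ``params.flank`` bases each
    side); every variant whose reference span overlaps the window
    contributes its alleles to the combinatorial expansion.  The
    all-reference fragment is emitted for every window.
    """
    params = params or DesignParams()
    variants = sorted(variant_set, key=lambda v: (v.chrom, v.pos, v.id))
    seen_ids = set()
    for v in variants:
        if v.id in seen_ids:
            raise DesignError(f"duplicate variant id {v.id}")
        seen_ids.add(v.id)
    if params.strict_snv:
        for v in variants:
            if not v.is_snv:
                raise DesignError(
                    f"variant {v.id} is not an SNV; rerun with strict_snv=False"
                )

    fragments: list[FragmentDesign] = []
    for center in variants:
        start, end = _window_for(center, params)
        if start < 0 or end > len(reference):
            raise DesignError(
                f"window for {center.id} ({start}, {end}) extends past the "
                f"reference ends (length {len(reference)})"
            )
        ref_slice = reference[start:end]
        bad = set(ref_slice) - _DNA
        if bad:
            raise DesignError(
                f"non-ACGT base {sorted(bad)} in reference window of {center.id}"
            )
        members = [
            v for v in variants if v.span[1] > start and v.span[0] < end
        ]
        if len(members) > params.max_variants_per_window:
            raise DesignError(
                f"window of {center.id} contains {len(members)} variants "
                f"(> max_variants_per_window={params.max_variants_per_window})"
            )
        for assignment in enumerate_allele_combinations(members):
            is_ref = all(
                assignment[v.id] == v.ref for v in members
            )
            label = "REF" if is_ref else ",".join(
                f"{v.id}:{assignment[v.id]}"
                for v in sorted(members, key=lambda v: v.pos)
                if assignment[v.id] != v.ref
            )
            fragments.append(
                FragmentDesign(
                    fragment_id=f"{center.id}|{label}",
                    chrom=center.chrom,
                    window=(start, end),
                    center_variant=center.id,
                    allele_assignment=assignment,
                    sequence=_apply_alleles(ref_slice, start, members, assignment),
                    is_reference=is_ref,
                )
            )
    return fragments


@dataclass
class FragmentCatalog:
    """Unique fragment catalog with merged-window provenance."""

    entries: list[FragmentDesign]
    provenance: dict[str, list[FragmentDesign]]
    window_reference: dict[tuple[str, int, int], str]
    params: DesignParams

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> dict[str, str]:
        return {e.fragment_id: e.sequence for e in self.entries}

    def oligos(self) -> list[OligoRecord]:
        p = self.params
        return [
            OligoRecord(e.fragment_id, p.adaptor_5p + e.sequence + p.adaptor_3p)
            for e in self.entries
        ]

    def get(self, fragment_id: str) -> FragmentDesign:
        for e in self.entries:
            if e.fragment_id == fragment_id:
                return e
        raise KeyError(fragment_id)


def dedupe_and_catalog(
    fragments: list[FragmentDesign],
    params: DesignParams | None = None,
) -> tuple[FragmentCatalog, list[OligoRecord]]:
    """Collapse identical variable-region sequences into a unique catalog.

    The first fragment seen for a sequence names the catalog entry; all
    fragments sharing the sequence are retained as provenance.  Each
    window's all-reference fragment is indexed in ``window_reference`` so
    downstream allele-specific tests can find their baseline.
    """
    params = params or DesignParams()
    by_seq: dict[str, str] = {}
    entries: list[FragmentDesign] = []
    provenance: dict[str, list[FragmentDesign]] = {}
    window_reference: dict[tuple[str, int, int], str] = {}
    for frag in fragments:
        fid = by_seq.get(frag.sequence)
        if fid is None:
            by_seq[frag.sequence] = frag.fragment_id
            entries.append(frag)
            provenance[frag.fragment_id] = [frag]
            fid = frag.fragment_id
        else:
            provenance[fid].append(frag)
        if frag.is_reference:
            window_reference[frag.window_key] = fid
    catalog = FragmentCatalog(entries, provenance, window_reference, params)
    return catalog, catalog.oligos()
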