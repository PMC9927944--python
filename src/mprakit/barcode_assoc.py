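"""Barcode-to-fragment dictionary from the association (inert) library.

Each association read pair carries a random barcode tag on one mate and the
fragment's variable-region sequence on the other.  Reads are matched
against the designed catalog (Hamming distance, catalog-restricted — no
genome alignment) and votes are tallied per barcode.  A barcode is kept
when a single fragment wins a configurable supermajority of its reads;
barcodes split between fragments are quarantined as ambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .design import FragmentCatalog

__all__ = [
    "ReadLayout",
    "AssociationPolicy",
    "BarcodeMap",
    "parse_association_reads",
    "map_statistics",
]


@dataclass(frozen=True)
class ReadLayout:
    """Where the barcode and fragment segments sit in the read pair.

    The assay construct fixes which mate carries which segment but not the
    sequencing geometry, so this is configuration.  Defaults: mate 1 starts
    with the 16 bp barcode, mate 2 starts with the fragment sequence.
    """

    barcode_mate: int = 1
    barcode_offset: int = 0
    fragment_mate: int = 2
    fragment_offset: int = 0


@dataclass(frozen=True)
class AssociationPolicy:
    barcode_length: int = 16
    max_mismatches: int = 2  # fragment segment; barcodes are matched exactly
    min_reads: int = 1
    purity: float = 0.90  # fraction of a barcode's reads one fragment must win


@dataclass
class BarcodeMap:
    """Many-to-one dictionary from barcode tags to fragment identifiers."""

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)
    ambiguous_barcodes: set[str] = field(default_factory=set)
    barcode_length: int = 16
    n_pairs_seen: int = 0
    n_malformed: int = 0
    n_unmatched: int = 0
    n_low_support: int = 0

    def fragment_of(self, barcode: str) -> str | None:
        hit = self.entries.get(barcode)
        return hit[0] if hit else None

    def barcodes_per_fragment(self) -> Counter:
        counts: Counter = Counter()
        for fragment_id, _ in self.entries.values():
            counts[fragment_id] += 1
        return counts

    def summary(self) -> dict:
        return {
            "n_barcodes": len(self.entries),
            "n_ambiguous": len(self.ambiguous_barcodes),
            "n_pairs_seen": self.n_pairs_seen,
            "n_malformed": self.n_malformed,
            "n_unmatched": self.n_unmatched,
            "n_low_support": self.n_low_support,
        }


class _FragmentMatcher:
    """Exact lookup with a vectorized Hamming-scan fallback."""

    def __init__(self, catalog: FragmentCatalog, max_mismatches: int):
        self.max_mismatches = max_mismatches
        self.exact: dict[str, str] = {}
        by_len: dict[int, tuple[list[str], list[str]]] = {}
        for fid, seq in catalog.sequences().items():
            self.exact[seq] = fid
            ids, seqs = by_len.setdefault(len(seq), ([], []))
            ids.append(fid)
            seqs.append(seq)
        self.by_len = {
            n: (ids, np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(ids), n))
            for n, (ids, seqs) in by_len.items()
        }
        self.min_len = min(self.by_len)

    def match(self, segment: str) -> str | None:
        for n in self.by_len:
            hit = self.exact.get(segment[:n])
            if hit is not None:
                return hit
        if self.max_mismatches == 0:
            return None
        best_id, best_dist, best_ties = None, self.max_mismatches + 1, 0
        for n, (ids, mat) in self.by_len.items():
            if len(segment) < n:
                continue
            query = np.frombuffer(segment[:n].encode(), dtype=np.uint8)
            dists = np.count_nonzero(mat != query, axis=1)
            i = int(dists.argmin())
            d = int(dists[i])
            if d < best_dist:
                best_id, best_dist = ids[i], d
                best_ties = int((dists == d).sum())
            elif d == best_dist:
                best_ties += int((dists == d).sum())
        if best_id is None or best_ties != 1:
            return None  # no hit within budget, or ambiguous best hit
        return best_id


def parse_association_reads(
    read_pairs: Iterable[tuple[str, str]],
    catalog: FragmentCatalog,
    policy: AssociationPolicy | None = None,
    layout: ReadLayout | None = None,
) -> BarcodeMap:
    """Build the barcode map from paired association reads.

    Each pair yields (barcode, best-matching fragment); the fragment
    segment must match a catalog sequence within ``policy.max_mismatches``
    and be the unique best hit.  Barcodes with fewer than
    ``policy.min_reads`` supporting reads are dropped; barcodes whose top
    fragment wins less than ``policy.purity`` of their reads are moved to
    ``ambiguous_barcodes``.
    """
    policy = policy or AssociationPolicy()
    layout = layout or ReadLayout()
    if not catalog.entries:
        raise ValueError("empty fragment catalog")
    matcher = _FragmentMatcher(catalog, policy.max_mismatches)

    bmap = BarcodeMap(barcode_length=policy.barcode_length)
    votes: dict[str, Counter] = {}
    bc_lo = layout.barcode_offset
    bc_hi = bc_lo + policy.barcode_length
    for pair in read_pairs:
        bmap.n_pairs_seen += 1
        bc_read = pair[layout.barcode_mate - 1]
        fr_read = pair[layout.fragment_mate - 1]
        if len(bc_read) < bc_hi or len(fr_read) < layout.fragment_offset + matcher.min_len:
            bmap.n_malformed += 1
            continue
        barcode = bc_read[bc_lo:bc_hi]
        fragment = matcher.match(fr_read[layout.fragment_offset:])
        if fragment is None:
            bmap.n_unmatched += 1
            continue
        votes.setdefault(barcode, Counter())[fragment] += 1

    for barcode in sorted(votes):
        counts = votes[barcode]
        total = sum(counts.values())
        if total < policy.min_reads:
            bmap.n_low_support += 1
            continue
        (top_fragment, top_count), = counts.most_common(1)
        if top_count / total >= policy.purity and (
            len(counts) == 1 or top_count > max(
                c for f, c in counts.items() if f != top_fragment
            )
        ):
            bmap.entries[barcode] = (top_fragment, top_count)
        else:
            bmap.ambiguous_barcodes.add(barcode)
    return bmap


def map_statistics(bmap: BarcodeMap, min_barcodes: int = 12) -> dict:
    """Barcode-per-fragment summary for the association dictionary.

    Returns the number of (unambiguous) barcodes, the number of fragments
    observed, the barcodes-per-fragment distribution, and the fraction of
    observed fragments carrying at least ``min_barcodes`` barcodes (0.0 for
    an empty map).
    """
    per_fragment = bmap.barcodes_per_fragment()
    n_fragments = len(per_fragment)
    distribution = Counter(per_fragment.values())
    n_passing = sum(1 for n in per_fragment.values() if n >= min_barcodes)
    return {
        "n_barcodes": len(bmap.entries),
        "n_fragments_observed": n_fragments,
        "barcodes_per_fragment": dict(sorted(distribution.items())),
        "fraction_with_min_barcodes": (n_passing / n_fragments) if n_fragments else 0.0,
        "min_barcodes": min_barcodes,
    }
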