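"""Barcode-count normalization, filtering, and fragment-level aggregation.

Counts are summarized per barcode tag, normalized by library size (counts
per ``scale``, default 1e6), and log2 transformed.  Small normalized values
show Poisson-like noise, so cells below a lower-end cutoff (default 0.5,
strictly below removed) are masked.  Per-barcode activity is the log2
ratio of cDNA to its paired pDNA library, defined only where both cells
survive the cutoff.  Activities are then grouped by fragment through the
barcode map, and fragments with fewer than ``min_barcodes`` (default 12)
activity-bearing barcodes are flagged as failing the filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_assoc import BarcodeMap

__all__ = [
    "NormalizedTable",
    "FragmentActivitySummary",
    "normalize",
    "compute_activity",
    "aggregate_fragments",
]


@dataclass
class NormalizedTable:
    """log2 library-size-normalized counts plus the retained-cell mask."""

    values: pd.DataFrame  # barcodes x libraries, float
    mask: pd.DataFrame  # True = retained (value >= cutoff)
    cutoff: float
    scale: float
    pseudocount: float

    @property
    def libraries(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FragmentActivitySummary:
    """Per-fragment activity summary after the minimum-barcode filter."""

    fragment_id: str
    activities: np.ndarray
    min_barcodes: int = 12
    n_barcodes: int = field(init=False)
    mean_activity: float = field(init=False)
    sd_activity: float = field(init=False)
    passed_filter: bool = field(init=False)

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        self.n_barcodes = len(self.activities)
        self.mean_activity = float(self.activities.mean()) if self.n_barcodes else math.nan
        self.sd_activity = (
            float(self.activities.std(ddof=1)) if self.n_barcodes > 1 else math.nan
        )
        self.passed_filter = self.n_barcodes >= self.min_barcodes


def normalize(
    counts: pd.DataFrame,
    scale: float = 1e6,
    pseudocount: float = 1.0,
    cutoff: float = 0.5,
) -> NormalizedTable:
    """Normalize a barcode x library count table.

    value = log2(count / library_size * scale + pseudocount); a cell is
    retained iff its value is >= ``cutoff`` (strictly-below removed, so a
    value of exactly 0.5 survives the default cutoff).
    """
    counts = counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("negative counts in count table")
    library_sizes = counts.sum(axis=0)
    empty = library_sizes[library_sizes == 0]
    if len(empty):
        raise ValueError(f"zero library size for: {', '.join(empty.index)}")
    values = np.log2(counts / library_sizes * scale + pseudocount)
    mask = values >= cutoff
    return NormalizedTable(values=values, mask=mask, cutoff=cutoff,
                           scale=scale, pseudocount=pseudocount)


def compute_activity(
    norm: NormalizedTable,
    pairing: dict[str, str],
) -> pd.DataFrame:
    """Per-barcode activity: normalized cDNA minus its paired pDNA (log2).

    ``pairing`` maps each cDNA library to its pDNA partner and must cover
    every cDNA library used.  An activity is emitted only for barcodes
    retained in both members of a pair.  Returns a tidy frame with columns
    barcode, cdna_library, pdna_library, activity.
    """
    missing = [lib for lib in pairing.values() if lib not in norm.values.columns]
    missing += [lib for lib in pairing if lib not in norm.values.columns]
    if missing:
        raise ValueError(f"libraries absent from normalized table: {missing}")
    frames = []
    for cdna, pdna in pairing.items():
        keep = norm.mask[cdna] & norm.mask[pdna]
        activity = norm.values.loc[keep, cdna] - norm.values.loc[keep, pdna]
        frames.append(
            pd.DataFrame(
                {
                    "barcode": activity.index,
                    "cdna_library": cdna,
                    "pdna_library": pdna,
                    "activity": activity.values,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["barcode", "cdna_library", "pdna_library", "activity"])
    return pd.concat(frames, ignore_index=True)


def pairing_from_manifest(manifest: pd.DataFrame) -> dict[str, str]:
    """Derive the cDNA -> pDNA pairing from a library manifest frame."""
    pairing = {}
    for _, row in manifest.iterrows():
        if row["role"] == "cDNA":
            pdna = row.get("pair")
            if not isinstance(pdna, str) or not pdna:
                raise ValueError(f"cDNA library {row['library']} has no pDNA partner")
            pairing[row["library"]] = pdna
    return pairing


def aggregate_fragments(
    activities: pd.DataFrame,
    bmap: BarcodeMap | dict[str, str],
    min_barcodes: int = 12,
) -> tuple[list[FragmentActivitySummary], dict]:
    """Group barcode activities by fragment and apply the barcode filter.

    Replicate cDNA libraries are pooled at the barcode level (each
    activity record counts toward its fragment).  Activities whose barcode
    is absent from the map are excluded and reported in the returned
    summary dict.
    """
    if isinstance(bmap, BarcodeMap):
        lookup = {bc: frag for bc, (frag, _) in bmap.entries.items()}
    else:
        lookup = dict(bmap)
    grouped: dict[str, list[float]] = {}
    n_unmapped = 0
    for barcode, activity in zip(activities["barcode"], activities["activity"]):
        fragment = lookup.get(barcode)
        if fragment is None:
            n_unmapped += 1
            continue
        grouped.setdefault(fragment, []).append(float(activity))
    summaries = [
        FragmentActivitySummary(fragment_id=fid, activities=np.array(acts),
                                min_barcodes=min_barcodes)
        for fid, acts in sorted(grouped.items())
    ]
    report = {
        "n_activity_records": len(activities),
        "n_unmapped_barcode_records": n_unmapped,
        "n_fragments": len(summaries),
        "n_fragments_passing": sum(s.passed_filter for s in summaries),
        "min_barcodes": min_barcodes,
    }
    return summaries, report
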