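"""Allele-specific activity testing against the window reference fragment.

Every fragment carrying at least one non-reference allele is compared to
the all-reference (WT) fragment of its window with a two-sample two-tailed
t test over the two barcode-activity lists (Student's pooled-variance test
by default, Welch available).  Variant-level summaries tally which
variants are implicated by significant fragments, classifying each result
by how many variant sites the construct carries (single / double / triple).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import FragmentCatalog, VariantRecord
from .quantify import FragmentActivitySummary

__all__ = [
    "DifferentialResult",
    "VariantCallSummary",
    "InsufficientBarcodesError",
    "two_sample_t",
    "test_fragment",
    "test_catalog",
    "summarize_variants",
]

_CONSTRUCT_CLASSES = {1: "single", 2: "double", 3: "triple"}


class InsufficientBarcodesError(ValueError):
    """A fragment failed the minimum-barcode filter; its test is withheld."""


@dataclass
class DifferentialResult:
    fragment_id: str
    reference_fragment_id: str
    n_test: int
    n_reference: int
    effect: float  # mean(test) - mean(reference), log2 units
    t_statistic: float
    p_value: float
    alpha: float
    n_variant_sites: int
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p_value < self.alpha


@dataclass
class VariantCallSummary:
    variant_id: str
    results: list[DifferentialResult]
    construct_classes: list[str]
    any_significant: bool


def two_sample_t(
    a: np.ndarray, b: np.ndarray, flavor: str = "student"
) -> tuple[float, float]:
    """Two-sample two-tailed t statistic and p value for a vs b.

    ``flavor`` selects Student's pooled-variance test or Welch's
    unequal-variance correction.  Degenerate zero-variance inputs are
    resolved by the limit of the statistic: equal means give (0, 1),
    unequal means give (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if flavor not in ("student", "welch"):
        raise ValueError(f"unknown t-test flavor: {flavor}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=(flavor == "student"))
    return float(t), float(p)


def test_fragment(
    test: FragmentActivitySummary,
    reference: FragmentActivitySummary,
    alpha: float = 0.05,
    flavor: str = "student",
    n_variant_sites: int = 1,
) -> DifferentialResult:
    """Test one fragment's activities against its window reference."""
    for side, name in ((test, "test"), (reference, "reference")):
        if not side.passed_filter:
            raise InsufficientBarcodesError(
                f"insufficient barcodes: {name} fragment {side.fragment_id} "
                f"has {side.n_barcodes} < {side.min_barcodes}"
            )
    t, p = two_sample_t(test.activities, reference.activities, flavor=flavor)
    return DifferentialResult(
        fragment_id=test.fragment_id,
        reference_fragment_id=reference.fragment_id,
        n_test=test.n_barcodes,
        n_reference=reference.n_barcodes,
        effect=test.mean_activity - reference.mean_activity,
        t_statistic=t,
        p_value=p,
        alpha=alpha,
        n_variant_sites=n_variant_sites,
    )


def test_catalog(
    catalog: FragmentCatalog,
    summaries: list[FragmentActivitySummary],
    variants: list[VariantRecord],
    alpha: float = 0.05,
    flavor: str = "student",
    fdr: bool = False,
) -> tuple[list[DifferentialResult], list[dict]]:
    """Run the allele-specific test for every non-reference fragment.

    Each catalog entry is tested once per provenance window against that
    window's all-reference fragment.  Returns (results, withheld) where
    withheld lists fragments skipped with their reason (typically the
    minimum-barcode filter).  With ``fdr=True`` a Benjamini-Hochberg
    q_value attribute is added to each result; significance still uses the
    raw p value unless callers choose otherwise.
    """
    by_id = {s.fragment_id: s for s in summaries}
    vmap = {v.id: v for v in variants}
    results: list[DifferentialResult] = []
    withheld: list[dict] = []
    for entry in catalog.entries:
        for frag in catalog.provenance[entry.fragment_id]:
            if frag.is_reference:
                continue
            ref_id = catalog.window_reference.get(frag.window_key)
            if ref_id is None:
                raise KeyError(
                    f"no reference fragment cataloged for window {frag.window_key}"
                )
            test_summary = by_id.get(entry.fragment_id)
            ref_summary = by_id.get(ref_id)
            if test_summary is None or ref_summary is None:
                withheld.append(
                    {"fragment_id": entry.fragment_id, "reason": "no activity data"}
                )
                continue
            try:
                result = test_fragment(
                    test_summary,
                    ref_summary,
                    alpha=alpha,
                    flavor=flavor,
                    n_variant_sites=frag.n_variant_sites(vmap),
                )
            except InsufficientBarcodesError as exc:
                withheld.append({"fragment_id": entry.fragment_id, "reason": str(exc)})
                continue
            results.append(result)
    if fdr and results:
        qs = stats.false_discovery_control([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results, withheld


def summarize_variants(
    results: list[DifferentialResult],
    catalog: FragmentCatalog,
    variants: list[VariantRecord],
    alpha: float = 0.05,
) -> list[VariantCallSummary]:
    """Roll fragment-level results up to variants.

    A variant is implicated by every tested fragment in which its allele
    differs from reference; it is flagged ``any_significant`` when at least
    one such fragment is significant at ``alpha``.  Multi-variant
    constructs implicate all their non-reference variants (no
    deconvolution), with the construct class recording how many variant
    sites the fragment carried.
    """
    vmap = {v.id: v for v in variants}
    per_variant: dict[str, list[DifferentialResult]] = {}
    for result in results:
        if result.fragment_id not in catalog.provenance:
            raise KeyError(f"result fragment {result.fragment_id} absent from catalog")
        implicated: set[str] = set()
        for frag in catalog.provenance[result.fragment_id]:
            for vid, allele in frag.allele_assignment.items():
                if allele != vmap[vid].ref:
                    implicated.add(vid)
        for vid in implicated:
            per_variant.setdefault(vid, []).append(result)
    summaries = []
    for vid in sorted(per_variant):
        res = per_variant[vid]
        classes = [
            _CONSTRUCT_CLASSES.get(r.n_variant_sites, "higher") for r in res
        ]
        summaries.append(
            VariantCallSummary(
                variant_id=vid,
                results=res,
                construct_classes=classes,
                any_significant=any(r.p_value < alpha for r in res),
            )
        )
    return summaries


def construct_class_counts(results: list[DifferentialResult], alpha: float = 0.05) -> dict:
    """Count significant constructs by class (single/double/triple/higher)."""
    counts = {"single": 0, "double": 0, "triple": 0, "higher": 0}
    for r in results:
        if r.p_value < alpha:
            counts[_CONSTRUCT_CLASSES.get(r.n_variant_sites, "higher")] += 1
    return counts


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    rows = [
        {
            "fragment_id": r.fragment_id,
            "reference_fragment_id": r.reference_fragment_id,
            "n_test": r.n_test,
            "n_reference": r.n_reference,
            "effect_log2": r.effect,
            "t_statistic": r.t_statistic,
            "p_value": r.p_value,
            "significant": r.significant,
            "n_variant_sites": r.n_variant_sites,
            **({"q_value": r.q_value} if hasattr(r, "q_value") else {}),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
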