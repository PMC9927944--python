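"""End-to-end drivers chaining the pipeline stages."""

from __future__ import annotations

import pandas as pd

from .allelic_test import DifferentialResult, summarize_variants, test_catalog
from .design import FragmentCatalog, VariantRecord
from .quantify import aggregate_fragments, compute_activity, normalize
from .simulate import SyntheticLibraries

__all__ = ["analyze_counts", "recovery_metrics"]


def analyze_counts(
    catalog: FragmentCatalog,
    variants: list[VariantRecord],
    counts: pd.DataFrame,
    barcode_map,
    pairing: dict[str, str] | None = None,
    cutoff: float = 0.5,
    min_barcodes: int = 12,
    alpha: float = 0.05,
    flavor: str = "student",
):
    """Counts -> normalized activities -> fragment summaries -> tests.

    Returns (results, variant_calls, summaries, report).  ``pairing``
    defaults to the single-replicate layout {"cDNA": "pDNA"}.
    """
    pairing = pairing or {"cDNA": "pDNA"}
    norm = normalize(counts, cutoff=cutoff)
    activities = compute_activity(norm, pairing)
    summaries, report = aggregate_fragments(activities, barcode_map, min_barcodes)
    results, withheld = test_catalog(catalog, summaries, variants, alpha=alpha, flavor=flavor)
    report = {**report, "n_withheld": len(withheld)}
    calls = summarize_variants(results, catalog, variants, alpha=alpha)
    return results, calls, summaries, report


def recovery_metrics(
    results: list[DifferentialResult],
    catalog: FragmentCatalog,
    variants: list[VariantRecord],
    true_effects: dict[str, float],
    alpha: float = 0.05,
) -> dict:
    """Compare pipeline calls and effect estimates with a truth table.

    Sensitivity is the fraction of truly active variants flagged
    significant; the false-positive rate is the fraction of null variants
    flagged.  Effect error is measured on single-variant fragments, where
    the estimate is directly comparable to the injected delta.
    """
    calls = summarize_variants(results, catalog, variants, alpha=alpha)
    flagged = {c.variant_id for c in calls if c.any_significant}
    tested = {c.variant_id for c in calls}
    true_pos = {vid for vid, d in true_effects.items() if d != 0.0} & tested
    null = tested - true_pos

    vmap = {v.id: v for v in variants}
    abs_errors = []
    for r in results:
        frags = catalog.provenance[r.fragment_id]
        non_ref = {
            vid
            for frag in frags
            for vid, allele in frag.allele_assignment.items()
            if allele != vmap[vid].ref
        }
        if len(non_ref) == 1:
            (vid,) = non_ref
            abs_errors.append(abs(r.effect - true_effects.get(vid, 0.0)))
    return {
        "sensitivity": len(flagged & true_pos) / len(true_pos) if true_pos else float("nan"),
        "false_positive_rate": len(flagged & null) / len(null) if null else float("nan"),
        "mean_abs_effect_error": sum(abs_errors) / len(abs_errors) if abs_errors else float("nan"),
        "n_true_positive_variants": len(true_pos),
        "n_null_variants": len(null),
        "n_single_variant_fragments": len(abs_errors),
    }
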