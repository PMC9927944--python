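# Methods

## Fragment design

Each candidate variant is placed at the center of a fragment window:
`fragment_length` (default 137 bp) equals `2 × flank + 1` for an SNV, with
`flank = 68` reference bases on each side. A neighboring variant belongs to
a window iff its reference span overlaps the window interval; no separate
distance rule is used. For a window with variants v₁…v_k the design emits
the full Cartesian product over `{ref} ∪ alts` per variant — `Π(1 + n_alts)`
fragments, `2^k` when all are biallelic — in a deterministic order (variants
sorted by position then id, reference allele first), so the first assignment
of every window is the all-reference (WT) fragment. Windows with more than
6 variants raise an error instead of silently emitting ≥ 128 fragments;
the bound is configurable.

Coordinates follow the VCF convention on input (1-based) and are 0-based
half-open internally; everything is handled on the forward strand.
Overlapping variants (colliding alleles at the same base) are rejected.
Indels are rejected by default (`strict_snv=True`); with the flag off, the
variable region keeps the variant centered by reference coordinate and may
deviate from 137 bp. Fragments with identical variable-region sequences are
collapsed into one catalog entry; the merged windows are kept as provenance
so variant attribution and reference lookup still work per window. Adaptor
sequences for the synthesized oligos are configuration with documented
placeholders — they are cloning arms, not analysis inputs.

## Barcode association

The inert-library read pair carries a random tag on one mate and the
fragment sequence on the other; which mate, and at what offset, is a
`ReadLayout` config block because sequencing geometry is instrument- and
protocol-specific. Barcodes (default 16 bp) are matched exactly — random
tags have no truth sequence to correct toward — while fragment segments are
matched against the catalog by Hamming distance with a budget of 2
mismatches, accepting only a unique best hit. Votes are tallied per
barcode; a barcode is kept when it has at least `min_reads` (default 1)
supporting reads and a single fragment wins at least 90% of them
(`purity`), otherwise it is quarantined as ambiguous and excluded from all
downstream counting. These support/purity defaults follow common MPRA
dictionary builders and are deliberately conservative; they are declared
knobs, not fitted values.

## Quantification

Counts are summarized per barcode and library, normalized as
`log2(count / library_size × scale + pseudocount)` with `scale = 1e6` and
`pseudocount = 1`. The exact normalization constant is a declared choice —
counts-per-million is the field's default — and both `scale` and
`pseudocount` are flags. Low normalized values behave Poisson-like, so
cells strictly below the cutoff τ = 0.5 are removed; a value equal to τ is
retained. The cutoff applies per cell in pDNA and cDNA alike, and an
activity `a = cDNA_norm − pDNA_norm` exists only where both members of a
pDNA/cDNA pair survive (joint retention). Replicate cDNA libraries are
pooled at the barcode level by default; per-replicate analysis is available
by passing one pairing at a time. Activities are grouped by fragment via
the barcode dictionary; fragments with fewer than 12 activity-bearing
barcodes are flagged and excluded from testing. Summary statistics are the
mean and the sample standard deviation (ddof = 1) over exactly the listed
activities.

## Allele-specific testing

Each non-reference fragment is compared with its window's WT fragment by a
two-sample, two-tailed t test over the two barcode-activity lists.
Student's pooled-variance test is the default; Welch's correction is one
flag away. Significance uses raw p < α (default 0.05); a
Benjamini–Hochberg q-value column can be added but never silently replaces
the raw decision. Degenerate inputs where both groups have zero variance
are resolved by the limit of the statistic: equal means → (t = 0, p = 1),
unequal means → (t = ±∞, p = 0). A fragment on either side of the
comparison that failed the 12-barcode filter withholds the result with an
explicit reason rather than producing a low-powered p value.

A significant multi-variant fragment implicates **all** of its
non-reference variants: the assay cannot deconvolve co-occurring alleles,
so attribution is deliberately inclusive, and the construct class (single /
double / triple) is carried on every result so single-variant evidence can
be prioritized separately. A consequence, verified in simulation, is that
variant-level error control should be read off single-variant constructs:
null variants sharing a window with an active variant ride along by
construction, and a variant tested in many constructs accumulates
family-wise false-positive risk at raw α. The operating-characteristics
test therefore measures sensitivity and false-positive rate on
isolated-variant geometry, where each variant maps to exactly one
construct, and asserts the inclusive attribution behavior separately.

## LD statistics and grouping

From phased haplotypes coded 0/1, `D = p₁₁ − p₁q₁`,
`r² = D²/(p₁(1−p₁)q₁(1−q₁))`, and `D′ = D/D_max` with
`D_max = min(p₁(1−q₁), (1−p₁)q₁)` for D > 0 and
`min(p₁q₁, (1−p₁)(1−q₁))` for D < 0; D = 0 gives D′ = 0. Monomorphic loci
raise an error (LD undefined). Grouping is seed-anchored: each lead SNP
seeds a group, seeds with mutual r² above the threshold merge (union-find),
and every other variant joins the merged group of its best seed if that r²
strictly exceeds the threshold (default 0.70; boundary values are
excluded). The grouping rule itself is a declared, reproducible choice —
published LD heatmaps rarely state one. Variants linked to no seed are
reported as ungrouped rather than forced into a partition. Phased input is
the contract; unphased data should be phased upstream.

## Synthetic data generator

The generator emulates a saturation MPRA of a GWAS locus:

- **Region**: uniform-random sequence with variant clusters spaced ≥ 160 bp
  apart (so distinct clusters never share a 137 bp window). A fraction of
  clusters (`close_fraction`, default 0.35) holds 2–3 variants within
  60 bp, forcing combinatorial multi-variant windows like those seen when
  several common variants fall near a tested variant.
- **Barcodes**: per fragment, Poisson with mean 30 (floor 1), drawn as
  distinct uniform 16-mers. At this mean, more than 98% of fragments carry
  at least 12 tags, reproducing a high-coverage dictionary; the
  `full-scale` profile raises the mean to ~900 tags across ~1,600
  fragments (~1.5 M barcodes).
- **Counts**: pDNA per barcode is negative binomial (mean 100, size 20 —
  near-Poisson, with overdispersion available for stress tests). A
  barcode's true activity is `μ + Σδ + N(0, σ)` with baseline μ = 0,
  per-barcode noise σ = 0.3, and allelic effects δ additive in log2 space
  across a fragment's non-reference alleles — the simplest model consistent
  with combinatorial constructs. The cDNA mean is the pDNA draw scaled by
  `2^activity`, sampled negative binomial again.
- **Association reads**: `reads_per_barcode` pairs per barcode (default 3),
  mate 1 = barcode, mate 2 = fragment sequence, with a configurable
  per-base substitution error rate (default 0).
- **Haplotypes**: within a block, each column copies a common ancestor with
  independent flips at rate `ε = (1 − r²^{1/4})/2`, giving expected pairwise
  r² equal to the target at allele frequency 0.5 (exact at r² = 1);
  blocks are mutually independent.

What the generator does **not** emulate: transfection biology and
cell-state heterogeneity, PCR jackpotting and barcode-sequencing errors in
the count libraries, GC- or position-dependent synthesis bias, realistic
allele-frequency spectra, and recombination-gradient LD decay. Passing
tests therefore demonstrate that the pipeline's computations are correct
and calibrated under a clean noise model, not that any particular real
library meets those assumptions.

## Problem sizes and numerical choices

The bundled `default` profile (~30 variants, ~30 barcodes/fragment) is
roughly 100× smaller than the assay it mimics and is the scale used
throughout the test suite; calibration checks use 200 isolated null
fragments at 20 barcodes each, and effect-recovery checks use 100 seeded
replicates of 10-variant studies with δ = 1.0, σ = 0.3, 30
barcodes/fragment. Determinism is treated as a contract: every stochastic
routine takes a seed or `numpy.random.Generator`, and identical seeds
reproduce byte-identical files. Oracle comparisons in the tests hold the t
statistic and p value to 1e-10 of a closed-form implementation and the LD
statistics to 1e-12 of a haplotype-counting derivation over all two-locus
tables with up to 10 haplotypes.

## Known limitations

- No genome alignment in the association stage: matching is
  catalog-restricted, so foreign inserts are reported as unmatched, never
  rescued.
- No dispersion modeling or shrinkage in testing: the t test over barcode
  activities is the method as practiced here; count-model alternatives
  (e.g., negative-binomial GLMs) are out of scope.
- Combinatorial attribution cannot localize effects within multi-variant
  fragments; use the construct-class breakdown to weigh single-variant
  evidence.
- Phased haplotypes are the LD contract. A two-locus EM
  (`em_haplotype_frequencies`, `pairwise_ld_unphased`) estimates haplotype
  frequencies from unphased dosages for convenience, but it is off the
  default path and shares the usual EM caveats (local optima at extreme
  frequencies, no multi-locus phasing).
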