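"""Two-locus LD statistics, seed-anchored grouping, and prioritization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mprakit.allelic_test import VariantCallSummary
from mprakit.ld import (
    HaplotypeMatrix,
    MonomorphicError,
    group_by_ld,
    pairwise_ld,
    prioritize,
)


def haplotypes_from_counts(n11, n10, n01, n00):
    """Expand two-locus haplotype counts into an explicit 0/1 matrix."""
    rows = (
        [(1, 1)] * n11 + [(1, 0)] * n10 + [(0, 1)] * n01 + [(0, 0)] * n00
    )
    return HaplotypeMatrix(np.array(rows, dtype=np.int8), ["vi", "vj"])


def counting_oracle(a, b):
    """LD from first principles: indicator covariance and the feasible
    range of the double-alt haplotype frequency (no reuse of the package's
    Dmax case split)."""
    n = len(a)
    p1, q1 = a.mean(), b.mean()
    p11 = np.mean(a * b)
    D = p11 - p1 * q1
    r2 = float(np.corrcoef(a, b)[0, 1]) ** 2
    upper = min(p1, q1) - p1 * q1  # p11 at its feasibility maximum
    lower = p1 * q1 - max(0.0, p1 + q1 - 1.0)
    if D > 0:
        d_prime = D / upper
    elif D < 0:
        d_prime = D / lower
    else:
        d_prime = 0.0
    return D, d_prime, r2


class TestPairwiseLD:
    def test_duplicated_column_is_perfect_ld(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, 40, dtype=np.int8)
        h = HaplotypeMatrix(np.column_stack([col, col]), ["a", "b"])
        pair = pairwise_ld(h, "a", "b")
        assert pair.r2 == pytest.approx(1.0)
        assert pair.D_prime == pytest.approx(1.0)

    def test_printed_count_example(self):
        h = haplotypes_from_counts(40, 10, 10, 40)
        pair = pairwise_ld(h, "vi", "vj")
        assert pair.D == pytest.approx(0.15)
        assert pair.r2 == pytest.approx(0.36)
        assert pair.D_prime == pytest.approx(0.6)

    def test_factorized_counts_are_independent(self):
        # counts proportional to the product of the margins: D must be 0
        h = haplotypes_from_counts(12, 28, 18, 42)  # p1=0.4, q1=0.3
        pair = pairwise_ld(h, "vi", "vj")
        assert pair.D == pytest.approx(0.0, abs=1e-15)
        assert pair.r2 == pytest.approx(0.0, abs=1e-15)
        assert pair.D_prime == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_locus_is_undefined(self):
        h = HaplotypeMatrix(
            np.array([[1, 0], [1, 1], [1, 0]], dtype=np.int8), ["mono", "poly"]
        )
        with pytest.raises(MonomorphicError, match="undefined LD"):
            pairwise_ld(h, "mono", "poly")

    def test_exhaustive_small_tables_match_counting_oracle(self):
        """Every polymorphic two-locus haplotype table with <= 10 haplotypes."""
        checked = 0
        for n in range(2, 11):
            for n11, n10, n01 in itertools.product(range(n + 1), repeat=3):
                n00 = n - n11 - n10 - n01
                if n00 < 0:
                    continue
                p1 = (n11 + n10) / n
                q1 = (n11 + n01) / n
                if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
                    continue
                h = haplotypes_from_counts(n11, n10, n01, n00)
                pair = pairwise_ld(h, "vi", "vj")
                D0, dp0, r20 = counting_oracle(
                    h.column("vi").astype(float), h.column("vj").astype(float)
                )
                assert pair.D == pytest.approx(D0, abs=1e-12)
                assert pair.D_prime == pytest.approx(dp0, abs=1e-12)
                assert pair.r2 == pytest.approx(r20, abs=1e-9)
                checked += 1
        assert checked > 500

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), flip_i=st.booleans(), flip_j=st.booleans())
    def test_symmetry_and_allele_label_invariance(self, seed, flip_i, flip_j):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 2, size=(30, 2), dtype=np.int8)
        if mat[:, 0].min() == mat[:, 0].max() or mat[:, 1].min() == mat[:, 1].max():
            return  # monomorphic draw: LD undefined by contract
        h = HaplotypeMatrix(mat, ["a", "b"])
        fwd = pairwise_ld(h, "a", "b")
        rev = pairwise_ld(h, "b", "a")
        assert fwd.r2 == pytest.approx(rev.r2)
        assert fwd.D_prime == pytest.approx(rev.D_prime)
        flipped = mat.copy()
        if flip_i:
            flipped[:, 0] ^= 1
        if flip_j:
            flipped[:, 1] ^= 1
        pf = pairwise_ld(HaplotypeMatrix(flipped, ["a", "b"]), "a", "b")
        assert pf.r2 == pytest.approx(fwd.r2)
        assert abs(pf.D_prime) == pytest.approx(abs(fwd.D_prime))
        sign = -1 if flip_i != flip_j else 1
        assert pf.D == pytest.approx(sign * fwd.D)


class TestUnphasedEM:
    def test_em_recovers_phased_frequencies(self):
        from mprakit.ld import em_haplotype_frequencies, pairwise_ld_unphased
        from mprakit.simulate import gen_haplotypes

        h = gen_haplotypes(600, [(2, 0.8)], seed=13)
        a, b = h.alleles[:, 0], h.alleles[:, 1]
        # collapse haplotype pairs into unphased diploid dosages
        gi = a[0::2] + a[1::2]
        gj = b[0::2] + b[1::2]
        freq = em_haplotype_frequencies(gi, gj)
        true_freq = {
            "11": np.mean((a == 1) & (b == 1)),
            "10": np.mean((a == 1) & (b == 0)),
            "01": np.mean((a == 0) & (b == 1)),
            "00": np.mean((a == 0) & (b == 0)),
        }
        for key in freq:
            assert freq[key] == pytest.approx(true_freq[key], abs=0.02)
        pair_phased = pairwise_ld(h, 0, 1)
        pair_em = pairwise_ld_unphased(gi, gj)
        assert pair_em.r2 == pytest.approx(pair_phased.r2, abs=0.05)

    def test_invalid_dosages_rejected(self):
        from mprakit.ld import em_haplotype_frequencies

        with pytest.raises(ValueError, match="dosages"):
            em_haplotype_frequencies([0, 3], [1, 1])


class TestGroupByLD:
    def test_seeds_in_perfect_ld_merge(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 2, 50, dtype=np.int8)
        other = rng.integers(0, 2, 50, dtype=np.int8)
        h = HaplotypeMatrix(np.column_stack([col, col, other]), ["s1", "s2", "x"])
        groups, _ = group_by_ld(h, ["s1", "s2"])
        assert len(groups) == 1
        assert set(groups[0].seeds) == {"s1", "s2"}

    def test_threshold_is_strict(self):
        # 10 haplotypes engineered so r2(seed, v) is exactly the threshold
        seed_col = np.array([1] * 5 + [0] * 5, dtype=np.int8)
        v = seed_col.copy()
        v[0] ^= 1
        v[5] ^= 1
        h = HaplotypeMatrix(np.column_stack([seed_col, v]), ["s", "v"])
        r2 = pairwise_ld(h, "s", "v").r2
        groups, ungrouped = group_by_ld(h, ["s"], threshold=r2)
        assert ungrouped == ["v"]
        groups, ungrouped = group_by_ld(h, ["s"], threshold=r2 - 1e-9)
        assert groups[0].members == ["s", "v"]

    def test_block_structure_recovered(self):
        from mprakit.simulate import gen_haplotypes

        h = gen_haplotypes(400, [(6, 0.9), (6, 0.9)], seed=5)
        seeds = [h.variant_ids[0], h.variant_ids[6]]
        groups, ungrouped = group_by_ld(h, seeds, threshold=0.70)
        assert len(groups) == 2
        assert set(groups[0].members) == set(h.variant_ids[:6])
        assert set(groups[1].members) == set(h.variant_ids[6:])
        assert ungrouped == []

    def test_threshold_one_groups_only_exact_duplicates(self):
        rng = np.random.default_rng(2)
        seed_col = rng.integers(0, 2, 60, dtype=np.int8)
        near = seed_col.copy()
        near[0] ^= 1
        h = HaplotypeMatrix(
            np.column_stack([seed_col, seed_col, near]), ["s", "dup", "near"]
        )
        groups, ungrouped = group_by_ld(h, ["s"], threshold=1.0)
        assert groups[0].members == ["s"]
        assert set(ungrouped) == {"dup", "near"}
        # r2 == 1 fails the strict inequality even for duplicates
        groups, ungrouped = group_by_ld(h, ["s"], threshold=1.0 - 1e-12)
        assert "dup" in groups[0].members and "near" in ungrouped

    def test_missing_seed_is_an_error(self):
        h = HaplotypeMatrix(np.array([[0, 1], [1, 0]], dtype=np.int8), ["a", "b"])
        with pytest.raises(KeyError, match="rsMissing"):
            group_by_ld(h, ["rsMissing"])


class TestPrioritize:
    @staticmethod
    def _call(vid, significant):
        return VariantCallSummary(vid, [], ["single"], significant)

    def test_strata_match_relational_join_oracle(self):
        from mprakit.ld import LDGroup

        groups = [LDGroup("LD_grp-1", ["lead1"], ["lead1", "vLinked"], 0.7)]
        calls = [
            self._call("lead1", True),
            self._call("vLinked", True),
            self._call("vLoner", True),
            self._call("vNull", False),
        ]
        table = prioritize(calls, groups, leads=["lead1"]).set_index("variant_id")
        assert table.loc["lead1", "stratum"] == "lead_significant"
        assert table.loc["vLinked", "stratum"] == "linked_significant"
        assert table.loc["vLoner", "stratum"] == "significant_only"
        assert table.loc["vNull", "stratum"] == "not_significant"
        # relational-join oracle over the same inputs
        membership = {m for g in groups for m in g.members}
        for vid, sig in [("lead1", True), ("vLinked", True), ("vLoner", True), ("vNull", False)]:
            expected = (
                "lead_significant" if sig and vid == "lead1"
                else "linked_significant" if sig and vid in membership
                else "significant_only" if sig
                else "not_significant"
            )
            assert table.loc[vid, "stratum"] == expected

    def test_significant_seed_lands_in_top_stratum(self):
        table = prioritize([self._call("lead1", True)], [], leads=["lead1"])
        assert list(table["stratum"]) == ["lead_significant"]
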