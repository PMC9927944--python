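"""Pairwise linkage disequilibrium and seed-anchored LD grouping.

Two-locus statistics are computed from phased haplotypes coded 0 (ref) /
1 (alt): D = p11 - p1*q1 (haplotype-frequency covariance), r^2 its squared
correlation, and D' = D / Dmax the normalized covariance.  LD groups are
seeded by lead GWAS SNPs: seeds in mutual LD above the threshold merge,
then every other variant joins the group of the seed it is most strongly
linked to, provided that r^2 strictly exceeds the threshold (default
0.70).  Prioritization intersects MPRA-significant variants with the
groups to stratify candidates by linkage to lead SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeMatrix",
    "LDPair",
    "LDGroup",
    "MonomorphicError",
    "pairwise_ld",
    "group_by_ld",
    "prioritize",
]


class MonomorphicError(ValueError):
    """LD is undefined when a locus carries a single allele."""


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes x variants matrix of 0/1 alleles."""

    alleles: np.ndarray  # shape (n_haplotypes, n_variants), entries in {0, 1}
    variant_ids: list[str]
    population: str = ""

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 2:
            raise ValueError("haplotype matrix needs >= 2 haplotype rows")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")
        if self.alleles.shape[1] != len(self.variant_ids):
            raise ValueError("column count does not match variant id list")
        self._index = {vid: i for i, vid in enumerate(self.variant_ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def column(self, variant: str | int) -> np.ndarray:
        i = variant if isinstance(variant, int) else self._index[variant]
        return self.alleles[:, i]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.alleles, columns=self.variant_ids).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, population: str = "") -> "HaplotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.values, list(df.columns), population=population)

    @classmethod
    def from_vcf(cls, path: str | Path, population: str = "") -> "HaplotypeMatrix":
        """Load phased genotypes; each sample contributes two haplotype rows."""
        import pysam

        ids, columns = [], []
        with pysam.VariantFile(str(path)) as vcf:
            for i, rec in enumerate(vcf):
                alleles = []
                for sample in rec.samples.values():
                    gt = sample["GT"]
                    if None in gt:
                        raise ValueError(f"missing genotype at {rec.id or rec.pos}")
                    alleles.extend(gt)
                ids.append(rec.id or f"var{i + 1}")
                columns.append(alleles)
        return cls(np.array(columns, dtype=np.int8).T, ids, population=population)


@dataclass(frozen=True)
class LDPair:
    variant_i: str
    variant_j: str
    D: float
    D_prime: float
    r2: float


@dataclass
class LDGroup:
    group_id: str
    seeds: list[str]
    members: list[str]  # includes the seeds
    threshold: float
    member_best_r2: dict[str, float] = field(default_factory=dict)


def _ld_from_frequencies(p1: float, q1: float, p11: float) -> tuple[float, float, float]:
    D = p11 - p1 * q1
    denom = p1 * (1 - p1) * q1 * (1 - q1)
    r2 = D * D / denom
    if D > 0:
        dmax = min(p1 * (1 - q1), (1 - p1) * q1)
    elif D < 0:
        dmax = min(p1 * q1, (1 - p1) * (1 - q1))
    else:
        return 0.0, 0.0, 0.0
    return D, D / dmax, r2


def pairwise_ld(h: HaplotypeMatrix, i: str | int, j: str | int) -> LDPair:
    """Two-locus D, D', and r^2 from phased haplotype counts."""
    a = h.column(i)
    b = h.column(j)
    n = h.n_haplotypes
    p1 = float(a.sum()) / n
    q1 = float(b.sum()) / n
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        which = "first" if p1 in (0.0, 1.0) else "second"
        raise MonomorphicError(f"undefined LD: {which} locus is monomorphic")
    p11 = float((a & b).sum()) / n
    D, D_prime, r2 = _ld_from_frequencies(p1, q1, p11)

    def name(v):
        return v if isinstance(v, str) else h.variant_ids[v]

    return LDPair(name(i), name(j), D=D, D_prime=D_prime, r2=r2)


def ld_table(h: HaplotypeMatrix, ids: list[str] | None = None) -> pd.DataFrame:
    """All-pairs LD statistics as a tidy frame (skips monomorphic loci)."""
    ids = ids or h.variant_ids
    rows = []
    for a_pos, vi in enumerate(ids):
        for vj in ids[a_pos + 1:]:
            try:
                pair = pairwise_ld(h, vi, vj)
            except MonomorphicError:
                continue
            rows.append(
                {"variant_i": pair.variant_i, "variant_j": pair.variant_j,
                 "D": pair.D, "D_prime": pair.D_prime, "r2": pair.r2}
            )
    return pd.DataFrame(rows)


def group_by_ld(
    h: HaplotypeMatrix,
    seeds: list[str],
    threshold: float = 0.70,
) -> tuple[list[LDGroup], list[str]]:
    """Seed-anchored LD grouping at a strict r^2 threshold.

    Each lead SNP seeds a group; seeds whose mutual r^2 exceeds the
    threshold are merged.  Every non-seed variant joins the (merged) group
    of the seed with which its r^2 is highest, if that r^2 strictly
    exceeds the threshold; otherwise it stays ungrouped.  Returns
    (groups, ungrouped_variant_ids) in deterministic order.
    """
    missing = [s for s in seeds if s not in h._index]
    if missing:
        raise KeyError(f"seed SNPs absent from haplotype matrix: {missing}")
    seeds = list(dict.fromkeys(seeds))  # de-dup, keep order

    def r2_of(a: str, b: str) -> float:
        try:
            return pairwise_ld(h, a, b).r2
        except MonomorphicError:
            return float("nan")

    # union-find over seeds
    parent = {s: s for s in seeds}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for a_pos, a in enumerate(seeds):
        for b in seeds[a_pos + 1:]:
            r2 = r2_of(a, b)
            if r2 > threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    cluster_seeds: dict[str, list[str]] = {}
    for s in seeds:
        cluster_seeds.setdefault(find(s), []).append(s)
    clusters = list(cluster_seeds.values())  # ordered by first seed appearance

    assignments: dict[int, list[tuple[str, float]]] = {i: [] for i in range(len(clusters))}
    ungrouped: list[str] = []
    seed_set = set(seeds)
    for vid in h.variant_ids:
        if vid in seed_set:
            continue
        best_r2, best_cluster = -1.0, None
        for ci, cseeds in enumerate(clusters):
            for s in cseeds:
                r2 = r2_of(vid, s)
                if r2 == r2 and r2 > best_r2:  # NaN-safe
                    best_r2, best_cluster = r2, ci
        if best_cluster is not None and best_r2 > threshold:
            assignments[best_cluster].append((vid, best_r2))
        else:
            ungrouped.append(vid)

    groups = []
    for ci, cseeds in enumerate(clusters):
        linked = assignments[ci]
        groups.append(
            LDGroup(
                group_id=f"LD_grp-{ci + 1}",
                seeds=cseeds,
                members=cseeds + [vid for vid, _ in linked],
                threshold=threshold,
                member_best_r2={vid: r2 for vid, r2 in linked},
            )
        )
    return groups, ungrouped


def em_haplotype_frequencies(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> dict[str, float]:
    """Two-locus haplotype frequencies from unphased genotypes by EM.

    Genotypes are alt-allele dosages in {0, 1, 2} per individual.  Only
    double heterozygotes are phase-ambiguous; the EM splits them between
    the coupling (11/00) and repulsion (10/01) configurations in
    proportion to the current haplotype-frequency estimates.  Off the
    default path: phased input is the contract, this is a convenience for
    genotype-only data.
    """
    gi = np.asarray(genotypes_i, dtype=int)
    gj = np.asarray(genotypes_j, dtype=int)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must have equal length")
    if not (np.isin(gi, (0, 1, 2)).all() and np.isin(gj, (0, 1, 2)).all()):
        raise ValueError("genotypes must be dosages in {0, 1, 2}")
    n_hap = 2 * len(gi)
    # fixed (phase-unambiguous) haplotype counts
    fixed = {"11": 0.0, "10": 0.0, "01": 0.0, "00": 0.0}
    n_dh = 0
    for a, b in zip(gi, gj):
        if a == 1 and b == 1:
            n_dh += 1
            continue
        # each individual contributes two haplotypes with known phase
        ha = [1] * a + [0] * (2 - a)
        hb = [1] * b + [0] * (2 - b)
        for x, y in zip(ha, hb):
            fixed[f"{x}{y}"] += 1.0
    freq = {k: 0.25 for k in fixed}
    for _ in range(max_iter):
        # E: split double heterozygotes between coupling and repulsion
        coupling = freq["11"] * freq["00"]
        repulsion = freq["10"] * freq["01"]
        total = coupling + repulsion
        w = 0.5 if total == 0 else coupling / total
        counts = dict(fixed)
        counts["11"] += n_dh * w
        counts["00"] += n_dh * w
        counts["10"] += n_dh * (1 - w)
        counts["01"] += n_dh * (1 - w)
        new = {k: v / n_hap for k, v in counts.items()}
        delta = max(abs(new[k] - freq[k]) for k in freq)
        freq = new
        if delta < tol:
            break
    return freq


def pairwise_ld_unphased(
    genotypes_i: np.ndarray, genotypes_j: np.ndarray,
    name_i: str = "i", name_j: str = "j",
) -> LDPair:
    """LD statistics with haplotype frequencies estimated by EM."""
    freq = em_haplotype_frequencies(genotypes_i, genotypes_j)
    p1 = freq["11"] + freq["10"]
    q1 = freq["11"] + freq["01"]
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise MonomorphicError("undefined LD: a locus is monomorphic")
    D, D_prime, r2 = _ld_from_frequencies(p1, q1, freq["11"])
    return LDPair(name_i, name_j, D=D, D_prime=D_prime, r2=r2)


def prioritize(
    calls,
    groups: list[LDGroup],
    leads: list[str],
) -> pd.DataFrame:
    """Stratify MPRA-tested variants by significance and lead-SNP linkage.

    ``calls`` is a list of VariantCallSummary.  Strata: "lead_significant"
    (a lead SNP with allele-specific activity), "linked_significant"
    (significant and in an LD group with a lead), "significant_only", and
    "not_significant".
    """
    lead_set = set(leads)
    group_of: dict[str, str] = {}
    for g in groups:
        for member in g.members:
            group_of.setdefault(member, g.group_id)
    rows = []
    for call in calls:
        vid = call.variant_id
        group = group_of.get(vid)
        is_lead = vid in lead_set
        linked = group is not None
        if call.any_significant and is_lead:
            stratum = "lead_significant"
        elif call.any_significant and linked:
            stratum = "linked_significant"
        elif call.any_significant:
            stratum = "significant_only"
        else:
            stratum = "not_significant"
        rows.append(
            {
                "variant_id": vid,
                "any_significant": call.any_significant,
                "is_lead": is_lead,
                "ld_group": group if group is not None else "",
                "linked_to_lead": linked,
                "stratum": stratum,
            }
        )
    order = ["lead_significant", "linked_significant", "significant_only", "not_significant"]
    df = pd.DataFrame(rows)
    if len(df):
        df["stratum"] = pd.Categorical(df["stratum"], categories=order, ordered=True)
        df = df.sort_values(["stratum", "variant_id"]).reset_index(drop=True)
    return df
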