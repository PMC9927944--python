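"""File I/O for the pipeline's standard formats.

FASTA/FASTQ go through Biopython, VCF through pysam, tables through
pandas.  All tables are plain TSV; FASTQ may be gzipped.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import DesignParams, FragmentCatalog, VariantRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_variants_vcf",
    "write_variants_vcf",
    "iter_fastq_pairs",
    "write_fastq_pairs",
    "write_catalog",
    "write_manifest",
    "read_counts_tsv",
    "read_library_manifest",
    "write_json",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Load candidate variants from a (plain or bgzipped) VCF."""
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            annotations = {k: str(v) for k, v in rec.info.items()}
            variants.append(
                VariantRecord(
                    id=rec.id or f"var{i + 1}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    annotations=annotations,
                )
            )
    return variants


def write_variants_vcf(
    variants: list[VariantRecord],
    path: str | Path,
    contig_lengths: dict[str, int],
) -> None:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("LEAD", 0, "Flag", "Lead GWAS SNP")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref,) + v.alts,
                id=v.id,
            )
            if v.annotations.get("LEAD"):
                rec.info["LEAD"] = True
            out.write(rec)


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str]]:
    """Yield (read1 sequence, read2 sequence) pairs from paired FASTQ."""
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        for rec1, rec2 in zip(
            SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq"), strict=True
        ):
            yield str(rec1.seq), str(rec2.seq)


def write_fastq_pairs(
    pairs: Iterable[tuple[str, str, str]],
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Write (name, seq1, seq2) triples as paired FASTQ with dummy quality."""

    def record(name: str, seq: str) -> SeqRecord:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        return rec

    pairs = list(pairs)
    SeqIO.write([record(n, s1) for n, s1, _ in pairs], str(r1_path), "fastq")
    SeqIO.write([record(n, s2) for n, _, s2 in pairs], str(r2_path), "fastq")


def write_catalog(catalog: FragmentCatalog, out_prefix: str | Path) -> dict[str, Path]:
    """Write catalog FASTA (variable regions), oligo FASTA, and manifest TSV."""
    out_prefix = Path(out_prefix)
    paths = {
        "fragments": out_prefix.with_suffix(".fragments.fa"),
        "oligos": out_prefix.with_suffix(".oligos.fa"),
        "manifest": out_prefix.with_suffix(".manifest.tsv"),
    }
    write_fasta(((e.fragment_id, e.sequence) for e in catalog.entries), paths["fragments"])
    write_fasta(((o.fragment_id, o.full_sequence) for o in catalog.oligos()), paths["oligos"])
    write_manifest(catalog, paths["manifest"])
    return paths


def write_manifest(catalog: FragmentCatalog, path: str | Path) -> None:
    rows = []
    for entry in catalog.entries:
        for frag in catalog.provenance[entry.fragment_id]:
            rows.append(
                {
                    "fragment_id": entry.fragment_id,
                    "chrom": frag.chrom,
                    "window_start": frag.window[0],
                    "window_end": frag.window[1],
                    "center_variant": frag.center_variant,
                    "allele_assignment": ";".join(
                        f"{vid}:{allele}"
                        for vid, allele in frag.allele_assignment.items()
                    ),
                    "is_reference": frag.is_reference,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a barcode x library count matrix (first column = barcode)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return df.set_index(df.columns[0])


def read_library_manifest(path: str | Path) -> pd.DataFrame:
    """Read the library manifest: columns library, role (pDNA/cDNA), pair."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"library manifest must have columns {sorted(required)}")
    return df


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
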