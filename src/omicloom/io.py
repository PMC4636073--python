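"""Readers and writers for the on-disk formats the pipeline exchanges.

Internal coordinates are 0-based half-open; GTF and VCF are written and
read with their native 1-based conventions. All writers emit records in a
deterministic order so that fixed seed + config gives byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Annotation, Interval, Transcript

PILEUP_COLUMNS = ["chrom", "pos0", "ref", "strand", "A", "C", "G", "T"]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Emit gene/transcript/exon/CDS/UTR features (1-based inclusive)."""

    def line(t: Transcript, feature: str, iv: Interval) -> str:
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_biotype "{t.biotype}";'
        )
        return (
            f"{t.chrom}\tomicloom\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{t.strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        for t in annotation:
            fh.write(line(t, "transcript", Interval(t.start, t.end)))
            for e in t.exons:
                fh.write(line(t, "exon", e))
            for iv in t.cds_intervals():
                fh.write(line(t, "CDS", iv))
            for iv in t.utr5_intervals():
                fh.write(line(t, "five_prime_utr", iv))
            for iv in t.utr3_intervals():
                fh.write(line(t, "three_prime_utr", iv))


def read_gtf(path: str | Path) -> Annotation:
    """Rebuild transcript models from a GTF written by :func:`write_gtf`.

    Only exon and CDS records are needed; UTRs are re-derived from the CDS
    span, so GTFs from other producers that follow the same attribute keys
    also load.
    """
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, dict] = {}
    cds_bounds: dict[str, list[int]] = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attr_str = raw.rstrip(
                "\n"
            ).split("\t")
            attrs = dict(_ATTR_RE.findall(attr_str))
            tid = attrs["transcript_id"]
            meta.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("gene_biotype", "protein_coding"),
                },
            )
            iv = Interval(int(start) - 1, int(end))
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feature == "CDS":
                cds_bounds.setdefault(tid, []).extend([iv.start, iv.end])
    transcripts = []
    for tid, m in meta.items():
        if tid not in exons:
            continue
        bounds = cds_bounds.get(tid)
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=sorted(exons[tid], key=lambda e: e.start),
                biotype=m["biotype"],
                cds_start=min(bounds) if bounds else None,
                cds_end=max(bounds) if bounds else None,
            )
        )
    return Annotation(transcripts)


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tdonor
"""


def write_vcf(
    variants: list[tuple[str, int, str, str, str]], path: str | Path
) -> None:
    """Write (chrom, pos0, ref, alt, zygosity) records as VCF v4.2.

    zygosity is 'het' or 'hom'; genotypes emitted as 0/1 and 1/1.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom, pos0, ref, alt, zyg in sorted(variants):
            gt = "0/1" if zyg == "het" else "1/1"
            fh.write(
                f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_vcf(path: str | Path) -> list[tuple[str, int, str, str, str]]:
    """Read a VCF into (chrom, pos0, ref, alt, zygosity) tuples via cyvcf2."""
    from cyvcf2 import VCF

    out = []
    vcf = VCF(str(path))
    for rec in vcf:
        gts = rec.genotypes[0] if rec.genotypes else [1, 1, False]
        alleles = {g for g in gts[:-1] if g >= 0}
        zyg = "het" if len(alleles) > 1 else "hom"
        for alt in rec.ALT:
            out.append((rec.CHROM, rec.POS - 1, rec.REF, alt, zyg))
    vcf.close()
    return out


# ---------------------------------------------------------------------------
# Pileup and plain tables

def write_pileup(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "strand": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
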