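"""Allele-specific expression (ASE) from RNA allele counts at het SNPs.

Heterozygous SNPs make the two alleles of a gene distinguishable in
RNA-Seq. Per informative site (>= ``min_total`` reads over both alleles):

* monoallelic — the minor allele has zero reads;
* allele_specific — major/minor fold change >= ``min_fold`` (inclusive,
  "at least a 5-fold difference");
* biallelic — otherwise.

A gene is monoallelic when every informative site is monoallelic (and the
gene has at least ``min_mono_reads`` total, so zero-coverage genes are not
miscalled), allele_specific when every informative site is allele-specific
or monoallelic, biallelic as soon as one informative site is biallelic,
and uninformative without informative sites. Without phasing, any per-site
pattern of major alleles is compatible with a single major haplotype
(each site's phase is free), so ``direction_consistent`` is true for
unphased input and the call is flagged ``phased=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .models import Annotation


@dataclass
class HetSiteCount:
    chrom: str
    pos: int
    gene_id: str
    ref_allele: str
    alt_allele: str
    ref_reads: int
    alt_reads: int
    other_reads: int = 0  # neither allele; kept for QC only


@dataclass
class AseCall:
    gene_id: str
    n_informative_sites: int
    total_reads: int
    fold: float  # major/minor over pooled informative sites; inf if minor == 0
    call: str  # biallelic | allele_specific | monoallelic | uninformative
    direction_consistent: bool
    phased: bool = False


def tally_het_sites(
    pileup: pd.DataFrame,
    variants: list[tuple[str, int, str, str, str]],
    annotation: Annotation,
) -> list[HetSiteCount]:
    """One count record per heterozygous SNP inside an annotated gene.

    Homozygous and indel records are skipped; het sites missing from the
    pileup are emitted with zero counts. Reads matching neither allele are
    tallied separately and do not enter the ASE arithmetic.
    """
    trees: dict[str, IntervalTree] = {}
    for tx in annotation:
        trees.setdefault(tx.chrom, IntervalTree()).addi(
            tx.start, tx.end, tx.gene_id
        )
    counts = {
        (r.chrom, r.pos0): {"A": r.A, "C": r.C, "G": r.G, "T": r.T}
        for r in pileup.itertuples(index=False)
    }
    out = []
    for chrom, pos, ref, alt, zyg in variants:
        if zyg != "het" or len(ref) != 1 or len(alt) != 1:
            continue
        hits = trees.get(chrom, IntervalTree())[pos]
        if not hits:
            continue
        gene_id = sorted(h.data for h in hits)[0]
        c = counts.get((chrom, pos), {"A": 0, "C": 0, "G": 0, "T": 0})
        out.append(
            HetSiteCount(
                chrom=chrom,
                pos=pos,
                gene_id=gene_id,
                ref_allele=ref,
                alt_allele=alt,
                ref_reads=int(c[ref]),
                alt_reads=int(c[alt]),
                other_reads=int(sum(c.values()) - c[ref] - c[alt]),
            )
        )
    return out


def classify_site(
    ref_reads: int, alt_reads: int, min_total: int = 10, min_fold: float = 5.0
) -> str:
    """Per-site ASE class: uninformative / monoallelic / allele_specific / biallelic."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total < min_total:
        return "uninformative"
    minor = min(ref_reads, alt_reads)
    if minor == 0:
        return "monoallelic"
    if max(ref_reads, alt_reads) / minor >= min_fold:
        return "allele_specific"
    return "biallelic"


def call_ase(
    sites: list[HetSiteCount],
    min_total: int = 10,
    min_fold: float = 5.0,
    min_mono_reads: int = 10,
) -> list[AseCall]:
    """Aggregate per-site classes into one call per gene."""
    by_gene: dict[str, list[HetSiteCount]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)

    calls = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]
        classes = [
            classify_site(s.ref_reads, s.alt_reads, min_total, min_fold)
            for s in group
        ]
        informative = [
            (s, cl) for s, cl in zip(group, classes) if cl != "uninformative"
        ]
        total = sum(s.ref_reads + s.alt_reads for s, _ in informative)
        major = sum(max(s.ref_reads, s.alt_reads) for s, _ in informative)
        minor = total - major
        fold = float("inf") if minor == 0 else major / minor
        if not informative:
            call = "uninformative"
        elif all(cl == "monoallelic" for _, cl in informative):
            # the read floor keeps barely-covered genes out of the mono set
            call = "monoallelic" if total >= min_mono_reads else "uninformative"
        elif any(cl == "biallelic" for _, cl in informative):
            call = "biallelic"
        else:  # a mix of allele_specific and monoallelic sites
            call = "allele_specific"
        calls.append(
            AseCall(
                gene_id=gene_id,
                n_informative_sites=len(informative),
                total_reads=total,
                fold=fold,
                call=call,
                # unphased: per-site phase is free, so some haplotype always
                # carries every site's major allele
                direction_consistent=True,
                phased=False,
            )
        )
    return calls


def ase_summary(calls: list[AseCall]) -> dict[str, int]:
    out = {
        "n_genes": len(calls),
        "monoallelic": 0,
        "allele_specific": 0,
        "biallelic": 0,
        "uninformative": 0,
    }
    for c in calls:
        out[c.call] += 1
    return out


def calls_to_frame(calls: list[AseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "n_informative_sites": c.n_informative_sites,
                "total_reads": c.total_reads,
                "fold": c.fold,
                "call": c.call,
                "direction_consistent": c.direction_consistent,
                "phased": c.phased,
            }
            for c in calls
        ]
    )
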