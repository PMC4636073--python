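"""RNA-DNA difference (RDD) detection with its filter cascade.

An RDD is a transcriptome site whose base calls differ from the genome
reference — an RNA-editing candidate once two classes of false positives
are removed:

1. germline variants: any candidate coinciding with a sequenced DNA variant
   (position match, any zygosity; candidates within a few bases of an indel
   are treated the same, since indel realignment is a classic false-RDD
   source), and
2. alignment artifacts: candidates whose flanking sequence, with the RDD
   base substituted in, matches a second locus in the genome almost exactly
   — the signature of reads cross-mapped from a paralog or pseudogene.

The artifact decision is made by an internal substituted-flank uniqueness
search (exact seed + Hamming verification on both strands), which asks the
same question an external aligner would: does this RDD-bearing sequence
align elsewhere?

Surviving candidates are classified by substitution type — A-to-G and
C-to-T are canonical deamination events; G-to-A and T-to-C are the same
events observed with the transcript strand unassigned — annotated by
transcript region, optionally reconciled against targeted DNA/RNA
re-sequencing, and screened for created/destroyed miRNA seed matches in
3'UTRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import Annotation, Transcript, revcomp

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_B2I = {b: i for i, b in enumerate("ACGT")}

CANONICAL = {("A", "G"), ("C", "T")}
STRAND_FLIPPED = {("G", "A"), ("T", "C")}


@dataclass
class RddCandidate:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    rdd_base: str
    strand: str  # '+', '-', or '.' (unknown)
    depth: int
    rdd_count: int
    rdd_fraction: float
    filter_status: str = "candidate"  # candidate|genomic_variant|alignment_artifact|pass
    substitution_class: str = ""
    region: str = ""


# ---------------------------------------------------------------------------
# Candidate calling


def call_candidates(
    pileup: pd.DataFrame,
    genome: dict[str, str],
    min_depth: int = 10,
    min_alt_reads: int = 3,
    min_fraction: float = 0.10,
) -> list[RddCandidate]:
    """Emit a candidate wherever a non-reference base clears the thresholds.

    ``depth`` is the total of the four base counts at the site; every
    non-reference base is tested independently, so one site can yield more
    than one candidate.
    """
    out: list[RddCandidate] = []
    for row in pileup.itertuples(index=False):
        ref = row.ref
        if ref not in _B2I:
            raise ValueError(f"pileup ref base {ref!r} at {row.chrom}:{row.pos0}")
        counts = {"A": row.A, "C": row.C, "G": row.G, "T": row.T}
        depth = sum(counts.values())
        if depth < min_depth:
            continue
        if genome[row.chrom][row.pos0] != ref:
            raise ValueError(
                f"pileup/reference mismatch at {row.chrom}:{row.pos0}"
            )
        for base, n in counts.items():
            if base == ref or n < min_alt_reads:
                continue
            frac = n / depth
            if frac < min_fraction:
                continue
            out.append(
                RddCandidate(
                    chrom=row.chrom,
                    pos=int(row.pos0),
                    ref_base=ref,
                    rdd_base=base,
                    strand=str(row.strand),
                    depth=int(depth),
                    rdd_count=int(n),
                    rdd_fraction=float(frac),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Germline-variant subtraction


def filter_genomic_variants(
    candidates: list[RddCandidate],
    variants: list[tuple[str, int, str, str, str]],
    genome: dict[str, str] | None = None,
    indel_window: int = 5,
) -> list[RddCandidate]:
    """Flag candidates at (or, for indels, near) known DNA variants.

    Matching is by position only — more conservative than requiring the
    alt allele to agree. Candidates within ``indel_window`` bases of an
    indel are also flagged, since realignment wobble around indels is the
    dominant source of spurious RDDs.
    """
    cand_chroms = {c.chrom for c in candidates}
    var_chroms = {v[0] for v in variants}
    unknown = var_chroms - set(genome) if genome is not None else set()
    if unknown:
        raise ValueError(
            f"variant contigs absent from reference: {sorted(unknown)}"
        )
    if cand_chroms and var_chroms and not (cand_chroms & var_chroms):
        raise ValueError(
            "no shared contigs between pileup and VCF "
            f"(pileup: {sorted(cand_chroms)}, vcf: {sorted(var_chroms)})"
        )
    masked: set[tuple[str, int]] = set()
    for chrom, pos, ref, alt, _zyg in variants:
        masked.add((chrom, pos))
        if len(ref) != 1 or len(alt) != 1:  # indel: mask the neighbourhood
            span = max(len(ref), len(alt))
            for d in range(-indel_window, span + indel_window):
                masked.add((chrom, pos + d))
    for c in candidates:
        if c.filter_status == "candidate" and (c.chrom, c.pos) in masked:
            c.filter_status = "genomic_variant"
    return candidates


# ---------------------------------------------------------------------------
# Alignment-artifact filtering


def _window_with_substitution(
    seq: str, pos: int, base: str, flank: int
) -> tuple[str, int]:
    """2*flank+1 window centred on pos with the RDD base substituted in.

    Truncated (with a warning) at contig edges; returns (window, start).
    """
    lo = pos - flank
    hi = pos + flank + 1
    if lo < 0 or hi > len(seq):
        logger.warning(
            "flank window at %d truncated to contig bounds [0, %d)", pos, len(seq)
        )
        lo, hi = max(lo, 0), min(hi, len(seq))
    return seq[lo:pos] + base + seq[pos + 1 : hi], lo


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _mismatch_profile(hay: np.ndarray, needle: np.ndarray) -> np.ndarray:
    """Hamming distance of ``needle`` against every offset of ``hay``."""
    L = needle.size
    n = hay.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    mm = np.zeros(n, dtype=np.int32)
    for j in range(L):
        mm += hay[j : j + n] != needle[j]
    return mm


def has_second_locus(
    genome: dict[str, str],
    chrom: str,
    pos: int,
    rdd_base: str,
    flank: int = 25,
    max_mismatches: int = 2,
    _cache: dict | None = None,
) -> bool:
    """True if the substituted flank matches a second locus on either strand."""
    window, wstart = _window_with_substitution(genome[chrom], pos, rdd_base, flank)
    needle = _encode(window)
    L = needle.size
    for name, seq in genome.items():
        if _cache is not None:
            fwd, rc = _cache.setdefault(
                name, (_encode(seq), _encode(revcomp(seq)))
            )
        else:
            fwd, rc = _encode(seq), _encode(revcomp(seq))
        mm = _mismatch_profile(fwd, needle)
        for i in np.flatnonzero(mm <= max_mismatches):
            # exclude the candidate's own locus (window overlap)
            if name == chrom and i < wstart + L and wstart < i + L:
                continue
            return True
        mm = _mismatch_profile(rc, needle)
        G = len(seq)
        for i in np.flatnonzero(mm <= max_mismatches):
            f_lo, f_hi = G - int(i) - L, G - int(i)  # forward-strand footprint
            if name == chrom and f_lo < wstart + L and wstart < f_hi:
                continue
            return True
    return False


def filter_alignment_artifacts(
    candidates: list[RddCandidate],
    genome: dict[str, str],
    flank: int = 25,
    max_mismatches: int = 2,
) -> list[RddCandidate]:
    """Flag cross-mapping artifacts; the survivors become ``pass``."""
    if flank < 15:
        raise ValueError(f"flank must be >= 15, got {flank}")
    cache: dict = {}
    for c in candidates:
        if c.filter_status != "candidate":
            continue
        if has_second_locus(
            genome, c.chrom, c.pos, c.rdd_base, flank, max_mismatches, cache
        ):
            c.filter_status = "alignment_artifact"
        else:
            c.filter_status = "pass"
    return candidates


# ---------------------------------------------------------------------------
# Substitution classification


def classify_substitution(
    ref_base: str, rdd_base: str, strand: str | None = None
) -> str:
    """Classify a substitution as canonical / strand-flipped / noncanonical.

    ``ref_base``/``rdd_base`` are forward-genome-strand observations. When
    the transcript strand is known to be '-', the pair is complemented to
    transcript orientation first, so a genomic T-to-C on a minus-strand
    transcript is reported as the canonical A-to-G it really is.
    """
    if ref_base == rdd_base:
        raise ValueError("ref and RDD base must differ")
    if strand == "-":
        ref_base, rdd_base = _COMP[ref_base], _COMP[rdd_base]
    pair = (ref_base, rdd_base)
    if pair in CANONICAL:
        return "canonical"
    if pair in STRAND_FLIPPED:
        return "canonical_strand_flipped"
    return "noncanonical"


def classify_candidates(candidates: list[RddCandidate]) -> list[RddCandidate]:
    for c in candidates:
        strand = c.strand if c.strand in "+-" else None
        c.substitution_class = classify_substitution(c.ref_base, c.rdd_base, strand)
    return candidates


def substitution_matrix(candidates: list[RddCandidate]) -> pd.DataFrame:
    """4x4 ref-by-observed substitution counts over a candidate set."""
    mat = pd.DataFrame(0, index=list("ACGT"), columns=list("ACGT"))
    for c in candidates:
        mat.loc[c.ref_base, c.rdd_base] += 1
    return mat


# ---------------------------------------------------------------------------
# Region annotation


_REGION_RANK = {"CDS": 0, "5'UTR": 1, "3'UTR": 1, "noncoding": 2}


def build_region_index(annotation: Annotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for tx in annotation:
        tree = trees.setdefault(tx.chrom, IntervalTree())
        if tx.is_coding:
            for iv in tx.cds_intervals():
                tree.addi(iv.start, iv.end, "CDS")
            for iv in tx.utr5_intervals():
                tree.addi(iv.start, iv.end, "5'UTR")
            for iv in tx.utr3_intervals():
                tree.addi(iv.start, iv.end, "3'UTR")
        else:
            for e in tx.exons:
                tree.addi(e.start, e.end, "noncoding")
    return trees


def annotate_region(
    candidates: list[RddCandidate], annotation: Annotation
) -> list[RddCandidate]:
    """Assign CDS / 5'UTR / 3'UTR / noncoding / intergenic by overlap.

    A site covered by several feature classes takes the highest-precedence
    one: CDS > UTR > noncoding.
    """
    trees = build_region_index(annotation)
    for c in candidates:
        hits = trees.get(c.chrom, IntervalTree())[c.pos]
        labels = sorted((h.data for h in hits), key=_REGION_RANK.__getitem__)
        c.region = labels[0] if labels else "intergenic"
    return candidates


def region_distribution(candidates: list[RddCandidate]) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in candidates:
        out[c.region or "unannotated"] = out.get(c.region or "unannotated", 0) + 1
    return out


# ---------------------------------------------------------------------------
# Validation reconciliation


@dataclass
class ValidationRecord:
    chrom: str
    pos: int
    dna_ref_count: int
    dna_alt_count: int
    rna_ref_count: int
    rna_alt_count: int
    verdict: str = ""


def reconcile_validation(
    records: list[ValidationRecord], dna_af_min: float = 0.1
) -> tuple[list[ValidationRecord], dict[str, int]]:
    """Adjudicate targeted re-sequencing of putative editing sites.

    A site whose DNA alt fraction reaches ``dna_af_min`` was a germline
    variant the original genome sequencing missed; otherwise >= 3 RNA reads
    on the edited base validate the RDD, and 0-2 supporting reads mean the
    original call was likely a sequencing error.
    """
    kept = []
    summary = {"snp_missed_by_wgs": 0, "validated_rdd": 0, "unsupported": 0}
    for r in records:
        dna_depth = r.dna_ref_count + r.dna_alt_count
        if dna_depth == 0:
            logger.warning("zero DNA depth at %s:%d; excluded", r.chrom, r.pos)
            continue
        if r.dna_alt_count / dna_depth >= dna_af_min:
            r.verdict = "snp_missed_by_wgs"
        elif r.rna_alt_count >= 3:
            r.verdict = "validated_rdd"
        else:
            r.verdict = "unsupported"
        summary[r.verdict] += 1
        kept.append(r)
    return kept, summary


# ---------------------------------------------------------------------------
# miRNA seed impact


@dataclass
class Utr3Sequence:
    """A transcript's 3'UTR in transcript (5'->3') orientation."""

    transcript: Transcript
    seq: str
    t_offset: int  # transcript coordinate of the UTR's first base

    def offset_of(self, chrom: str, pos: int) -> int | None:
        if chrom != self.transcript.chrom:
            return None
        t = self.transcript.genome_to_transcript(pos)
        if t is None or not (self.t_offset <= t < self.t_offset + len(self.seq)):
            return None
        return t - self.t_offset


def build_utr3_sequences(
    annotation: Annotation, genome: dict[str, str]
) -> dict[str, Utr3Sequence]:
    out = {}
    for tx in annotation:
        if not tx.is_coding:
            continue
        span = tx.cds_transcript_span()
        spliced = tx.spliced_sequence(genome)
        if span[1] < len(spliced):
            out[tx.transcript_id] = Utr3Sequence(
                transcript=tx, seq=spliced[span[1] :], t_offset=span[1]
            )
    return out


def seed_sequence(mirna: str) -> str:
    """miRNA seed: nucleotides 2-8 (a 7-mer), as DNA."""
    s = mirna.upper().replace("U", "T")
    if len(s) < 8:
        raise ValueError(f"miRNA sequence shorter than 8 nt: {mirna!r}")
    return s[1:8]


def _site_matches(utr: str, target: str, offset: int) -> set[int]:
    """Start positions of ``target`` matches that cover ``offset``."""
    k = len(target)
    hits = set()
    for p in range(max(0, offset - k + 1), min(len(utr) - k, offset) + 1):
        if utr[p : p + k] == target:
            hits.add(p)
    return hits


def mirna_seed_impact(
    candidates: list[RddCandidate],
    mirna_seqs: dict[str, str],
    utrs: dict[str, Utr3Sequence],
) -> pd.DataFrame:
    """Seed-site creation/destruction by editing, per (site, miRNA) pair.

    For each passing 3'UTR candidate, the reverse complement of each
    miRNA's seed is searched in the edited versus unedited UTR sequence,
    restricted to match windows covering the edited base. A match present
    only before editing is destroyed; one present only after is created.
    Rows are emitted for destroyed and created matches; the summary counts
    are stored in ``df.attrs``.
    """
    rows = []
    for c in candidates:
        if c.filter_status != "pass":
            continue
        hit = None
        for utr in utrs.values():
            off = utr.offset_of(c.chrom, c.pos)
            if off is not None:
                hit = (utr, off)
                break
        if hit is None:
            raise ValueError(
                f"edit site {c.chrom}:{c.pos} not inside any provided UTR sequence"
            )
        utr, off = hit
        strand = utr.transcript.strand
        edited_base = c.rdd_base if strand == "+" else _COMP[c.rdd_base]
        unedited = utr.seq
        edited = unedited[:off] + edited_base + unedited[off + 1 :]
        for name, mseq in mirna_seqs.items():
            target = revcomp(seed_sequence(mseq))
            before = _site_matches(unedited, target, off)
            after = _site_matches(edited, target, off)
            for _ in before - after:
                rows.append(
                    {
                        "chrom": c.chrom,
                        "pos": c.pos,
                        "transcript_id": utr.transcript.transcript_id,
                        "mirna": name,
                        "impact": "destroys_seed_match",
                    }
                )
            for _ in after - before:
                rows.append(
                    {
                        "chrom": c.chrom,
                        "pos": c.pos,
                        "transcript_id": utr.transcript.transcript_id,
                        "mirna": name,
                        "impact": "creates_seed_match",
                    }
                )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "transcript_id", "mirna", "impact"]
    )
    df.attrs["summary"] = {
        "n_destroyed": int((df["impact"] == "destroys_seed_match").sum()),
        "n_created": int((df["impact"] == "creates_seed_match").sum()),
    }
    return df


# ---------------------------------------------------------------------------
# Cascade orchestration


@dataclass
class RddSummary:
    n_candidates: int
    n_genomic_variant: int
    n_alignment_artifact: int
    n_pass: int
    substitution_matrix: pd.DataFrame
    region_distribution: dict[str, int]

    def partition_holds(self) -> bool:
        return self.n_candidates == (
            self.n_genomic_variant + self.n_alignment_artifact + self.n_pass
        )

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_genomic_variant": self.n_genomic_variant,
            "n_alignment_artifact": self.n_alignment_artifact,
            "n_pass": self.n_pass,
            "substitution_matrix": self.substitution_matrix.to_dict(),
            "region_distribution": self.region_distribution,
        }


def run_rdd_pipeline(
    pileup: pd.DataFrame,
    genome: dict[str, str],
    variants: list[tuple[str, int, str, str, str]],
    annotation: Annotation,
    min_depth: int = 10,
    min_alt_reads: int = 3,
    min_fraction: float = 0.10,
    flank: int = 25,
    max_mismatches: int = 2,
) -> tuple[list[RddCandidate], RddSummary]:
    """Candidate calling -> variant subtraction -> artifact filter -> annotation."""
    cands = call_candidates(pileup, genome, min_depth, min_alt_reads, min_fraction)
    filter_genomic_variants(cands, variants, genome)
    filter_alignment_artifacts(cands, genome, flank, max_mismatches)
    classify_candidates(cands)
    annotate_region(cands, annotation)
    statuses = [c.filter_status for c in cands]
    passing = [c for c in cands if c.filter_status == "pass"]
    summary = RddSummary(
        n_candidates=len(cands),
        n_genomic_variant=statuses.count("genomic_variant"),
        n_alignment_artifact=statuses.count("alignment_artifact"),
        n_pass=len(passing),
        substitution_matrix=substitution_matrix(cands),
        region_distribution=region_distribution(passing),
    )
    return cands, summary


def candidates_to_frame(candidates: list[RddCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos0": c.pos,
                "ref_base": c.ref_base,
                "rdd_base": c.rdd_base,
                "strand": c.strand,
                "depth": c.depth,
                "rdd_count": c.rdd_count,
                "rdd_fraction": c.rdd_fraction,
                "filter_status": c.filter_status,
                "substitution_class": c.substitution_class,
                "region": c.region,
            }
            for c in candidates
        ]
    )
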