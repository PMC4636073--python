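"""Proteogenomic search-database construction and peptide back-mapping.

Mass-spectrometry searches only find peptides present in the database they
are run against; discovering unannotated coding regions therefore requires
custom databases. This module builds the classic set:

* ``six_frame`` — stop-to-stop ORFs from all six genome reading frames;
* ``three_frame`` — ORFs from the three forward frames of every annotated
  transcript (mRNA, ncRNA, pseudogene), spliced through the exon chain;
* ``variant`` — tryptic peptides altered by coding genomic variants;
* ``alt_start_upstream`` / ``alt_start_downstream`` — N-terminal peptides
  from in-frame methionines near annotated translation starts;
* ``signal_cleavage`` — semi-tryptic mature-protein N-termini downstream of
  signal-peptide cleavage sites;
* ``junction`` — peptides spanning exon-exon splice junctions.

Every entry carries genome intervals (0-based half-open blocks with
strand) whose strand-aware translation reproduces the peptide, so an
identified peptide maps straight back to coordinates. ORFs are stop-to-stop
rather than ATG-initiated, which maximizes sensitivity for novel peptides;
an ATG-initiated mode is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .models import Annotation, Transcript, revcomp

STOP = "*"


@dataclass
class DigestParams:
    """Trypsin in-silico digestion settings (cleave after K/R, not before P)."""

    missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 45

    def __post_init__(self) -> None:
        if self.min_len < 5:
            raise ValueError(f"min_len must be >= 5, got {self.min_len}")
        if self.max_len <= self.min_len:
            raise ValueError("max_len must exceed min_len")


@dataclass
class PeptideDbEntry:
    peptide: str
    source_class: str
    origin: str  # contig or transcript id, plus frame / CDS anchor
    genome_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    header: str = ""
    variant: tuple[str, int, str, str] | None = None  # applied DNA change
    annotation_note: str = ""  # e.g. "K45E" for variant peptides


def translate_nt(nt: str) -> str:
    """Standard-table translation; trailing partial codon dropped, N -> X."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


# ---------------------------------------------------------------------------
# Trypsin digestion


def cleavage_boundaries(seq: str) -> list[int]:
    """All tryptic boundaries of ``seq``: 0, each post-K/R point, len(seq)."""
    pts = [0]
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR" and seq[i + 1] != "P":
            pts.append(i + 1)
    pts.append(len(seq))
    return pts


def digest(
    seq: str, params: DigestParams | None = None
) -> list[tuple[int, int, str]]:
    """Tryptic peptides as (start, end, sequence), up to the allowed missed
    cleavages and within the length window."""
    p = params or DigestParams()
    b = cleavage_boundaries(seq)
    out = []
    for i in range(len(b) - 1):
        for j in range(i + 1, min(i + 2 + p.missed_cleavages, len(b))):
            s, e = b[i], b[j]
            if p.min_len <= e - s <= p.max_len:
                out.append((s, e, seq[s:e]))
    return out


# ---------------------------------------------------------------------------
# Frame translations


def _orf_spans(protein: str, min_orf_aa: int) -> list[tuple[int, int]]:
    """Stop-to-stop segments (aa coordinates) of length >= min_orf_aa."""
    spans = []
    start = 0
    for i, aa in enumerate(protein + STOP):
        if aa == STOP:
            if i - start >= min_orf_aa:
                spans.append((start, i))
            start = i + 1
    return spans


def translate_six_frame(
    genome: dict[str, str], min_orf_aa: int = 20, atg_initiated: bool = False
) -> list[PeptideDbEntry]:
    """Stop-to-stop ORFs in all six frames of every contig."""
    entries = []
    for chrom, seq in genome.items():
        G = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for frame in range(3):
                prot = translate_nt(s[frame:])
                for a, b in _orf_spans(prot, min_orf_aa):
                    pep = prot[a:b]
                    if atg_initiated:
                        m = pep.find("M")
                        if m < 0 or b - (a + m) < min_orf_aa:
                            continue
                        a, pep = a + m, pep[m:]
                    if "X" in pep:
                        continue
                    nt0, nt1 = frame + 3 * a, frame + 3 * b
                    if strand == "+":
                        iv = (chrom, nt0, nt1, "+")
                    else:
                        iv = (chrom, G - nt1, G - nt0, "-")
                    entries.append(
                        PeptideDbEntry(
                            peptide=pep,
                            source_class="six_frame",
                            origin=f"{chrom}|{strand}{frame + 1}",
                            genome_intervals=[iv],
                        )
                    )
    return _assign_headers(entries)


def translate_transcripts_three_frame(
    annotation: Annotation,
    genome: dict[str, str],
    min_orf_aa: int = 20,
    atg_initiated: bool = False,
) -> list[PeptideDbEntry]:
    """Stop-to-stop ORFs in the three forward frames of each transcript,
    back-mapped through the exon chain to (possibly split) genome blocks."""
    entries = []
    for tx in annotation:
        spliced = tx.spliced_sequence(genome)
        for frame in range(3):
            prot = translate_nt(spliced[frame:])
            for a, b in _orf_spans(prot, min_orf_aa):
                pep = prot[a:b]
                if atg_initiated:
                    m = pep.find("M")
                    if m < 0 or b - (a + m) < min_orf_aa:
                        continue
                    a, pep = a + m, pep[m:]
                if "X" in pep:
                    continue
                blocks = tx.transcript_to_genome(frame + 3 * a, frame + 3 * b)
                entries.append(
                    PeptideDbEntry(
                        peptide=pep,
                        source_class="three_frame",
                        origin=f"{tx.transcript_id}|{tx.biotype}|+{frame + 1}",
                        genome_intervals=[
                            (tx.chrom, s, e, tx.strand) for s, e in blocks
                        ],
                    )
                )
    return _assign_headers(entries)


# ---------------------------------------------------------------------------
# Variant peptides


def _apply_variant_to_cds(
    tx: Transcript,
    genome: dict[str, str],
    variant: tuple[str, int, str, str, str],
) -> tuple[str, str] | None:
    """Return (reference CDS, variant CDS) or None if not applicable.

    Handles SNPs and frame-preserving indels whose reference span lies
    entirely inside the CDS of a single transcript.
    """
    chrom, pos, ref, alt, _zyg = variant
    if chrom != tx.chrom or not tx.is_coding:
        return None
    if (len(ref) - len(alt)) % 3 != 0:
        return None  # frameshift: out of scope for peptide substitution
    span = tx.cds_transcript_span()
    tcoords = [tx.genome_to_transcript(pos + i) for i in range(len(ref))]
    if any(t is None for t in tcoords):
        return None
    lo, hi = min(tcoords), max(tcoords) + 1
    if not (span[0] <= lo and hi <= span[1]):
        return None
    spliced = tx.spliced_sequence(genome)
    cds = spliced[span[0] : span[1]]
    alt_tx = alt if tx.strand == "+" else revcomp(alt)
    a, b = lo - span[0], hi - span[0]
    return cds, cds[:a] + alt_tx + cds[b:]


def _protein(cds: str) -> str:
    prot = translate_nt(cds)
    stop = prot.find(STOP)
    return prot if stop < 0 else prot[:stop]


def build_variant_db(
    annotation: Annotation,
    genome: dict[str, str],
    variants: list[tuple[str, int, str, str, str]],
    params: DigestParams | None = None,
) -> list[PeptideDbEntry]:
    """Tryptic peptides altered by coding SNPs and frame-preserving indels.

    Both protein versions are digested; peptides present only in the
    variant digest and overlapping the altered residue range are emitted.
    Synonymous changes yield nothing; a stop gain yields the new C-terminal
    peptide. SNP entries carry codon-exact genome intervals (reference
    coordinates; re-translation after applying the recorded base change
    reproduces the peptide); indel entries record their origin through the
    transcript anchor instead.
    """
    p = params or DigestParams()
    entries = []
    for tx in annotation:
        if not tx.is_coding:
            continue
        span = tx.cds_transcript_span()
        for var in variants:
            applied = _apply_variant_to_cds(tx, genome, var)
            if applied is None:
                continue
            cds_ref, cds_alt = applied
            prot_ref, prot_alt = _protein(cds_ref), _protein(cds_alt)
            if prot_ref == prot_alt:
                continue  # synonymous
            # changed residue range in the variant protein
            first = next(
                i
                for i in range(min(len(prot_ref), len(prot_alt)) + 1)
                if i >= min(len(prot_ref), len(prot_alt))
                or prot_ref[i] != prot_alt[i]
            )
            tail = 0
            while (
                tail < min(len(prot_ref), len(prot_alt)) - first
                and prot_ref[len(prot_ref) - 1 - tail]
                == prot_alt[len(prot_alt) - 1 - tail]
            ):
                tail += 1
            changed_lo, changed_hi = first, len(prot_alt) - tail
            ref_peps = {pep for _, _, pep in digest(prot_ref, p)}
            is_snp = len(var[2]) == 1 and len(var[3]) == 1
            note = (
                f"{prot_ref[first]}{first + 1}"
                f"{prot_alt[first] if first < len(prot_alt) else '*'}"
                if first < len(prot_ref)
                else "ext"
            )
            for s, e, pep in digest(prot_alt, p):
                if pep in ref_peps:
                    continue
                # keep peptides touching the changed region (inclusive at the
                # edges so a truncated C-terminus still qualifies)
                if e < changed_lo or s > changed_hi:
                    continue
                intervals = []
                if is_snp and len(prot_ref) == len(prot_alt):
                    blocks = tx.transcript_to_genome(
                        span[0] + 3 * s, span[0] + 3 * e
                    )
                    intervals = [(tx.chrom, b0, b1, tx.strand) for b0, b1 in blocks]
                entries.append(
                    PeptideDbEntry(
                        peptide=pep,
                        source_class="variant",
                        origin=f"{tx.transcript_id}|cds+{3 * s}",
                        genome_intervals=intervals,
                        variant=(var[0], var[1], var[2], var[3]),
                        annotation_note=note,
                    )
                )
    return _assign_headers(entries)


# ---------------------------------------------------------------------------
# Alternate translation starts


def _n_terminal_peptides(
    protein: str, params: DigestParams
) -> list[tuple[str, int]]:
    """The N-terminal tryptic peptide, with and without the initiator Met.

    Returns (sequence, offset-from-protein-start) pairs that pass the
    length window.
    """
    out = []
    b = cleavage_boundaries(protein)
    first_end = b[1] if len(b) > 1 else len(protein)
    for off in (0, 1):  # intact and Met-excised
        pep = protein[off:first_end]
        if params.min_len <= len(pep) <= params.max_len:
            out.append((pep, off))
    return out


def build_alt_start_db(
    annotation: Annotation,
    genome: dict[str, str],
    window_codons: int = 50,
    params: DigestParams | None = None,
) -> list[PeptideDbEntry]:
    """N-terminal peptides from in-frame ATGs near annotated starts.

    Upstream ATGs are scanned outward from the start; an in-frame stop
    terminates the scan (a blocked upstream ATG cannot extend the protein).
    Downstream, every in-frame internal Met within the window yields a
    candidate shortened N-terminus. The annotated start itself is excluded.
    """
    p = params or DigestParams()
    entries = []
    for tx in annotation:
        if not tx.is_coding:
            continue
        spliced = tx.spliced_sequence(genome)
        t0, t1 = tx.cds_transcript_span()
        # upstream scan
        for k in range(1, window_codons + 1):
            s = t0 - 3 * k
            if s < 0:
                break
            codon = spliced[s : s + 3]
            if translate_nt(codon) == STOP:
                break
            if codon == "ATG":
                prot = _protein(spliced[s:t1])
                for pep, off in _n_terminal_peptides(prot, p):
                    blocks = tx.transcript_to_genome(
                        s + 3 * off, s + 3 * (off + len(pep))
                    )
                    entries.append(
                        PeptideDbEntry(
                            peptide=pep,
                            source_class="alt_start_upstream",
                            origin=f"{tx.transcript_id}|-{k}",
                            genome_intervals=[
                                (tx.chrom, b0, b1, tx.strand) for b0, b1 in blocks
                            ],
                        )
                    )
        # downstream scan
        prot = _protein(spliced[t0:t1])
        for i in range(1, min(window_codons, len(prot))):
            if prot[i] != "M":
                continue
            for pep, off in _n_terminal_peptides(prot[i:], p):
                s = t0 + 3 * (i + off)
                blocks = tx.transcript_to_genome(s, s + 3 * len(pep))
                entries.append(
                    PeptideDbEntry(
                        peptide=pep,
                        source_class="alt_start_downstream",
                        origin=f"{tx.transcript_id}|+{i + 1}",
                        genome_intervals=[
                            (tx.chrom, b0, b1, tx.strand) for b0, b1 in blocks
                        ],
                    )
                )
    return _assign_headers(entries)


# ---------------------------------------------------------------------------
# Signal-peptide cleavage


def build_signal_cleavage_db(
    proteins: dict[str, str],
    cleavage_sites: list[tuple[str, int]],
    params: DigestParams | None = None,
    annotation: Annotation | None = None,
    genome: dict[str, str] | None = None,
) -> list[PeptideDbEntry]:
    """Mature-protein N-terminal peptides after signal-peptide cleavage.

    ``cleavage_sites`` gives (protein_id, c) with ``c`` the 1-based last
    residue of the signal peptide; the emitted semi-tryptic peptide runs
    from residue c+1 to the next tryptic cleavage point. When the protein
    id matches a coding transcript in ``annotation``, genome intervals are
    attached.
    """
    p = params or DigestParams()
    entries = []
    tx_by_id = (
        {t.transcript_id: t for t in annotation} if annotation is not None else {}
    )
    for pid, c in cleavage_sites:
        if pid not in proteins:
            raise KeyError(f"unknown protein id {pid!r}")
        prot = proteins[pid]
        if not 0 < c < len(prot):
            raise ValueError(
                f"cleavage site {c} outside protein {pid} (len {len(prot)})"
            )
        mature = prot[c:]
        b = cleavage_boundaries(mature)
        pep = mature[: b[1] if len(b) > 1 else len(mature)]
        if not (p.min_len <= len(pep) <= p.max_len):
            continue
        intervals = []
        tx = tx_by_id.get(pid)
        if tx is not None and tx.is_coding and genome is not None:
            t0, _ = tx.cds_transcript_span()
            blocks = tx.transcript_to_genome(t0 + 3 * c, t0 + 3 * (c + len(pep)))
            intervals = [(tx.chrom, b0, b1, tx.strand) for b0, b1 in blocks]
        entries.append(
            PeptideDbEntry(
                peptide=pep,
                source_class="signal_cleavage",
                origin=f"{pid}|cleave@{c}",
                genome_intervals=intervals,
            )
        )
    return _assign_headers(entries)


# ---------------------------------------------------------------------------
# Splice-junction peptides


def build_junction_db(
    annotation: Annotation, genome: dict[str, str], flank_aa: int = 10
) -> list[PeptideDbEntry]:
    """Peptides spanning exon-exon junctions.

    For coding transcripts the window around each junction is translated in
    the annotated CDS frame; non-coding transcripts get all three frames.
    Peptides are retained only if they cross the junction by at least one
    residue on each side; a stop inside the window truncates to the
    junction-containing fragment.
    """
    entries = []
    for tx in annotation:
        if len(tx.exons) < 2:
            continue
        spliced = tx.spliced_sequence(genome)
        # transcript-order cumulative exon ends = junction coordinates
        lens = [len(e) for e in (tx.exons if tx.strand == "+" else tx.exons[::-1])]
        j = 0
        for li in lens[:-1]:
            j += li
            if tx.is_coding:
                t0, t1 = tx.cds_transcript_span()
                if not (t0 < j < t1):
                    continue  # junction outside the CDS: no annotated frame
                raw = max(t0, j - 3 * flank_aa)
                s = t0 + 3 * (-(-(raw - t0) // 3))  # next codon boundary
                windows = [(s, t1)]
            else:
                windows = [
                    (max(0, j - 3 * flank_aa) + f, len(spliced)) for f in range(3)
                ]
            for s, limit in windows:
                e = min(j + 3 * flank_aa, limit)
                e = s + ((e - s) // 3) * 3
                if e <= s:
                    continue
                prot = translate_nt(spliced[s:e])
                # keep the stop-free fragment containing the junction
                aa_j = (j - s) / 3.0  # junction in residue coordinates
                frag_lo = 0
                frag = None
                for seg in prot.split(STOP):
                    frag_hi = frag_lo + len(seg)
                    if frag_lo + 1 <= aa_j <= frag_hi - 1 and len(seg) >= 2:
                        frag = (frag_lo, frag_hi, seg)
                        break
                    frag_lo = frag_hi + 1
                if frag is None:
                    continue
                a, bnd, pep = frag
                nt_s, nt_e = s + 3 * a, s + 3 * bnd
                blocks = tx.transcript_to_genome(nt_s, nt_e)
                if len(blocks) < 2:
                    continue
                entries.append(
                    PeptideDbEntry(
                        peptide=pep,
                        source_class="junction",
                        origin=f"{tx.transcript_id}|junction@{j}",
                        genome_intervals=[
                            (tx.chrom, b0, b1, tx.strand) for b0, b1 in blocks
                        ],
                    )
                )
    return _assign_headers(entries)


# ---------------------------------------------------------------------------
# Round trip, headers, FASTA, mapping


def translate_intervals(
    genome: dict[str, str],
    intervals: list[tuple[str, int, int, str]],
    variant: tuple[str, int, str, str] | None = None,
) -> str:
    """Strand-aware translation of genome blocks (the round-trip check).

    ``variant`` applies a recorded single-base change before translating,
    which is how variant-peptide entries are verified against the reference
    they differ from.
    """
    if not intervals:
        return ""
    strand = intervals[0][3]
    parts = []
    for chrom, s, e, _ in sorted(intervals, key=lambda iv: iv[1]):
        seg = genome[chrom][s:e]
        if variant is not None and variant[0] == chrom and s <= variant[1] < e:
            off = variant[1] - s
            seg = seg[:off] + variant[3] + seg[off + len(variant[2]) :]
        parts.append(seg)
    nt = "".join(parts)
    if strand == "-":
        nt = revcomp(nt)
    return translate_nt(nt)


def _assign_headers(entries: list[PeptideDbEntry]) -> list[PeptideDbEntry]:
    seen: dict[str, int] = {}
    for e in entries:
        ivs = ";".join(f"{c}:{s}-{t}{st}" for c, s, t, st in e.genome_intervals)
        base = f"{e.source_class}|{e.origin}|{ivs}"
        k = seen.get(base, 0)
        seen[base] = k + 1
        e.header = base if k == 0 else f"{base}|{k}"
    return entries


def write_database_fasta(entries: list[PeptideDbEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.header}\n{e.peptide}\n")


@dataclass
class PeptideMapping:
    entry: PeptideDbEntry
    genome_intervals: list[tuple[str, int, int, str]]
    category: str


def _slice_intervals(
    entry: PeptideDbEntry, aa_off: int, aa_len: int
) -> list[tuple[str, int, int, str]]:
    """Genome blocks of a peptide substring of an ORF entry."""
    strand = entry.genome_intervals[0][3]
    blocks = sorted(entry.genome_intervals, key=lambda iv: iv[1])
    reading = blocks if strand == "+" else blocks[::-1]
    want_lo, want_hi = 3 * aa_off, 3 * (aa_off + aa_len)
    out = []
    off = 0
    for chrom, s, e, st in reading:
        n = e - s
        lo, hi = max(want_lo, off), min(want_hi, off + n)
        if lo < hi:
            if st == "+":
                out.append((chrom, s + (lo - off), s + (hi - off), st))
            else:
                out.append((chrom, e - (hi - off), e - (lo - off), st))
        off += n
    return sorted(out, key=lambda iv: iv[1])


def map_peptide_to_genome(
    peptide: str,
    databases: list[PeptideDbEntry],
    annotation: Annotation,
) -> list[PeptideMapping]:
    """Locate an identified peptide in the built databases.

    ORF-class entries (six_frame / three_frame) match by substring with the
    coordinates narrowed to the matched stretch; peptide-class entries match
    exactly. The category interprets the hit against the annotation: a
    genome-frame hit inside an annotated CDS is ``known_exon``, inside a
    5'UTR ``utr_orf``, on a pseudogene transcript ``pseudogene``, anywhere
    else (intron, intergenic, unannotated-coding) ``novel_exon``. An empty
    list means not found.
    """
    from .rdd import build_region_index  # shared interval index

    trees = build_region_index(annotation)
    biotype_of = {t.transcript_id: t.biotype for t in annotation}

    def region_labels(intervals) -> set[str]:
        labels: set[str] = set()
        for chrom, s, e, _ in intervals:
            if chrom in trees:
                for hit in trees[chrom].overlap(s, e):
                    labels.add(hit.data)
        return labels

    out = []
    for entry in databases:
        if entry.source_class in ("six_frame", "three_frame"):
            pos = entry.peptide.find(peptide)
            if pos < 0:
                continue
            intervals = _slice_intervals(entry, pos, len(peptide))
        else:
            if entry.peptide != peptide:
                continue
            intervals = entry.genome_intervals
        labels = region_labels(intervals)
        if entry.source_class.startswith("alt_start"):
            category = "alt_start"
        elif entry.source_class == "signal_cleavage":
            category = "signal_cleavage"
        elif entry.source_class == "three_frame" and (
            biotype_of.get(entry.origin.split("|")[0]) == "pseudogene"
        ):
            category = "pseudogene"
        elif "CDS" in labels:
            category = "known_exon"
        elif "5'UTR" in labels:
            category = "utr_orf"
        else:
            category = "novel_exon"
        out.append(
            PeptideMapping(entry=entry, genome_intervals=intervals, category=category)
        )
    return out
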