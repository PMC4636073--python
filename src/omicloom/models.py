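"""Core containers: gene models and coordinate arithmetic.

All coordinates are 0-based, half-open on the forward genome strand.
Transcript coordinates run 5'->3' along the transcript (i.e. they follow
the transcript strand), which is what splicing-aware translation and
peptide back-mapping need. Emitted GTF/VCF use the 1-based conventions of
those formats; conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Transcript:
    """A single transcript model with exon chain and optional CDS.

    ``cds_start``/``cds_end`` delimit the coding span in genome coordinates
    (half-open, forward strand) and must fall inside exons. Non-coding
    transcripts (biotype ``noncoding`` or ``pseudogene``) leave them None.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]  # sorted by genomic start, non-overlapping
    biotype: str = "protein_coding"  # protein_coding | noncoding | pseudogene
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: exons out of order or overlapping"
                )

    # -- basic geometry ----------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    # -- coordinate mapping ------------------------------------------------

    def genome_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to transcript coordinate, None if intronic."""
        off = 0
        if self.strand == "+":
            for e in self.exons:
                if e.contains(pos):
                    return off + (pos - e.start)
                off += len(e)
        else:
            for e in reversed(self.exons):
                if e.contains(pos):
                    return off + (e.end - 1 - pos)
                off += len(e)
        return None

    def transcript_to_genome(self, tstart: int, tend: int) -> list[tuple[int, int]]:
        """Map a transcript-coordinate interval to genome intervals.

        Returns a list of forward-strand half-open (start, end) blocks in
        genomic order; an interval spanning a splice junction yields one
        block per exon touched.
        """
        if not 0 <= tstart <= tend <= self.spliced_length:
            raise ValueError(
                f"transcript interval [{tstart},{tend}) outside "
                f"{self.transcript_id} (len {self.spliced_length})"
            )
        blocks: list[tuple[int, int]] = []
        off = 0
        exon_iter = self.exons if self.strand == "+" else list(reversed(self.exons))
        for e in exon_iter:
            lo = max(tstart, off)
            hi = min(tend, off + len(e))
            if lo < hi:
                if self.strand == "+":
                    blocks.append((e.start + (lo - off), e.start + (hi - off)))
                else:
                    blocks.append((e.end - (hi - off), e.end - (lo - off)))
            off += len(e)
        blocks.sort()
        return blocks

    # -- sequence ----------------------------------------------------------

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Transcript sequence 5'->3' (reverse-complemented on '-' strand)."""
        seq = "".join(genome[self.chrom][e.start : e.end] for e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    # -- CDS / UTR geometry --------------------------------------------------

    def cds_transcript_span(self) -> tuple[int, int] | None:
        """CDS as a half-open interval in transcript coordinates."""
        if not self.is_coding:
            return None
        if self.strand == "+":
            t0 = self.genome_to_transcript(self.cds_start)
            t1 = self.genome_to_transcript(self.cds_end - 1)
        else:
            t0 = self.genome_to_transcript(self.cds_end - 1)
            t1 = self.genome_to_transcript(self.cds_start)
        if t0 is None or t1 is None:
            raise ValueError(f"{self.transcript_id}: CDS bounds not exonic")
        return t0, t1 + 1

    def cds_sequence(self, genome: dict[str, str]) -> str:
        span = self.cds_transcript_span()
        if span is None:
            return ""
        return self.spliced_sequence(genome)[span[0] : span[1]]

    def _exonic_sub(self, lo: int, hi: int) -> list[Interval]:
        out = []
        for e in self.exons:
            s, t = max(e.start, lo), min(e.end, hi)
            if s < t:
                out.append(Interval(s, t))
        return out

    def cds_intervals(self) -> list[Interval]:
        if not self.is_coding:
            return []
        return self._exonic_sub(self.cds_start, self.cds_end)

    def utr5_intervals(self) -> list[Interval]:
        if not self.is_coding:
            return []
        if self.strand == "+":
            return self._exonic_sub(self.start, self.cds_start)
        return self._exonic_sub(self.cds_end, self.end)

    def utr3_intervals(self) -> list[Interval]:
        if not self.is_coding:
            return []
        if self.strand == "+":
            return self._exonic_sub(self.cds_end, self.end)
        return self._exonic_sub(self.start, self.cds_start)


@dataclass
class Annotation:
    """A set of transcripts with gene-level and positional lookups."""

    transcripts: list[Transcript] = field(default_factory=list)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene_id, None)
        return list(seen)

    def by_transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def by_gene(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.gene_id == gene_id]
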