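"""Truth-tagged synthetic multi-omics data.

Generates a small diploid-style genome with gene models, planted germline
variants, canonical A-to-G editing sites, duplicated-locus alignment-artifact
decoys, allele-specific genes, a bimodal transcript-abundance mixture, and a
multi-sample methylation/expression panel with planted inversely coupled
CpG-gene pairs. Every planted feature is recorded in a :class:`TruthTable`
so downstream callers can be scored for recall and precision.

The simulation product is pileup-style per-site allele counts rather than
reads: the analyses downstream operate on aligned base calls, and counts
keep the data desk-scale. Cross-mapping artifact signal is injected directly
as mismatch counts at the positions where duplicated segments differ.

Determinism: every generator draws from a stream keyed by (seed, stage), so
identical seed + config gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import Annotation, Interval, Transcript, revcomp

BASES = np.array(list("ACGT"))
BASE_IDX = {b: i for i, b in enumerate("ACGT")}
STOPS = {"TAA", "TAG", "TGA"}


class ConfigError(ValueError):
    """A SimulationConfig field violates its constraints."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Rates and fractions are probabilities in [0, 1]; ``mixture_params`` is
    (mu_noise, sigma_noise, mu_expressed, sigma_expressed, weight_noise) on
    the log10-FPKM scale.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 2
    snp_rate: float = 0.002
    het_fraction: float = 1.0
    n_indels: int = 10
    n_edit_sites: int = 50
    edit_rate: float = 0.3
    rna_depth: float = 50.0
    n_duplicated_segments: int = 5
    duplication_length: int = 300
    n_genes: int = 50
    noncoding_fraction: float = 0.12
    pseudogene_fraction: float = 0.06
    ase_fraction: float = 0.10
    ase_major_fraction: float = 0.95
    mixture_params: tuple[float, float, float, float, float] = (
        -1.0,
        0.4,
        1.5,
        0.5,
        0.4,
    )
    fpkm_ibaq_spearman: float = 0.35
    n_expression_transcripts: int = 2000
    n_mirnas: int = 300
    n_panel_samples: int = 100
    n_panel_probes: int = 500
    n_inverse_cpgs: int = 50
    inverse_rho: float = 0.85
    seq_error_rate: float = 0.002
    cross_map_fraction: float = 0.4
    n_intronic_orfs: int = 1
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "snp_rate": self.snp_rate,
            "het_fraction": self.het_fraction,
            "edit_rate": self.edit_rate,
            "ase_fraction": self.ase_fraction,
            "ase_major_fraction": self.ase_major_fraction,
            "noncoding_fraction": self.noncoding_fraction,
            "pseudogene_fraction": self.pseudogene_fraction,
            "seq_error_rate": self.seq_error_rate,
            "cross_map_fraction": self.cross_map_fraction,
            "inverse_rho": self.inverse_rho,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "n_indels": self.n_indels,
            "n_edit_sites": self.n_edit_sites,
            "n_duplicated_segments": self.n_duplicated_segments,
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "n_panel_samples": self.n_panel_samples,
            "n_panel_probes": self.n_panel_probes,
            "n_inverse_cpgs": self.n_inverse_cpgs,
            "n_intronic_orfs": self.n_intronic_orfs,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.genome_length < 1000:
            raise ConfigError(
                f"genome_length must be >= 1000, got {self.genome_length}"
            )
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.rna_depth <= 0:
            raise ConfigError(f"rna_depth must be > 0, got {self.rna_depth}")
        mu_n, sig_n, mu_e, sig_e, w = self.mixture_params
        if sig_n <= 0 or sig_e <= 0:
            raise ConfigError("mixture_params sigmas must be > 0")
        if not 0.0 <= w <= 1.0:
            raise ConfigError(f"mixture weight_noise must be in [0,1], got {w}")
        if self.n_inverse_cpgs > self.n_panel_probes:
            raise ConfigError(
                "n_inverse_cpgs exceeds n_panel_probes "
                f"({self.n_inverse_cpgs} > {self.n_panel_probes})"
            )
        if not -1.0 < self.fpkm_ibaq_spearman < 1.0:
            raise ConfigError("fpkm_ibaq_spearman must be in (-1, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixture_params"] = list(self.mixture_params)
        return d


@dataclass
class TruthTable:
    """Ground truth of every planted feature, in 0-based genome coordinates."""

    planted_variants: list[tuple[str, int, str, str, str]] = field(
        default_factory=list
    )  # (chrom, pos0, ref, alt, zygosity) — SNPs and indels
    planted_edits: list[tuple[str, int, str, float]] = field(
        default_factory=list
    )  # (chrom, pos0, transcript strand, edit_rate)
    planted_artifacts: list[tuple[str, int, int, str, int, int]] = field(
        default_factory=list
    )  # paired near-identical segments (chromA, a0, a1, chromB, b0, b1)
    planted_artifact_sites: list[tuple[str, int]] = field(default_factory=list)
    planted_ase_genes: dict[str, tuple[float, bool]] = field(
        default_factory=dict
    )  # gene_id -> (major_allele_fraction, major_is_ref)
    planted_intronic_orfs: list[tuple[str, int, int]] = field(default_factory=list)
    expressed_transcripts: set[str] = field(default_factory=set)
    inverse_cpgs: set[tuple[str, str]] = field(default_factory=set)
    differential_probes: list[tuple[str, str, float, float]] = field(
        default_factory=list
    )  # (probe_id, gene_id, delta_beta, delta_log2_expr), naive - memory

    def snp_sites(self) -> set[tuple[str, int]]:
        return {
            (c, p)
            for c, p, ref, alt, _ in self.planted_variants
            if len(ref) == 1 and len(alt) == 1
        }

    def edit_sites(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _ in self.planted_edits}


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


# ---------------------------------------------------------------------------
# Genome, annotation, truth


def _random_orf_nt(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, 3))
        if c not in STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _make_gene(
    rng: np.random.Generator,
    gene_idx: int,
    chrom: str,
    cursor: int,
    biotype: str,
) -> tuple[Transcript, int]:
    """Lay out a 3-exon gene starting at ``cursor``; returns span end."""
    exon_lens = rng.integers(150, 230, size=3)
    intron_lens = rng.integers(150, 260, size=2)
    starts = []
    pos = cursor
    for i in range(3):
        starts.append(pos)
        pos += int(exon_lens[i])
        if i < 2:
            pos += int(intron_lens[i])
    exons = [Interval(s, s + int(exon_lens[i])) for i, s in enumerate(starts)]
    strand = "+" if rng.random() < 0.5 else "-"
    gid = f"GENE{gene_idx:04d}"
    tid = f"TX{gene_idx:04d}"
    tx = Transcript(
        transcript_id=tid,
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        exons=exons,
        biotype=biotype,
    )
    if biotype == "protein_coding":
        spliced = tx.spliced_length
        utr5 = 75
        utr3 = 75
        cds_len = ((spliced - utr5 - utr3) // 3) * 3
        blocks = tx.transcript_to_genome(utr5, utr5 + cds_len)
        tx.cds_start = blocks[0][0]
        tx.cds_end = blocks[-1][1]
    return tx, pos


def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], Annotation, TruthTable]:
    """Build reference chromosomes, gene models, and the truth table.

    Genes occupy the first ~70% of each chromosome; duplicated decoy
    segments (pseudogene-like cross-mapping traps, pairwise >=98% identical)
    occupy the tail. Coding CDSs are rewritten as clean open reading frames
    so that protein-level stages have translatable input.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    truth = TruthTable()

    chrom_len = config.genome_length // config.n_chromosomes
    chroms = {
        f"chr{i + 1}": rng.integers(0, 4, size=chrom_len) for i in range(
            config.n_chromosomes
        )
    }

    # --- genes, round-robin over chromosomes -------------------------------
    n_nc = round(config.noncoding_fraction * config.n_genes)
    n_ps = round(config.pseudogene_fraction * config.n_genes)
    biotypes = (
        ["protein_coding"] * (config.n_genes - n_nc - n_ps)
        + ["noncoding"] * n_nc
        + ["pseudogene"] * n_ps
    )
    rng.shuffle(biotypes)

    transcripts: list[Transcript] = []
    cursors = {c: 150 for c in chroms}
    gene_limit = {c: int(0.70 * chrom_len) for c in chroms}
    chrom_names = list(chroms)
    ci = 0
    for gi in range(config.n_genes):
        placed = False
        for _ in range(config.n_chromosomes):
            chrom = chrom_names[ci % config.n_chromosomes]
            ci += 1
            tx, end = _make_gene(rng, gi, chrom, cursors[chrom], biotypes[gi])
            if end < gene_limit[chrom]:
                transcripts.append(tx)
                cursors[chrom] = end + int(rng.integers(80, 180))
                placed = True
                break
        if not placed:
            raise ConfigError(
                "genome_length too small for n_genes with this gene geometry"
            )
    annotation = Annotation(transcripts)

    # rewrite coding CDSs as clean ORFs (strand-aware)
    for tx in transcripts:
        if not tx.is_coding:
            continue
        span = tx.cds_transcript_span()
        n_codons = (span[1] - span[0]) // 3
        orf = _random_orf_nt(rng, n_codons)
        blocks = tx.transcript_to_genome(span[0], span[1])
        genomic_nt = orf if tx.strand == "+" else revcomp(orf)
        off = 0
        for s, e in blocks:
            chroms[tx.chrom][s:e] = [BASE_IDX[b] for b in genomic_nt[off : off + e - s]]
            off += e - s

    # --- planted intronic ORFs (novel-exon decoys) --------------------------
    planted = 0
    for tx in transcripts:
        if planted >= config.n_intronic_orfs:
            break
        if not tx.is_coding or len(tx.exons) < 2:
            continue
        intron = Interval(tx.exons[0].end, tx.exons[1].start)
        n_codons = 27
        payload = "TAA" + _random_orf_nt(rng, n_codons) + "TAA"
        if len(intron) < len(payload) + 20:
            continue
        at = intron.start + 10
        chroms[tx.chrom][at : at + len(payload)] = [BASE_IDX[b] for b in payload]
        # the ORF proper: between the leading stop and the ORF's own stop
        truth.planted_intronic_orfs.append(
            (tx.chrom, at + 3, at + len(payload) - 6)
        )
        planted += 1

    # --- duplicated segments (alignment-artifact decoys) ---------------------
    dup_len = config.duplication_length
    for k in range(config.n_duplicated_segments):
        chrom = chrom_names[k % config.n_chromosomes]
        lo = int(0.72 * chrom_len)
        # sequential non-overlapping placement in the chromosome tail
        per_chrom = sum(
            1
            for j in range(config.n_duplicated_segments)
            if chrom_names[j % config.n_chromosomes] == chrom
        )
        slot = k // config.n_chromosomes
        pitch = (chrom_len - lo - 100) // max(per_chrom, 1)
        if pitch < 2 * dup_len + 60:
            raise ConfigError(
                "genome_length too small for duplicated segments of this length"
            )
        a0 = lo + slot * pitch
        b0 = a0 + dup_len + 40
        seg = chroms[chrom][a0 : a0 + dup_len].copy()
        # copy with 1-2 interior mismatches (>=98% identity)
        n_mm = int(rng.integers(1, 3))
        mm_pos = rng.choice(np.arange(30, dup_len - 30), size=n_mm, replace=False)
        for p in sorted(mm_pos):
            seg[p] = (seg[p] + int(rng.integers(1, 4))) % 4
        chroms[chrom][b0 : b0 + dup_len] = seg
        truth.planted_artifacts.append(
            (chrom, a0, a0 + dup_len, chrom, b0, b0 + dup_len)
        )
        for p in sorted(mm_pos):
            truth.planted_artifact_sites.append((chrom, a0 + int(p)))
            truth.planted_artifact_sites.append((chrom, b0 + int(p)))

    genome = {c: "".join(BASES[arr]) for c, arr in chroms.items()}

    # --- variants -----------------------------------------------------------
    rng_v = _rng(config.seed, 2)
    dup_mask: set[tuple[str, int]] = set()
    for c, a0, a1, _, b0, b1 in truth.planted_artifacts:
        dup_mask.update((c, p) for p in range(a0 - 60, b1 + 60))
    used: set[tuple[str, int]] = set(dup_mask)

    n_snps = round(config.snp_rate * config.genome_length)
    snp_sites: list[tuple[str, int]] = []
    # guarantee >=2 exonic het-SNP-capable sites per gene for ASE calling
    for tx in transcripts:
        exonic = [
            (tx.chrom, p) for e in tx.exons for p in range(e.start, e.end)
        ]
        picks = rng_v.choice(len(exonic), size=min(2, len(exonic)), replace=False)
        for i in picks:
            if exonic[i] not in used:
                snp_sites.append(exonic[i])
                used.add(exonic[i])
    while len(snp_sites) < n_snps:
        chrom = chrom_names[int(rng_v.integers(config.n_chromosomes))]
        pos = int(rng_v.integers(chrom_len))
        if (chrom, pos) not in used:
            snp_sites.append((chrom, pos))
            used.add((chrom, pos))
    snp_sites = snp_sites[:n_snps]

    n_het = round(config.het_fraction * len(snp_sites))
    order = rng_v.permutation(len(snp_sites))
    for rank, idx in enumerate(order):
        chrom, pos = snp_sites[idx]
        ref = genome[chrom][pos]
        alt = str(rng_v.choice([b for b in "ACGT" if b != ref]))
        zyg = "het" if rank < n_het else "hom"
        truth.planted_variants.append((chrom, pos, ref, alt, zyg))

    # indels: half inside CDS (frame-preserving, length 3), half intergenic
    coding = [t for t in transcripts if t.is_coding]
    for k in range(config.n_indels):
        if coding and k % 2 == 0:
            tx = coding[int(rng_v.integers(len(coding)))]
            iv = tx.cds_intervals()[0]
            pos = int(rng_v.integers(iv.start + 3, iv.end - 6))
            chrom = tx.chrom
        else:
            chrom = chrom_names[int(rng_v.integers(config.n_chromosomes))]
            pos = int(rng_v.integers(chrom_len - 10))
        if any((chrom, pos + d) in used for d in range(-6, 7)):
            continue
        ref_nt = genome[chrom][pos : pos + 4]
        if rng_v.random() < 0.5:  # deletion of 3 bases
            truth.planted_variants.append(
                (chrom, pos, ref_nt, ref_nt[0], "het")
            )
        else:  # insertion of 3 bases
            ins = "".join(rng_v.choice(BASES, 3))
            truth.planted_variants.append(
                (chrom, pos, ref_nt[0], ref_nt[0] + ins, "het")
            )
        used.update((chrom, pos + d) for d in range(-6, 7))

    # --- edit sites: transcript-strand adenosines in unique exonic sequence --
    rng_e = _rng(config.seed, 3)
    want = "A"
    candidates_by_gene: list[tuple[str, int, str]] = []
    for tx in transcripts:
        target = want if tx.strand == "+" else "T"
        for e in tx.exons:
            for p in range(e.start, e.end):
                if genome[tx.chrom][p] == target and (tx.chrom, p) not in used:
                    candidates_by_gene.append((tx.chrom, p, tx.strand))
    if len(candidates_by_gene) < config.n_edit_sites:
        raise ConfigError("not enough exonic adenosines for n_edit_sites")
    picks = rng_e.choice(
        len(candidates_by_gene), size=config.n_edit_sites, replace=False
    )
    for i in sorted(picks):
        chrom, pos, strand = candidates_by_gene[i]
        truth.planted_edits.append((chrom, pos, strand, config.edit_rate))
        used.add((chrom, pos))

    # --- ASE genes ----------------------------------------------------------
    rng_a = _rng(config.seed, 4)
    n_ase = round(config.ase_fraction * config.n_genes)
    gene_ids = [t.gene_id for t in transcripts]
    ase_picks = rng_a.choice(len(gene_ids), size=n_ase, replace=False)
    for j, i in enumerate(sorted(ase_picks)):
        frac = 1.0 if j % 3 == 0 else config.ase_major_fraction  # some monoallelic
        truth.planted_ase_genes[gene_ids[i]] = (frac, bool(rng_a.random() < 0.5))

    return genome, annotation, truth


# ---------------------------------------------------------------------------
# RNA pileup


def simulate_rna_pileup(
    genome: dict[str, str],
    annotation: Annotation,
    truth: TruthTable,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-site A/C/G/T read counts over transcribed sites and decoy loci.

    Depth is Poisson(rna_depth) per site. Het SNPs receive both alleles
    (50/50, or the planted major fraction in ASE genes); edit sites receive
    the edited base at ``edit_rate``; positions where duplicated segments
    differ receive extra cross-mapped reads carrying the paralog's base.
    A uniform base-miscall error is applied to every read.
    """
    config.validate()
    rng = _rng(config.seed, 5)
    err = config.seq_error_rate

    variant_at = {(c, p): (ref, alt, zyg) for c, p, ref, alt, zyg in truth.planted_variants
                  if len(ref) == 1 and len(alt) == 1}
    edit_at = {(c, p): (strand, rate) for c, p, strand, rate in truth.planted_edits}
    paralog_base: dict[tuple[str, int], str] = {}
    for chrom, a0, a1, _, b0, b1 in truth.planted_artifacts:
        for c, p in truth.planted_artifact_sites:
            if c == chrom and a0 <= p < a1:
                paralog_base[(c, p)] = genome[c][b0 + (p - a0)]
            elif c == chrom and b0 <= p < b1:
                paralog_base[(c, p)] = genome[c][a0 + (p - b0)]

    gene_of: dict[tuple[str, int], Transcript] = {}
    sites: dict[tuple[str, int], str] = {}
    for tx in annotation:
        for e in tx.exons:
            for p in range(e.start, e.end):
                sites[(tx.chrom, p)] = tx.strand
                gene_of[(tx.chrom, p)] = tx
    for chrom, a0, a1, c2, b0, b1 in truth.planted_artifacts:
        for p in range(a0, a1):
            sites.setdefault((chrom, p), ".")
        for p in range(b0, b1):
            sites.setdefault((c2, p), ".")

    for (c, p) in variant_at:
        if (c, p) in sites and genome[c][p] != variant_at[(c, p)][0]:
            raise ValueError(
                f"truth/reference mismatch at {c}:{p}: "
                f"reference {genome[c][p]} vs truth {variant_at[(c, p)][0]}"
            )

    rows = []
    for (chrom, pos) in sorted(sites):
        strand = sites[(chrom, pos)]
        ref = genome[chrom][pos]
        depth = int(rng.poisson(config.rna_depth))
        probs = np.zeros(4)
        key = (chrom, pos)
        if key in variant_at:
            _, alt, zyg = variant_at[key]
            if zyg == "hom":
                probs[BASE_IDX[alt]] = 1.0
            else:
                tx = gene_of.get(key)
                frac_ref = 0.5
                if tx is not None and tx.gene_id in truth.planted_ase_genes:
                    f, major_is_ref = truth.planted_ase_genes[tx.gene_id]
                    frac_ref = f if major_is_ref else 1.0 - f
                probs[BASE_IDX[ref]] = frac_ref
                probs[BASE_IDX[alt]] = 1.0 - frac_ref
        elif key in edit_at:
            strand_e, rate = edit_at[key]
            edited = "G" if strand_e == "+" else "C"  # A->G on transcript strand
            probs[BASE_IDX[ref]] = 1.0 - rate
            probs[BASE_IDX[edited]] = rate
        else:
            probs[BASE_IDX[ref]] = 1.0
        # uniform miscall: each read flips to one of the 3 other bases at err
        p_obs = probs * (1.0 - err) + (1.0 - probs) * (err / 3.0)
        counts = rng.multinomial(depth, p_obs / p_obs.sum())
        if key in paralog_base:
            n_cross = int(rng.binomial(depth, config.cross_map_fraction))
            counts[BASE_IDX[paralog_base[key]]] += n_cross
        rows.append(
            {
                "chrom": chrom,
                "pos0": pos,
                "ref": ref,
                "strand": strand,
                "A": int(counts[0]),
                "C": int(counts[1]),
                "G": int(counts[2]),
                "T": int(counts[3]),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "strand", "A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Expression, protein and miRNA abundance


def _rank_normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = pd.Series(x).rank(method="average").to_numpy()
    return norm.ppf((ranks - 0.5) / len(x))


def spearman_latent_r(rho: float) -> float:
    """Latent Gaussian correlation giving Spearman rho under a normal copula."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def simulate_expression_tables(
    annotation: Annotation,
    config: SimulationConfig,
    truth: TruthTable | None = None,
    n_transcripts: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """FPKM, iBAQ, and miRNA abundance tables.

    log10-FPKM is drawn from the two-component mixture in
    ``config.mixture_params``. iBAQ is coupled to FPKM through a Gaussian
    copula on FPKM's normal scores so that the realized Spearman correlation
    matches ``config.fpkm_ibaq_spearman``. miRNA abundance is heavy-tailed
    (log-normal across two decades).
    """
    config.validate()
    mu_n, sig_n, mu_e, sig_e, w_noise = config.mixture_params
    rng = _rng(config.seed, 6)

    ids = [t.transcript_id for t in annotation]
    genes = {t.transcript_id: t.gene_id for t in annotation}
    if n_transcripts is None:
        n_transcripts = config.n_expression_transcripts
    if n_transcripts > len(ids):
        # pad with unannotated transcripts so the mixture has realistic n
        ids = ids + [f"TXX{i:05d}" for i in range(n_transcripts - len(ids))]
    from_noise = rng.random(len(ids)) < w_noise
    z = rng.normal(size=len(ids))
    log_fpkm = np.where(from_noise, mu_n + sig_n * z, mu_e + sig_e * z)
    fpkm = pd.DataFrame(
        {
            "transcript_id": ids,
            "gene_id": [genes.get(t, t) for t in ids],
            "fpkm": 10.0 ** log_fpkm,
        }
    )
    if truth is not None:
        truth.expressed_transcripts = set(np.array(ids)[~from_noise])

    r = spearman_latent_r(config.fpkm_ibaq_spearman)
    scores = _rank_normal_scores(np.asarray(fpkm["fpkm"]))
    z_i = r * scores + np.sqrt(1.0 - r * r) * rng.normal(size=len(ids))
    ibaq = pd.DataFrame(
        {
            "gene_id": fpkm["gene_id"],
            "ibaq": 10.0 ** (6.0 + z_i),
        }
    ).groupby("gene_id", as_index=False, sort=False).first()

    mirna_log = rng.normal(1.2, 1.1, size=config.n_mirnas)
    mirna = pd.DataFrame(
        {
            "mirna_id": [f"mir-{i:04d}" for i in range(config.n_mirnas)],
            "fpkm": 10.0 ** mirna_log,
            "reads": np.maximum(
                1, (10.0 ** mirna_log / 5.0).round().astype(int)
            ),
        }
    )
    return fpkm, ibaq, mirna


# ---------------------------------------------------------------------------
# Methylation panel


def simulate_methylation_panel(
    annotation: Annotation,
    config: SimulationConfig,
    truth: TruthTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-sample CpG beta and expression panel with planted inverse pairs.

    Returns (probe table, expression table). The probe table has one row per
    probe with chrom/pos/gene assignment, one beta column per panel sample,
    and two cell-state columns (``naive``, ``memory``) carrying planted
    differential probes. The expression table mirrors the sample columns on
    the gene level (log2 units).

    Planted inverse probes track their gene's expression through a negative
    Gaussian-copula coupling of strength ``inverse_rho``; all other probes
    are independent of expression.
    """
    config.validate()
    if config.n_panel_samples < 10:
        raise ConfigError(
            f"n_panel_samples must be >= 10, got {config.n_panel_samples}"
        )
    rng = _rng(config.seed, 7)
    n_s = config.n_panel_samples
    samples = [f"S{i + 1:03d}" for i in range(n_s)]

    txs = list(annotation)
    gene_expr: dict[str, np.ndarray] = {}
    probe_rows = []
    expr_rows = []
    n_probes = config.n_panel_probes
    inverse_idx = set(range(config.n_inverse_cpgs))  # deterministic: first block
    r = config.inverse_rho

    for i in range(n_probes):
        tx = txs[i % len(txs)]
        gid = tx.gene_id
        if gid not in gene_expr:
            base = rng.normal(5.0, 0.3)
            gene_expr[gid] = base + rng.normal(0.0, 1.0, size=n_s)
        expr = gene_expr[gid]
        if i in inverse_idx:
            z_e = (expr - expr.mean()) / expr.std()
            latent = -r * z_e + np.sqrt(1 - r * r) * rng.normal(size=n_s)
        else:
            latent = rng.normal(size=n_s)
        betas = norm.cdf(latent + rng.normal(0.0, 0.2))
        # probe position: inside the promoter window, strand-adjusted
        off = int(rng.integers(1, 1400))
        pos = tx.tss - off if tx.strand == "+" else tx.tss + off
        pos = max(0, pos)
        pid = f"cg{i:06d}"
        row = {
            "probe_id": pid,
            "chrom": tx.chrom,
            "pos": pos,
            "gene_id": gid,
        }
        row.update({s: float(b) for s, b in zip(samples, betas)})
        probe_rows.append(row)
        if truth is not None and i in inverse_idx:
            truth.inverse_cpgs.add((pid, gid))

    for gid, expr in gene_expr.items():
        row = {"gene_id": gid}
        row.update({s: float(e) for s, e in zip(samples, expr)})
        expr_rows.append(row)

    probes = pd.DataFrame(probe_rows)
    exprs = pd.DataFrame(expr_rows)

    # two cell-state columns with planted differential probes
    rng_d = _rng(config.seed, 8)
    base_beta = rng_d.uniform(0.05, 0.95, size=n_probes)
    naive_beta = base_beta.copy()
    memory_beta = base_beta.copy()
    naive_expr = {g: float(rng_d.normal(5, 1)) for g in exprs["gene_id"]}
    memory_expr = dict(naive_expr)
    n_diff = min(30, n_probes)
    diff_idx = rng_d.choice(n_probes, size=n_diff, replace=False)
    for j, i in enumerate(sorted(diff_idx)):
        gid = probes.loc[i, "gene_id"]
        sign = 1 if j % 2 == 0 else -1  # hyper- vs hypo-methylated in naive
        naive_beta[i] = float(np.clip(base_beta[i] + 0.35 * sign, 0.01, 0.99))
        memory_beta[i] = float(np.clip(base_beta[i] - 0.05 * sign, 0.01, 0.99))
        d_expr = -sign * 2.0  # inverse coupling for planted probes
        naive_expr[gid] = memory_expr[gid] + d_expr
        if truth is not None:
            truth.differential_probes.append(
                (
                    str(probes.loc[i, "probe_id"]),
                    str(gid),
                    float(naive_beta[i] - memory_beta[i]),
                    d_expr,
                )
            )
    probes["naive"] = np.clip(naive_beta, 0.0, 1.0)
    probes["memory"] = np.clip(memory_beta, 0.0, 1.0)
    exprs["naive"] = [naive_expr[g] for g in exprs["gene_id"]]
    exprs["memory"] = [memory_expr[g] for g in exprs["gene_id"]]
    return probes, exprs
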