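# Methods

This note documents the models and procedures the package implements, the
parameter defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions that a user
comparing results against their own pipeline will want to know.

## RNA-DNA difference (RDD) detection

An RDD is a transcriptome site whose RNA base calls differ from the genome
reference. Under physiological conditions most true RDDs are A-to-I
deamination events read out as A→G (and C-to-U as C→T); observed G→A and
T→C changes are the same events on transcripts whose strand the RNA-Seq
protocol did not resolve. The pipeline operates on pileup-style per-site
allele counts (chrom, 0-based position, reference base, strand if known,
A/C/G/T counts) rather than reads: every decision the cascade makes needs
only aligned base calls, and counts keep the data desk-scale.

**Candidate calling.** A non-reference base becomes a candidate when it has
at least `min_alt_reads` (3) supporting reads, site depth is at least
`min_depth` (10), and the alternative fraction is at least `min_fraction`
(0.10). These cutoffs are configurable; the defaults follow common RDD
practice and are chosen so that, at the simulated depths, every planted
edit is recoverable while sequencing error (0.2% per base) essentially
never is: at depth 50 the probability of three 0.2%-error reads of the
same wrong base at one site is ~2×10⁻⁵.

**Germline subtraction.** Any candidate whose position matches a DNA
variant is reclassified `genomic_variant`. Matching is by position only
(not allele) — the conservative choice, since a mispositioned variant call
should still disqualify the site. Candidates within 5 bp of an indel are
also reclassified: indel realignment wobble is the classic source of false
RDDs.

**Alignment-artifact filtering.** Reads from a near-identical paralog or
pseudogene that cross-map onto a locus produce systematic mismatches.
The classical check re-aligns the RDD-bearing sequence with an external
aligner; here the same decision — *does this RDD-bearing window align
elsewhere?* — is made by an internal uniqueness search: the 51-bp window
around the candidate, with the RDD base substituted in, is scanned against
both strands of the whole genome, and a second locus matching within 2
mismatches flags the candidate `alignment_artifact`. The window scan is a
vectorized Hamming profile; the test suite holds it to exact agreement
with an independent brute-force all-positions scan. Window half-width
(25 bp, minimum 15) and mismatch budget are configurable. Survivors of
both filters are `pass`, so the three terminal statuses partition the
candidate set — an invariant the pipeline asserts.

**Validation reconciliation.** When targeted DNA+RNA re-sequencing of
candidate sites is available, each site is adjudicated: a DNA alternative
allele fraction ≥ 0.1 means the site was a germline variant missed by the
original genome sequencing; otherwise ≥ 3 RNA reads on the edited base
validate the RDD, and 0–2 reads mean the original call was likely a
sequencing error. The 0.1 DNA threshold separates heterozygotes (~0.5)
from error at targeted depths.

**miRNA seed impact.** The seed of a miRNA is nucleotides 2–8; a
reverse-complement 7-mer match in a 3'UTR is the primary targeting
determinant. For each passing 3'UTR edit, seed matches covering the edited
position are enumerated in the edited and unedited UTR (transcript
orientation); matches lost are destroyed sites, matches gained are created
sites, reported per (site, miRNA) pair.

## Allele-specific expression

Heterozygous SNPs make a gene's two alleles countable. Per site with at
least 10 reads over the two alleles: monoallelic if the minor allele has
zero reads; allele-specific if major/minor ≥ 5 (inclusive — the rule is
"at least 5-fold"); biallelic otherwise. The 10-read floor is applied per
site, the stricter of the two readings of "at least 10 reads were mapped".
Gene-level: monoallelic if all informative sites are monoallelic (with a
`min_mono_reads` = 10 total-read guard so zero-coverage genes are not
called), biallelic as soon as any informative site is biallelic,
allele-specific otherwise, uninformative without informative sites. No
phasing is attempted; since each site's phase is free in unphased data,
some haplotype always carries every site's major allele, so
`direction_consistent` is reported true with `phased=False` — with phased
input the cross-site check would become substantive.

## Expression-noise threshold

Bulk log-abundance is bimodal: a noise peak of fragmentary transcripts and
an expressed peak. A two-component Gaussian mixture is fitted by EM to
log10 of the strictly positive FPKM values (zeros cannot be logged; base
10 is a convention of this package). The fit is delegated to
scikit-learn's `GaussianMixture` (k-means initialization, tolerance 1e-6,
500 iterations, seeded); components are relabeled left/right by mean so
the result is invariant to initialization order. The cutoff is
`mu_left + 2·sigma_left` on the log scale, exclusive: expressed requires
FPKM strictly greater. A fit whose component means are closer than one
pooled standard deviation is flagged non-bimodal and refuses to look like
a meaningful threshold. On the reference synthetic mixture
(0.5·N(−1, 0.4²) + 0.5·N(1.5, 0.5²), n = 10,000) the median cutoff
recovery error across 20 seeds is well under 0.1 log units.

The miRNA copies-per-cell conversion is a plain division by an externally
calibrated FPKM-per-copy constant (~73 in the deeply sequenced T-cell
library that motivates the default used in the documentation examples);
the calibration method is upstream of this package, so the constant is an
input, never hard-coded.

## Proteogenomic databases

All databases are built from the standard codon table. ORFs for the
six-frame (genome) and three-frame (transcript) databases are
stop-to-stop, not ATG-initiated — the sensitivity-maximizing convention
for novel-peptide discovery; an ATG-initiated mode is a flag. Defaults:
minimum ORF 20 aa; tryptic digestion cleaves C-terminal to K/R except
before P, ≤ 2 missed cleavages, peptide length 7–45 aa. Entries carry
0-based half-open genome blocks with strand whose strand-aware translation
reproduces the peptide exactly — the round-trip invariant the tests apply
to every emitted entry. Variant peptides are the set difference between
the digests of the reference and variant protein, restricted to peptides
touching the changed residue range (so a synonymous change yields nothing
and a stop gain yields the new C-terminus). SNP entries keep codon-exact
intervals and round-trip with the recorded base change applied;
frame-preserving indel entries are anchored to their transcript instead of
carrying genome intervals, since no reference interval translates to an
insertion-bearing peptide. Frameshifts are out of scope. Alternate-start
scanning covers 50 codons on either side of the annotated start (in-frame
upstream ATGs are abandoned at the first in-frame stop), emitting each
N-terminal tryptic peptide with and without the initiator Met, matching
how N-terminal acetylation evidence is searched. Junction windows span 10
aa on each side; for coding transcripts only junctions inside the CDS are
emitted (the annotated frame is defined there), non-coding transcripts get
all three frames. Peptide-to-genome mapping categorizes hits against the
annotation: CDS overlap → `known_exon`, 5'UTR → `utr_orf`, pseudogene
transcript → `pseudogene`, anything else (introns, intergenic, non-coding
exons) → `novel_exon`.

## Methylation integration

Beta values are classified with strict inequalities — hypo < 0.33,
hyper > 0.66, boundary values intermediate — so the three classes
partition any input. Promoters are [TSS−1500, TSS) on the transcribed
strand. Naive/memory differential calls use effect-size floors
|Δbeta| ≥ 0.2 and |Δlog2 expression| ≥ 1.0 (standard floors for 450K-style
arrays and RNA-Seq; pseudocount 0.1 for ratios of linear expression);
opposite signs above both floors are `inverse`, same signs `concordant`,
anything smaller `unchanged`. Informer selection computes per probe-gene
pair the sample-wise Spearman correlation across a panel of at least 30
samples and retains pairs with rho ≤ −0.3 at Benjamini-Hochberg q ≤ 0.05.
The −0.3/0.05 pair is this package's choice of "inverse correlation";
both knobs are exposed. Spearman uses average ranks throughout
(scipy); the suite pins it to rank-then-Pearson agreement at 1e-10.

## The synthetic generator

`synth.generate_genome` builds 2 chromosomes totalling 100 kb by default:
50 three-exon genes (~12% non-coding, ~6% pseudogene) in the head of each
chromosome, with coding CDSs rewritten as clean ORFs so protein stages have
translatable input; 5 pairs of 300-bp duplicated segments (≥ 98% identity)
in the tails as cross-mapping decoys; 200 SNPs (2 guaranteed exonic per
gene so every gene is ASE-assessable), 10 indels, and 50 A-to-G edit sites
on transcript-strand adenosines in unique sequence. Pileups draw depth
from Poisson(50) per transcribed site, apply a uniform 0.2% base-miscall
error, give het sites 50/50 alleles (or the planted major fraction, 0.95,
in the 10% of genes planted allele-specific, a third of them fully
monoallelic), give edit sites the edited base at rate 0.3, and inject
cross-mapped counts (40% of depth) at the positions where duplicated
segments differ. Abundance tables draw log10-FPKM from the mixture
(−1, 0.4, 1.5, 0.5, weight 0.4) over 2,000 transcripts and couple iBAQ to
FPKM through a Gaussian copula on FPKM's normal scores, so the realized
Spearman correlation hits the 0.35 target within ±0.05 at n = 5,000. The
methylation panel has 100 samples and 500 promoter probes, the first 50
coupled to their gene's expression with latent correlation −0.85 (realized
Spearman ≈ −0.8), plus naive/memory columns with 30 planted differential
probes (Δbeta ±0.4 inversely coupled to a 2-unit log2 expression change).
Every stream is keyed by (seed, stage), so identical seed and config give
byte-identical outputs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (mapping quality, strand
bias, soft-clipping), position-dependent error profiles, editing
hyper-clusters and ADAR sequence context, mapping bias at het sites,
transcript-abundance-dependent coverage (pileup depth is independent of
the FPKM table), probe cross-reactivity and array normalization effects,
and correlated gene expression across panel samples. Thresholds tuned
here demonstrate internal correctness of the decision rules, not
field-calibrated operating points.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally; VCF and GTF are read and
written 1-based. Mixture fitting refuses < 100 positive values, all-equal
values, and non-finite input. Candidate calling rejects non-ACGT reference
bases; flank windows truncated at contig edges are logged, zero-depth
validation records are excluded with a warning, constant-beta probes are
skipped in informer selection. Ties in region assignment resolve by
precedence (CDS > UTR > noncoding; promoter > 3'UTR > gene body) and then
lexicographically by gene id, so outputs are order-stable.

## Problem sizes

The default study conditions (100 kb genome, 50 genes, depth 50, 100-sample
panel) were chosen so that every statistical contract is measurable with
comfortable margins — planted-edit recall and artifact flagging are exact,
mixture recovery and copula targets have ±0.05-type tolerances at
n = 5,000–10,000 — while a full simulate-and-analyse run completes in a
few seconds. Scaling the config up changes nothing structural: all
operations are linear in genome size except the artifact uniqueness scan,
which is O(genome × window) per surviving candidate.
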