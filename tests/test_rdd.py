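"""RNA-DNA-difference cascade: calling, filters, classification, seed impact."""

import numpy as np
import pandas as pd
import pytest

from omicloom import rdd, synth
from omicloom.models import Annotation, Interval, Transcript, revcomp


def make_pileup(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "strand", "A", "C", "G", "T"])


class TestCallCandidates:
    GENOME = {"chr1": "ACGT" * 30}

    def test_threshold_arithmetic(self):
        pu = make_pileup([("chr1", 0, "A", "+", 70, 0, 30, 0)])
        (c,) = rdd.call_candidates(pu, self.GENOME)
        assert (c.rdd_base, c.rdd_fraction, c.depth) == ("G", 0.3, 100)
        assert c.filter_status == "candidate"

    def test_below_min_alt_reads_not_called(self):
        pu = make_pileup([("chr1", 0, "A", "+", 98, 0, 2, 0)])
        assert rdd.call_candidates(pu, self.GENOME) == []

    def test_below_depth_or_fraction_not_called(self):
        pu = make_pileup(
            [
                ("chr1", 0, "A", "+", 5, 0, 4, 0),  # depth 9 < 10
                ("chr1", 4, "A", "+", 95, 0, 5, 0),  # fraction 0.05 < 0.10
            ]
        )
        assert rdd.call_candidates(pu, self.GENOME) == []

    def test_invalid_ref_base_rejected(self):
        pu = make_pileup([("chr1", 0, "N", "+", 10, 0, 10, 0)])
        with pytest.raises(ValueError, match="ref base"):
            rdd.call_candidates(pu, self.GENOME)

    def test_all_planted_edits_recovered_as_candidates(
        self, dataset, pileup, config
    ):
        genome, _, truth = dataset
        cands = rdd.call_candidates(pileup, genome)
        called = {(c.chrom, c.pos) for c in cands}
        idx = pileup.set_index(["chrom", "pos0"])
        for chrom, pos, strand, _ in truth.planted_edits:
            row = idx.loc[(chrom, pos)]
            alt = row["G" if strand == "+" else "C"]
            depth = row[["A", "C", "G", "T"]].sum()
            if alt >= 3 and depth >= 10:
                assert (chrom, pos) in called


class TestVariantFilter:
    def test_planted_snps_flagged_edits_retained(self, dataset, pileup):
        genome, _, truth = dataset
        cands = rdd.call_candidates(pileup, genome)
        rdd.filter_genomic_variants(cands, truth.planted_variants, genome)
        by_site = {(c.chrom, c.pos): c for c in cands}
        for site in truth.snp_sites():
            if site in by_site:
                assert by_site[site].filter_status == "genomic_variant"
        for site in truth.edit_sites():
            if site in by_site:
                assert by_site[site].filter_status == "candidate"

    def test_contig_mismatch_reported(self):
        cands = [
            rdd.RddCandidate("chrX", 5, "A", "G", "+", 50, 20, 0.4)
        ]
        with pytest.raises(ValueError, match="chrX"):
            rdd.filter_genomic_variants(
                cands, [("chr1", 5, "A", "T", "het")], {"chr1": "A" * 10}
            )

    def test_indel_proximal_candidates_masked(self):
        genome = {"chr1": "A" * 100}
        variants = [("chr1", 50, "AAAA", "A", "het")]
        cands = [
            rdd.RddCandidate("chr1", 48, "A", "G", "+", 50, 20, 0.4),
            rdd.RddCandidate("chr1", 70, "A", "G", "+", 50, 20, 0.4),
        ]
        rdd.filter_genomic_variants(cands, variants, genome)
        assert cands[0].filter_status == "genomic_variant"
        assert cands[1].filter_status == "candidate"


def brute_force_second_locus(genome, chrom, pos, base, flank, max_mm):
    """Independent all-positions Hamming scan over both strands."""
    seq = genome[chrom]
    lo, hi = max(pos - flank, 0), min(pos + flank + 1, len(seq))
    window = seq[lo:pos] + base + seq[pos + 1 : hi]
    L = len(window)
    for name, s in genome.items():
        for strand_seq, is_rc in ((s, False), (revcomp(s), True)):
            G = len(strand_seq)
            for i in range(G - L + 1):
                mm = 0
                for a, b in zip(strand_seq[i : i + L], window):
                    if a != b:
                        mm += 1
                        if mm > max_mm:
                            break
                if mm > max_mm:
                    continue
                if name == chrom:
                    f_lo, f_hi = (G - i - L, G - i) if is_rc else (i, i + L)
                    if f_lo < lo + L and lo < f_hi:
                        continue  # own locus
                return True
    return False


class TestArtifactFilter:
    def test_flank_too_small_rejected(self):
        with pytest.raises(ValueError, match="flank"):
            rdd.filter_alignment_artifacts([], {"chr1": "A" * 100}, flank=10)

    def test_duplicated_locus_flagged_unique_passes(self, dataset, pileup):
        genome, _, truth = dataset
        cands = rdd.call_candidates(pileup, genome)
        rdd.filter_genomic_variants(cands, truth.planted_variants, genome)
        rdd.filter_alignment_artifacts(cands, genome)
        artifact_sites = set(truth.planted_artifact_sites)
        for c in cands:
            if (c.chrom, c.pos) in artifact_sites:
                assert c.filter_status == "alignment_artifact"
            elif (c.chrom, c.pos) in truth.edit_sites():
                assert c.filter_status == "pass"

    def test_matches_brute_force_oracle_on_small_genome(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, 3000))
        # plant a duplicate of a 120 bp segment with one mismatch
        seg = list(seq[500:620])
        seg[60] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seg[60]]
        genome = {"chr1": seq[:2000] + "".join(seg) + seq[2000:]}
        probe_positions = [560, 2060, 100, 900, 1500, 2500]
        for pos in probe_positions:
            ref = genome["chr1"][pos]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            expected = brute_force_second_locus(genome, "chr1", pos, alt, 25, 2)
            got = rdd.has_second_locus(genome, "chr1", pos, alt, 25, 2)
            assert got == expected, f"disagreement at {pos}"


class TestSubstitutionClass:
    @pytest.mark.parametrize(
        "ref,alt,strand,expected",
        [
            ("A", "G", None, "canonical"),
            ("C", "T", None, "canonical"),
            ("G", "A", None, "canonical_strand_flipped"),
            ("T", "C", None, "canonical_strand_flipped"),
            ("A", "C", None, "noncanonical"),
            ("T", "C", "-", "canonical"),  # minus-strand transcript: A-to-G
            ("G", "A", "-", "canonical"),  # minus-strand transcript: C-to-T
            ("A", "G", "-", "canonical_strand_flipped"),
        ],
    )
    def test_classification_table(self, ref, alt, strand, expected):
        assert rdd.classify_substitution(ref, alt, strand) == expected

    def test_same_base_rejected(self):
        with pytest.raises(ValueError):
            rdd.classify_substitution("A", "A")

    def test_matrix_sums_match_candidate_counts(self, dataset, pileup):
        genome, _, truth = dataset
        cands = rdd.call_candidates(pileup, genome)
        mat = rdd.substitution_matrix(cands)
        assert mat.to_numpy().sum() == len(cands)
        for base in "ACGT":
            assert mat.loc[base].sum() == sum(
                1 for c in cands if c.ref_base == base
            )
        assert all(mat.loc[b, b] == 0 for b in "ACGT")


class TestRegionAnnotation:
    @pytest.fixture
    def annotation(self):
        coding = Transcript(
            "t1", "gA", "chr1", "+", [Interval(100, 400)],
            cds_start=150, cds_end=300,
        )
        nc = Transcript(
            "t2", "gB", "chr1", "+", [Interval(250, 500)], biotype="noncoding"
        )
        return Annotation([coding, nc])

    def cand(self, pos):
        return rdd.RddCandidate("chr1", pos, "A", "G", "+", 50, 20, 0.4)

    @pytest.mark.parametrize(
        "pos,region",
        [
            (200, "CDS"),
            (120, "5'UTR"),
            (350, "3'UTR"),
            (450, "noncoding"),
            (50, "intergenic"),
            (280, "CDS"),  # CDS of gA beats noncoding exon of gB
        ],
    )
    def test_assignment_with_precedence(self, annotation, pos, region):
        (c,) = rdd.annotate_region([self.cand(pos)], annotation)
        assert c.region == region


class TestValidation:
    def test_verdict_rules(self):
        recs = [
            rdd.ValidationRecord("chr1", 1, 0, 40, 40, 20),  # DNA all-alt
            rdd.ValidationRecord("chr1", 2, 60, 0, 79, 1),  # 1 RNA read
            rdd.ValidationRecord("chr1", 3, 60, 0, 65, 15),  # solid RNA support
            rdd.ValidationRecord("chr1", 4, 0, 0, 10, 10),  # zero DNA depth
        ]
        kept, summary = rdd.reconcile_validation(recs)
        assert [r.verdict for r in kept] == [
            "snp_missed_by_wgs",
            "unsupported",
            "validated_rdd",
        ]
        assert summary == {
            "snp_missed_by_wgs": 1,
            "validated_rdd": 1,
            "unsupported": 1,
        }

    def test_unsupported_boundary_at_two_reads(self):
        kept, _ = rdd.reconcile_validation(
            [rdd.ValidationRecord("chr1", 1, 60, 0, 78, 2)]
        )
        assert kept[0].verdict == "unsupported"


def brute_force_seed_matches(utr, seed7, off):
    """All 7-mer windows equal to the target that cover the site."""
    return {
        p
        for p in range(len(utr) - 6)
        if utr[p : p + 7] == seed7 and p <= off <= p + 6
    }


class TestMirnaSeedImpact:
    def build(self, utr3_seq):
        # plus-strand single-exon gene: 9 nt 5'UTR, 30 nt CDS, then the UTR
        pre = "ATGAAAGGG" * 1 + "ATG" + "GCT" * 9
        genome = {"chr1": "TTTT" + pre + utr3_seq + "TTTT"}
        start = 4
        tx = Transcript(
            "t1", "g1", "chr1", "+",
            [Interval(start, start + len(pre) + len(utr3_seq))],
            cds_start=start + 9, cds_end=start + len(pre),
        )
        return genome, Annotation([tx]), start + len(pre)

    def passing(self, pos, ref, alt):
        return rdd.RddCandidate(
            "chr1", pos, ref, alt, "+", 50, 20, 0.4, filter_status="pass"
        )

    def test_edit_destroys_existing_seed_match(self):
        mirna = "UGAGGUAGUAGGUUGUAUAGUU"  # seed GAGGUAG -> site CTACCTC
        site = "CTACCTC"
        utr = "AAAA" + site + "AAAAGGGG"
        genome, ann, utr_start = self.build(utr)
        utrs = rdd.build_utr3_sequences(ann, genome)
        # edit the A inside the site (utr offset 4+3=7 is C... pick offset 5: T->C)
        pos = utr_start + 5
        ref = genome["chr1"][pos]
        c = self.passing(pos, ref, "G" if ref != "G" else "C")
        df = rdd.mirna_seed_impact([c], {"let7": mirna}, utrs)
        # oracle: compare brute-force scans of both versions
        edited = utr[:5] + c.rdd_base + utr[6:]
        target = rdd.revcomp(rdd.seed_sequence(mirna))
        before = brute_force_seed_matches(utr, target, 5)
        after = brute_force_seed_matches(edited, target, 5)
        assert before and not after
        assert list(df["impact"]) == ["destroys_seed_match"]

    def test_edit_creates_new_seed_match(self):
        mirna = "UGAGGUAGUAGGUUGUAUAGUU"
        broken = "CTACATC"  # one base off the true site CTACCTC
        utr = "AAAA" + broken + "AAAAGGGG"
        genome, ann, utr_start = self.build(utr)
        utrs = rdd.build_utr3_sequences(ann, genome)
        pos = utr_start + 8  # the A that should be C
        c = self.passing(pos, genome["chr1"][pos], "C")
        df = rdd.mirna_seed_impact([c], {"let7": mirna}, utrs)
        assert list(df["impact"]) == ["creates_seed_match"]
        assert df.attrs["summary"] == {"n_destroyed": 0, "n_created": 1}

    def test_edit_outside_any_match_is_silent(self):
        mirna = "UGAGGUAGUAGGUUGUAUAGUU"
        utr = "AAAAAAAAAAAAAAAAGGGG"
        genome, ann, utr_start = self.build(utr)
        utrs = rdd.build_utr3_sequences(ann, genome)
        c = self.passing(utr_start + 2, "A", "G")
        df = rdd.mirna_seed_impact([c], {"let7": mirna}, utrs)
        assert df.empty

    def test_site_outside_provided_utrs_rejected(self):
        genome, ann, _ = self.build("AAAATTTTCCCCGGGG")
        utrs = rdd.build_utr3_sequences(ann, genome)
        c = self.passing(0, "T", "C")
        with pytest.raises(ValueError, match="not inside"):
            rdd.mirna_seed_impact([c], {"m": "UUUUUUUUUU"}, utrs)


class TestCascadeInvariants:
    def test_partition_and_no_vcf_pass(self, dataset, pileup):
        genome, annotation, truth = dataset
        cands, summary = rdd.run_rdd_pipeline(
            pileup, genome, truth.planted_variants, annotation
        )
        assert summary.partition_holds()
        statuses = {c.filter_status for c in cands}
        assert statuses <= {"genomic_variant", "alignment_artifact", "pass"}
        passing = {(c.chrom, c.pos) for c in cands if c.filter_status == "pass"}
        assert not passing & {(c, p) for c, p, *_ in truth.planted_variants}
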