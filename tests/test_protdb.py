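"""Proteogenomic databases: translation identities, digestion, round trips."""

import numpy as np
import pytest

from omicloom import protdb
from omicloom.models import Annotation, Interval, Transcript, revcomp
from omicloom.protdb import DigestParams


def random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(np.array(list("ACGT")), n))


def oracle_digest(seq, missed=2, min_len=7, max_len=45):
    """Independent quadratic enumeration: every substring, validity-checked."""
    def is_boundary(i):
        return i == 0 or i == len(seq) or (seq[i - 1] in "KR" and seq[i] != "P")

    out = set()
    for i in range(len(seq)):
        for j in range(i + 1, len(seq) + 1):
            if not (is_boundary(i) and is_boundary(j)):
                continue
            internal = sum(
                1 for k in range(i + 1, j) if seq[k - 1] in "KR" and seq[k] != "P"
            )
            if internal <= missed and min_len <= j - i <= max_len:
                out.add((i, j, seq[i:j]))
    return out


class TestDigestion:
    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            prot = "".join(rng.choice(aas, int(rng.integers(30, 120))))
            got = set(protdb.digest(prot))
            assert got == oracle_digest(prot), prot

    def test_no_cleavage_before_proline(self):
        peps = {p for _, _, p in protdb.digest("AAAAKPAAAAKAAAA", DigestParams(0))}
        assert peps == {"AAAAKPAAAAK"}  # KP bond uncut; len-4 tail filtered


class TestSixFrame:
    def test_codon_table_example(self):
        entries = protdb.translate_six_frame({"s": "ATGGCCTAA"}, min_orf_aa=2)
        fwd = [e for e in entries if e.genome_intervals[0][3] == "+"]
        assert any(e.peptide == "MA" for e in fwd)

    def test_six_equals_three_plus_three_revcomp(self):
        seq = random_seq(7, 2000)
        six = protdb.translate_six_frame({"c": seq}, min_orf_aa=10)
        # single-exon "transcripts" covering both strands
        fwd = Transcript("f", "f", "c", "+", [Interval(0, 2000)], biotype="noncoding")
        rev = Transcript("r", "r", "c", "-", [Interval(0, 2000)], biotype="noncoding")
        three = protdb.translate_transcripts_three_frame(
            Annotation([fwd, rev]), {"c": seq}, min_orf_aa=10
        )

        def key(e):
            return (e.peptide, tuple(sorted(e.genome_intervals)))

        assert {key(e) for e in six} == {key(e) for e in three}

    def test_orfs_agree_with_independent_single_frame_scan(self):
        seq = random_seq(11, 1000)
        six = protdb.translate_six_frame({"c": seq}, min_orf_aa=5)
        # brute-force scanner: walk codons of frame +2, split at stops
        frame = 1
        codon_map = {"TAA": "*", "TAG": "*", "TGA": "*"}
        from Bio.Seq import Seq

        prot = "".join(
            codon_map.get(seq[i : i + 3], str(Seq(seq[i : i + 3]).translate()))
            for i in range(frame, len(seq) - 2, 3)
        )
        expected = {p for p in prot.split("*") if len(p) >= 5}
        got = {
            e.peptide
            for e in six
            if e.origin == "c|+2"
        }
        assert got == expected

    def test_round_trip_on_synthetic_genome(self, dataset):
        genome, _, _ = dataset
        for e in protdb.translate_six_frame(genome):
            assert protdb.translate_intervals(genome, e.genome_intervals) == e.peptide

    def test_headers_unique(self, dataset):
        genome, _, _ = dataset
        entries = protdb.translate_six_frame(genome)
        headers = [e.header for e in entries]
        assert len(headers) == len(set(headers))


class TestThreeFrame:
    def test_spliced_orf_round_trips_through_split_intervals(self, dataset):
        genome, annotation, _ = dataset
        entries = protdb.translate_transcripts_three_frame(annotation, genome)
        split = [e for e in entries if len(e.genome_intervals) >= 2]
        assert split, "expected ORFs spanning splice junctions"
        for e in entries:
            assert protdb.translate_intervals(genome, e.genome_intervals) == e.peptide

    def test_pseudogene_origin_recorded(self, dataset):
        genome, annotation, _ = dataset
        entries = protdb.translate_transcripts_three_frame(annotation, genome)
        pseudo = [e for e in entries if "pseudogene" in e.origin]
        assert pseudo
        assert all(e.source_class == "three_frame" for e in pseudo)


class TestVariantDb:
    def build_tx(self, cds_nt):
        genome = {"c": "TT" + cds_nt + "TT"}
        tx = Transcript(
            "t", "g", "c", "+", [Interval(2, 2 + len(cds_nt))],
            cds_start=2, cds_end=2 + len(cds_nt),
        )
        return genome, Annotation([tx])

    def test_missense_and_lost_cleavage_site(self):
        # protein M A A A K E E E E E E R ...; K->E removes a cleavage site
        cds = "ATG" + "GCT" * 4 + "AAA" + "GAA" * 7 + "CGT" + "TTT" * 6 + "TAA"
        genome, ann = self.build_tx(cds)
        prot_ref = protdb._protein(cds)
        k_pos = prot_ref.index("K")
        # AAA -> GAA at the K codon: K->E
        gpos = 2 + 3 * k_pos
        variants = [("c", gpos, "A", "G", "het")]
        entries = protdb.build_variant_db(ann, genome, variants, DigestParams(2))
        peps = {e.peptide for e in entries}
        assert peps  # the substitution is non-synonymous
        ref_peps = {p for _, _, p in protdb.digest(prot_ref, DigestParams(2))}
        assert not peps & ref_peps
        # the destroyed cleavage produces a peptide spanning the old K site
        assert any("E" * 7 in p for p in peps)
        # oracle: digest both protein versions and diff
        prot_alt = protdb._protein(cds[: 3 * k_pos] + "GAA" + cds[3 * k_pos + 3 :])
        alt_peps = {p for _, _, p in protdb.digest(prot_alt, DigestParams(2))}
        assert peps <= alt_peps - ref_peps

    def test_synonymous_variant_emits_nothing(self):
        cds = "ATG" + "AAA" + "GCT" * 10 + "TAA"
        genome, ann = self.build_tx(cds)
        # GCT -> GCC: both alanine
        entries = protdb.build_variant_db(
            ann, genome, [("c", 2 + 8, "T", "C", "het")], DigestParams(2)
        )
        assert entries == []

    def test_stop_gain_truncates(self):
        cds = "ATG" + "GCT" * 6 + "AAA" + "GCT" * 6 + "TGG" + "GCT" * 3 + "TAA"
        genome, ann = self.build_tx(cds)
        w_codon = 3 * (1 + 6 + 1 + 6)
        # TGG -> TGA: stop gain
        entries = protdb.build_variant_db(
            ann, genome, [("c", 2 + w_codon + 2, "G", "A", "het")], DigestParams(2)
        )
        prot_alt = protdb._protein(
            cds[: w_codon + 2] + "A" + cds[w_codon + 3 :]
        )
        assert any(prot_alt.endswith(e.peptide) for e in entries)

    def test_snp_entries_round_trip_with_variant_applied(self, dataset):
        genome, annotation, truth = dataset
        entries = protdb.build_variant_db(
            annotation, genome, truth.planted_variants
        )
        checked = 0
        for e in entries:
            if not e.genome_intervals:
                continue
            t = protdb.translate_intervals(genome, e.genome_intervals, e.variant)
            assert t == e.peptide, e.header
            checked += 1
        assert checked > 0


class TestAltStart:
    def make(self):
        # 5'UTR with an upstream in-frame ATG, CDS with a downstream Met
        utr5 = "GGG" + "ATG" + "GAAGAA"  # upstream ATG 4 codons before start
        cds = (
            "ATG" + "GCT" * 10 + "AAA"
            + "ATG" + "GAT" * 8 + "AAA" + "GCT" * 5 + "TAA"
        )
        genome = {"c": utr5 + cds + "AAAA"}
        tx = Transcript(
            "t", "g", "c", "+", [Interval(0, len(utr5) + len(cds))],
            cds_start=len(utr5), cds_end=len(utr5) + len(cds),
        )
        return genome, Annotation([tx])

    def test_upstream_and_downstream_entries(self):
        genome, ann = self.make()
        entries = protdb.build_alt_start_db(ann, genome, 50, DigestParams(2))
        up = [e for e in entries if e.source_class == "alt_start_upstream"]
        down = [e for e in entries if e.source_class == "alt_start_downstream"]
        assert up and down
        # downstream Met at protein position 12 (0-based) -> peptide starts M or D
        assert any(e.peptide.startswith("MD") for e in down)
        assert any(e.peptide.startswith("DD") for e in down)  # Met-excised
        for e in entries:
            assert protdb.translate_intervals(genome, e.genome_intervals) == e.peptide

    def test_upstream_atg_behind_stop_excluded(self):
        utr5 = "ATG" + "TAA" + "GAAGAAGAA"  # ATG blocked by in-frame stop
        cds = "ATG" + "GCTAAAGCTGCTGCTGCTAAA" + "TAA"
        genome = {"c": utr5 + cds}
        tx = Transcript(
            "t", "g", "c", "+", [Interval(0, len(utr5) + len(cds))],
            cds_start=len(utr5), cds_end=len(utr5) + len(cds),
        )
        entries = protdb.build_alt_start_db(
            Annotation([tx]), genome, 50, DigestParams(2)
        )
        assert not [e for e in entries if e.source_class == "alt_start_upstream"]

    def test_annotated_start_itself_excluded(self):
        genome, ann = self.make()
        entries = protdb.build_alt_start_db(ann, genome, 50, DigestParams(2))
        tx = ann.transcripts[0]
        prot = protdb._protein(tx.cds_sequence(genome))
        b = protdb.cleavage_boundaries(prot)
        annotated_n_term = prot[: b[1]]
        assert annotated_n_term not in {e.peptide for e in entries}


class TestSignalCleavage:
    def test_hand_enumerated_toy_table(self):
        proteins = {
            # cleave after 22; next boundary after K at 35 (1-based)
            "p1": "M" + "A" * 21 + "WWWWWWWWWWWWK" + "LLLL",
            # cleavage followed immediately by R: 1-residue peptide dropped
            "p2": "M" + "A" * 21 + "R" + "GGGGGGGG",
            "p3": "M" + "A" * 19 + "DDDDDDDDDDKPDDDDK" + "EE",
        }
        sites = [("p1", 22), ("p2", 22), ("p3", 20)]
        entries = protdb.build_signal_cleavage_db(
            proteins, sites, DigestParams(2, min_len=5, max_len=45)
        )
        peps = {e.origin.split("|")[0]: e.peptide for e in entries}
        assert peps["p1"] == "WWWWWWWWWWWWK"
        assert "p2" not in peps  # single-R peptide below min_len
        assert peps["p3"] == "DDDDDDDDDDKPDDDDK"  # KP bond not cleaved

    def test_site_beyond_protein_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            protdb.build_signal_cleavage_db({"p": "MAAA"}, [("p", 10)])


class TestJunctions:
    def test_coding_junction_round_trip(self, dataset):
        genome, annotation, _ = dataset
        entries = protdb.build_junction_db(annotation, genome)
        assert entries
        for e in entries:
            assert len(e.genome_intervals) >= 2  # crosses the junction
            assert protdb.translate_intervals(genome, e.genome_intervals) == e.peptide

    def test_noncoding_transcript_gets_three_frames(self, dataset):
        genome, annotation, _ = dataset
        nc = [t for t in annotation if t.biotype != "protein_coding"]
        entries = protdb.build_junction_db(Annotation(nc), genome)
        by_origin = {}
        for e in entries:
            by_origin.setdefault(e.origin, []).append(e)
        # some junction yields peptides in more than one frame
        assert any(len(v) >= 2 for v in by_origin.values())


class TestPeptideMapping:
    def test_planted_intronic_orf_maps_as_novel_exon(self, dataset):
        genome, annotation, truth = dataset
        six = protdb.translate_six_frame(genome)
        chrom, s, e = truth.planted_intronic_orfs[0]
        (entry,) = [
            x for x in six if x.genome_intervals[0][:3] == (chrom, s, e)
        ]
        maps = protdb.map_peptide_to_genome(entry.peptide[2:12], six, annotation)
        assert maps and all(m.category == "novel_exon" for m in maps)
        for m in maps:
            assert all(s <= a and b <= e for _, a, b, _ in m.genome_intervals)

    def test_cds_peptide_maps_as_known_exon(self, dataset):
        genome, annotation, _ = dataset
        tx = next(t for t in annotation if t.is_coding)
        prot = protdb._protein(tx.cds_sequence(genome))
        query = prot[2:14]
        six = protdb.translate_six_frame(genome)
        maps = protdb.map_peptide_to_genome(query, six, annotation)
        assert any(m.category == "known_exon" for m in maps)

    def test_pseudogene_only_peptide(self, dataset):
        genome, annotation, _ = dataset
        three = protdb.translate_transcripts_three_frame(annotation, genome)
        pseudo_entry = next(e for e in three if "pseudogene" in e.origin)
        maps = protdb.map_peptide_to_genome(
            pseudo_entry.peptide, [pseudo_entry], annotation
        )
        assert maps[0].category == "pseudogene"

    def test_unknown_peptide_not_found(self, dataset):
        genome, annotation, _ = dataset
        assert protdb.map_peptide_to_genome("WWWWWWWWWWWW", [], annotation) == []
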