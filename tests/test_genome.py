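"""Circular-genome model and architecture statistics."""

import pytest

from mitodui.codes import DEFAULT_START_CODONS, revcomp, stop_codons
from mitodui.genome import (AnnotationError, GeneFeature, MitoGenome,
                            canonical_label, cox2_extension, find_orfs,
                            gene_overlaps, gene_table, intergenic_regions,
                            load_genome, write_fasta, write_feature_table)

from conftest import toy_genome


class TestModel:
    def test_labels_canonicalized(self):
        assert canonical_label("COI") == "cox1"
        assert canonical_label("ND4L") == "nad4L"
        assert canonical_label("tRNA-Ser1") == "trnS1"
        assert canonical_label("trnl2") == "trnL2"
        assert canonical_label("12S rRNA") == "rrnS"
        assert canonical_label("F-orf") == "FORF"

    def test_duplicate_labels_rejected(self):
        with pytest.raises(AnnotationError, match="duplicate"):
            toy_genome(100, [GeneFeature("COI", "PCG", 0, 30, 1),
                             GeneFeature("cox1", "PCG", 40, 70, 1)])

    def test_extract_is_strand_corrected(self):
        g = toy_genome(12, seq="ATGAAATTTTAG",
                       features=[GeneFeature("x", "PCG", 0, 12, -1)])
        assert g.extract("x") == revcomp("ATGAAATTTTAG")

    def test_wrapping_feature_extraction(self):
        g = toy_genome(10, seq="AACCGGTTAC",
                       features=[GeneFeature("w", "other", 8, 4, 1,
                                             wraps_origin=True)])
        assert g.extract("w") == "ACAACC"
        assert g.feature("w").length(10) == 6


class TestIntergenic:
    def test_hand_enumerated_regions(self, two_gene_circle):
        regions = intergenic_regions(two_gene_circle)
        spans = [(r.start, r.end, r.wraps_origin, r.length) for r in regions]
        assert spans == [(40, 50, False, 10), (90, 0, True, 10)]
        assert regions[0].flank_upstream == "g1"
        assert regions[0].flank_downstream == "g2"
        assert regions[1].flank_upstream == "g2"
        assert regions[1].flank_downstream == "g1"

    def test_fully_tiled_circle_has_no_gaps(self):
        g = toy_genome(60, [GeneFeature("a", "PCG", 0, 30, 1),
                            GeneFeature("b", "PCG", 30, 60, 1)])
        assert intergenic_regions(g) == []

    def test_featureless_genome_errors(self):
        with pytest.raises(AnnotationError):
            intergenic_regions(toy_genome(50))

    def test_fixture_counts(self, f_genome, m_genome):
        f_regions = intergenic_regions(f_genome)
        m_regions = intergenic_regions(m_genome)
        assert len(f_regions) == 27
        assert len(m_regions) == 23
        largest = max(f_regions, key=lambda r: r.length)
        assert (largest.flank_upstream, largest.flank_downstream,
                largest.length) == ("nad5", "trnQ", 1049)


class TestOverlaps:
    def test_half_open_abutment_is_not_overlap(self):
        g = toy_genome(40, [GeneFeature("a", "PCG", 0, 10, 1),
                            GeneFeature("b", "PCG", 10, 20, 1)])
        assert gene_overlaps(g) == []

    def test_wrapped_overlap(self):
        g = toy_genome(100, [GeneFeature("a", "PCG", 95, 5, 1, wraps_origin=True),
                             GeneFeature("b", "PCG", 0, 3, 1)])
        (rec,) = gene_overlaps(g)
        assert rec.overlap_length == 3

    def test_fixture_overlaps(self, f_genome, m_genome):
        f_ov = {(o.gene_a, o.gene_b): o.overlap_length
                for o in gene_overlaps(f_genome)}
        m_ov = {frozenset((o.gene_a, o.gene_b)): o.overlap_length
                for o in gene_overlaps(m_genome)}
        assert len(f_ov) == 2 and set(f_ov.values()) == {1, 8}
        assert len(m_ov) == 6
        assert m_ov[frozenset(("nad6", "nad4"))] == 168
        assert m_ov[frozenset(("cox3", "cox1"))] == 8

    def test_conservation_of_genome_length(self, fixture_pair):
        # sum of feature spans - overlaps + intergenic = genome length
        for g in fixture_pair:
            spans = sum(f.length(g.length) for f in g.features)
            ov = sum(o.overlap_length for o in gene_overlaps(g))
            gaps = sum(r.length for r in intergenic_regions(g))
            assert spans - ov + gaps == g.length

    def test_rotation_invariance(self, f_genome):
        base_gaps = sorted(r.length for r in intergenic_regions(f_genome))
        base_ov = sorted(o.overlap_length for o in gene_overlaps(f_genome))
        for offset in (1, 1000, f_genome.length - 7):
            rot = f_genome.rotated(offset)
            assert sorted(r.length for r in intergenic_regions(rot)) == base_gaps
            assert sorted(o.overlap_length for o in gene_overlaps(rot)) == base_ov


class TestGeneTable:
    def test_canonical_codons(self):
        g = toy_genome(12, seq="ATGAAATTTTAA",
                       features=[GeneFeature("x", "PCG", 0, 12, 1)])
        (row,) = gene_table(g)
        assert (row.start_codon, row.stop_codon, row.start_class) == \
            ("ATG", "TAA", "conventional")

    def test_frame_error_names_gene(self):
        g = toy_genome(11, seq="ATGAAATTTTA",
                       features=[GeneFeature("x", "PCG", 0, 11, 1)])
        with pytest.raises(AnnotationError, match="x"):
            gene_table(g)

    def test_fixture_start_stop_codons(self, f_genome, m_genome):
        f_rows = {r.label: r for r in gene_table(f_genome)}
        assert (f_rows["cox1"].length, f_rows["cox1"].start_codon,
                f_rows["cox1"].stop_codon) == (1545, "TTG", "TAG")
        assert f_rows["atp8"].start_codon == "GTG"
        assert f_rows["FORF"].start_codon == "ATA"
        # 7 of the 14 coding genes start with ATG in the female genome
        assert sum(r.start_codon == "ATG" for r in f_rows.values()) == 7
        m_rows = {r.label: r for r in gene_table(m_genome)}
        assert (m_rows["cox2"].length, m_rows["nad5"].start_codon) == (1224, "GTG")
        # stop codons are all complete TAA/TAG, TAG ten times in M, seven in F
        assert all(r.stop_codon in ("TAA", "TAG") for r in m_rows.values())
        assert sum(r.stop_codon == "TAG" for r in m_rows.values()) == 10
        assert sum(r.stop_codon == "TAG" for r in f_rows.values()) == 7

    def test_reverse_complement_invariance(self, f_genome):
        flipped = MitoGenome(
            f_genome.identifier, revcomp(f_genome.sequence),
            [GeneFeature(f.label, f.kind,
                         (f_genome.length - f.end) % f_genome.length,
                         (f_genome.length - f.start) % f_genome.length or
                         f_genome.length,
                         -f.strand, f.wraps_origin)
             for f in f_genome.features if not f.wraps_origin],
            sex_type=f_genome.sex_type)
        orig = {r.label: (r.start_codon, r.stop_codon)
                for r in gene_table(f_genome)}
        new = {r.label: (r.start_codon, r.stop_codon)
               for r in gene_table(flipped)}
        assert new == {k: v for k, v in orig.items() if k in new}


def brute_force_orfs(region, min_aa, starts):
    """Independent ORF scan: every in-frame start on both strands."""
    stops = stop_codons(5)
    found = []
    n = len(region)
    for strand in (1, -1):
        seq = region if strand == 1 else revcomp(region)
        for s in range(n - 2):
            if seq[s:s + 3] not in starts:
                continue
            # preceded by an in-frame start closer to 5'? then not maximal
            maximal = True
            i = s - 3
            while i >= 0:
                if seq[i:i + 3] in stops:
                    break
                if seq[i:i + 3] in starts:
                    maximal = False
                    break
                i -= 3
            if not maximal:
                continue
            e = s
            has_stop = False
            while e + 3 <= n:
                if seq[e:e + 3] in stops:
                    has_stop = True
                    e += 3
                    break
                e += 3
            aa = (e - s) // 3 - (1 if has_stop else 0)
            if aa >= min_aa:
                found.append((strand, s if strand == 1 else n - e, aa))
    return sorted(found)


class TestOrfScan:
    def test_poly_a_has_no_orfs(self):
        assert find_orfs("A" * 120, min_aa=5) == []

    def test_planted_orf_recovered(self):
        orf = "ATG" + "GCT" * 17 + "TAG"
        region = "CCCCC" + orf + "CCCC"
        hits = find_orfs(region, min_aa=10)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.aa_length) == (5, 5 + len(orf), 1, 18)

    def test_matches_brute_force_scanner(self):
        import random
        rng = random.Random(17)
        for _ in range(25):
            region = "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 300)))
            hits = find_orfs(region, min_aa=5)
            got = sorted((h.strand, h.start, h.aa_length) for h in hits)
            assert got == brute_force_orfs(region, 5, DEFAULT_START_CODONS)

    def test_fixture_forf_found_in_intergenic_scan(self, f_genome):
        forf = f_genome.feature("FORF")
        trne, trnw = f_genome.feature("trnE"), f_genome.feature("trnW")
        region = f_genome.region_sequence(trne.end, trnw.start)
        hits = find_orfs(region, min_aa=80)
        ends = {trne.end + h.end for h in hits if h.strand == 1}
        assert forf.end in ends
        best = max(hits, key=lambda h: h.aa_length)
        assert best.aa_length >= 86


class TestCox2Extension:
    def test_fixture_values(self, f_genome, m_genome):
        bp, frac = cox2_extension(f_genome, m_genome)
        assert bp == 543
        assert frac == pytest.approx(0.797, abs=0.001)

    def test_arithmetic(self):
        f = toy_genome(300, [GeneFeature("cox2", "PCG", 0, 100, 1)])
        m = toy_genome(300, [GeneFeature("cox2", "PCG", 0, 150, 1)])
        assert cox2_extension(f, m) == (50, 0.5)
        assert cox2_extension(f, f) == (0, 0.0)

    def test_missing_gene_errors(self, f_genome):
        with pytest.raises(KeyError):
            cox2_extension(f_genome, toy_genome(50))


class TestIO:
    def test_fasta_feature_table_round_trip(self, f_genome, tmp_path):
        write_fasta(f_genome, tmp_path / "g.fasta")
        write_feature_table(f_genome, tmp_path / "g.features.tsv")
        back = load_genome(tmp_path / "g.fasta", "fasta")
        assert back.sequence == f_genome.sequence
        assert back.features == f_genome.features

    def test_fasta_without_table_is_featureless(self, tmp_path):
        (tmp_path / "s.fasta").write_text(">s\nACGTACGT\n")
        g = load_genome(tmp_path / "s.fasta")
        assert g.length == 8 and g.features == []

    def test_genbank_parsing(self, tmp_path):
        gb = """LOCUS       test                 30 bp    DNA     circular INV 01-JAN-2000
FEATURES             Location/Qualifiers
     CDS             1..12
                     /gene="COI"
     tRNA            complement(16..24)
                     /product="tRNA-Met"
ORIGIN
        1 atgaaatttt agccccacgt acgtacgtac
//
"""
        (tmp_path / "t.gb").write_text(gb)
        g = load_genome(tmp_path / "t.gb")
        assert g.is_circular
        labels = {(f.label, f.kind, f.start, f.end, f.strand)
                  for f in g.features}
        assert ("cox1", "PCG", 0, 12, 1) in labels
        assert ("trnM", "tRNA", 15, 24, -1) in labels
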