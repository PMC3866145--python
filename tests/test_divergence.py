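"""Codon-aware alignment, p-distances, bootstrap SEs, NG86 Ka/Ks."""

import itertools
import math
import random

import pytest
from Bio.Align import substitution_matrices

from mitodui.codes import codon_to_aa, sense_codons, stop_codons
from mitodui.divergence import (CodonAlignment, SaturationError,
                                align_aa_global, bootstrap_se,
                                concat_and_mask, gene_divergence,
                                nei_gojobori, p_distance,
                                pairwise_codon_alignment, retro_align)


# ---------------------------------------------------------------------------
# alignment

def brute_force_global_score(a, b, matrix, gap_open, gap_extend):
    """Enumerate every global alignment of two short peptides."""
    best = -math.inf

    def gap_cost(k):
        return 0 if k == 0 else gap_open + gap_extend * (k - 1)

    def rec(i, j, score, in_gap_a, in_gap_b):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], False, False)
        if i < len(a):  # a[i] against gap
            cost = gap_extend if in_gap_a else gap_open
            rec(i + 1, j, score - cost, True, False)
        if j < len(b):
            cost = gap_extend if in_gap_b else gap_open
            rec(i, j + 1, score - cost, False, True)

    rec(0, 0, 0.0, False, False)
    return best


class TestAlignment:
    def test_identity_alignment(self):
        assert align_aa_global("MKVL", "MKVL") == ("MKVL", "MKVL")

    def test_single_gap(self):
        row_a, row_b = align_aa_global("MKV", "MV")
        assert row_a == "MKV" and row_b in ("M-V",)

    def test_matches_exhaustive_enumeration(self):
        blosum = substitution_matrices.load("BLOSUM62")
        aligner_scorer = None
        rng = random.Random(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = blosum
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        for _ in range(15):
            a = "".join(rng.choice(aas) for _ in range(rng.randint(2, 6)))
            b = "".join(rng.choice(aas) for _ in range(rng.randint(2, 6)))
            assert aligner.score(a, b) == pytest.approx(
                brute_force_global_score(a, b, blosum, 10, 1))

    def test_substitutions_only_stay_gap_free(self):
        rng = random.Random(5)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(aas) for _ in range(50))
        b = list(a)
        for pos in rng.sample(range(50), 5):
            b[pos] = rng.choice(aas.replace(a[pos], ""))
        row_a, row_b = align_aa_global(a, "".join(b))
        assert "-" not in row_a and "-" not in row_b

    def test_empty_and_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            align_aa_global("", "MK")
        with pytest.raises(ValueError):
            align_aa_global("M*K", "MK")


class TestRetroAlign:
    def test_gap_free_case(self):
        aln = retro_align(("MK", "MK"), "ATGAAA", "ATGAAG")
        assert aln.rows == ("ATGAAA", "ATGAAG")

    def test_gap_becomes_codon_gap(self):
        aln = retro_align(("M-K", "MSK"), "ATGAAA", "ATGTCTAAA")
        assert aln.rows[0] == "ATG---AAA"
        assert aln.rows[1] == "ATGTCTAAA"

    def test_terminal_stop_stripped(self):
        aln = retro_align(("MK", "MK"), "ATGAAATAA", "ATGAAG")
        assert aln.rows[0] == "ATGAAA"

    def test_wrong_cds_is_correspondence_error(self):
        with pytest.raises(ValueError, match="residue|alignment row"):
            retro_align(("MK", "MK"), "ATGCCC", "ATGAAA")

    def test_ungapped_rows_reproduce_cds(self):
        cds_a, cds_b = "ATGTTTAAACCC", "ATGAAACCC"
        aln = pairwise_codon_alignment(cds_a, cds_b)
        assert aln.ungapped(0) == cds_a
        assert aln.ungapped(1) == cds_b


class TestPDistance:
    def test_identical_rows(self):
        assert p_distance(("ACGT", "ACGT")) == 0.0

    def test_hand_count(self):
        assert p_distance(("AAAAAAAAAA", "AAAAAAAATT")) == pytest.approx(0.2)

    def test_pairwise_deletion(self):
        assert p_distance(("AC-T", "ANGT")) == pytest.approx(0.0)

    def test_symmetry_and_column_permutation(self):
        rng = random.Random(11)
        a = "".join(rng.choice("ACGT") for _ in range(60))
        b = "".join(rng.choice("ACGT") for _ in range(60))
        assert p_distance((a, b)) == p_distance((b, a))
        perm = list(range(60))
        rng.shuffle(perm)
        ap = "".join(a[i] for i in perm)
        bp = "".join(b[i] for i in perm)
        assert p_distance((ap, bp)) == p_distance((a, b))

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError):
            p_distance(("---", "AAA"))


class TestBootstrap:
    def test_identical_rows_zero_se(self):
        assert bootstrap_se(("ACGT" * 30, "ACGT" * 30), replicates=100) == 0.0

    def test_matches_binomial_closed_form(self):
        rng = random.Random(23)
        n, p = 1000, 0.2
        a = "".join(rng.choice("ACGT") for _ in range(n))
        b = list(a)
        for pos in rng.sample(range(n), int(n * p)):
            b[pos] = rng.choice("ACGT".replace(a[pos], ""))
        se = bootstrap_se((a, "".join(b)), replicates=1000, seed=9)
        closed = math.sqrt(p * (1 - p) / n)
        assert abs(se - closed) / closed < 0.15

    def test_reproducible_for_seed(self):
        rows = ("ACGTAGGTCC" * 20, "ACCTAGGTCA" * 20)
        assert bootstrap_se(rows, seed=4) == bootstrap_se(rows, seed=4)
        assert bootstrap_se(rows, seed=4) != bootstrap_se(rows, seed=5)

    def test_replicate_floor(self):
        with pytest.raises(ValueError):
            bootstrap_se(("ACGT", "ACGT"), replicates=10)


# ---------------------------------------------------------------------------
# NG86

def oracle_ng86(codons_a, codons_b, code=5):
    """Independent NG86: direct site counting + pathway enumeration."""
    aa = codon_to_aa(code)

    def syn_sites(codon):
        s = 0
        for pos in range(3):
            for base in "ACGT":
                if base != codon[pos]:
                    alt = codon[:pos] + base + codon[pos + 1:]
                    if aa[alt] != "*" and aa[alt] == aa[codon]:
                        s += 1
        return s / 3

    def diffs(ca, cb):
        pos = [i for i in range(3) if ca[i] != cb[i]]
        if not pos:
            return 0.0, 0.0
        paths = []
        for order in itertools.permutations(pos):
            cur, sd, nd, ok = ca, 0, 0, True
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if aa[nxt] == "*" and nxt != cb:
                    ok = False
                    break
                sd += aa[nxt] == aa[cur]
                nd += aa[nxt] != aa[cur]
                cur = nxt
            if ok:
                paths.append((sd, nd))
        if not paths:
            for order in itertools.permutations(pos):
                cur, sd, nd = ca, 0, 0
                for p in order:
                    nxt = cur[:p] + cb[p] + cur[p + 1:]
                    sd += aa[nxt] == aa[cur]
                    nd += aa[nxt] != aa[cur]
                    cur = nxt
                paths.append((sd, nd))
        return (sum(x for x, _ in paths) / len(paths),
                sum(y for _, y in paths) / len(paths))

    S = sum((syn_sites(a) + syn_sites(b)) / 2
            for a, b in zip(codons_a, codons_b))
    N = 3 * len(codons_a) - S
    sd = sum(diffs(a, b)[0] for a, b in zip(codons_a, codons_b))
    nd = sum(diffs(a, b)[1] for a, b in zip(codons_a, codons_b))
    ps, pn = sd / S, nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(ps), jc(pn), S, N


class TestNeiGojobori:
    def test_identical_sequences(self):
        aln = CodonAlignment(("a", "b"), ("ATGAAATTT", "ATGAAATTT"))
        r = nei_gojobori(aln)
        assert r.ka == r.ks == 0.0
        assert r.omega is None

    def test_glycine_hand_example(self):
        # 5 Gly codons; one G->C change at a third position
        aln = CodonAlignment(("a", "b"), ("GGG" * 5, "GGG" * 4 + "GGC"))
        r = nei_gojobori(aln)
        assert r.s_sites == pytest.approx(5.0)
        assert r.sd == pytest.approx(1.0)
        assert r.ps == pytest.approx(0.2)
        assert r.ks == pytest.approx(0.2326, abs=1e-4)
        assert r.ka == 0.0

    def test_site_conservation_and_swap_symmetry(self):
        rng = random.Random(41)
        codons = sense_codons(5)
        for _ in range(20):
            n = rng.randint(1, 10)
            a = [rng.choice(codons) for _ in range(n)]
            b = [rng.choice(codons) for _ in range(n)]
            aln = CodonAlignment(("x", "y"), ("".join(a), "".join(b)))
            try:
                r = nei_gojobori(aln)
            except SaturationError:
                continue
            assert r.s_sites + r.n_sites == pytest.approx(3 * n)
            swapped = CodonAlignment(("y", "x"), ("".join(b), "".join(a)))
            try:
                r2 = nei_gojobori(swapped)
            except SaturationError:
                continue
            assert r2.ka == pytest.approx(r.ka)
            assert r2.ks == pytest.approx(r.ks)

    def test_matches_independent_oracle(self):
        rng = random.Random(7)
        codons = sense_codons(5)
        checked = 0
        while checked < 12:
            n = rng.randint(2, 10)
            a = [rng.choice(codons) for _ in range(n)]
            # mutate a few positions of a copy so divergence stays moderate
            b = list(a)
            for _ in range(rng.randint(0, n)):
                i = rng.randrange(n)
                pos = rng.randrange(3)
                cand = b[i][:pos] + rng.choice("ACGT") + b[i][pos + 1:]
                if cand not in stop_codons(5):
                    b[i] = cand
            aln = CodonAlignment(("x", "y"), ("".join(a), "".join(b)))
            try:
                r = nei_gojobori(aln)
            except SaturationError:
                continue
            ks, ka, S, N = oracle_ng86(a, b)
            assert r.ks == pytest.approx(ks)
            assert r.ka == pytest.approx(ka)
            assert r.s_sites == pytest.approx(S)
            checked += 1

    def test_gapped_codons_masked(self):
        aln = CodonAlignment(("a", "b"), ("ATG---AAA", "ATGCCCAAA"))
        assert nei_gojobori(aln).codons == 2

    def test_saturation_raises(self):
        # every codon differs synonymously -> ps = 1 > 3/4
        aln = CodonAlignment(("a", "b"), ("GGG" * 5, "GGA" * 5))
        with pytest.raises(SaturationError):
            nei_gojobori(aln)

    def test_stop_in_alignment_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori(CodonAlignment(("a", "b"), ("TAA", "ATG")))


class TestConcat:
    def _toy(self, ncodons, seed):
        rng = random.Random(seed)
        codons = sense_codons(5)
        a = "".join(rng.choice(codons) for _ in range(ncodons))
        b = "".join(rng.choice(codons) for _ in range(ncodons))
        return CodonAlignment(("x", "y"), (a, b))

    def test_single_gene_no_drop_is_identity(self):
        aln = self._toy(4, 1)
        out, parts = concat_and_mask([aln])
        assert out.rows == aln.rows
        assert parts == {"g1": (0, 12)}

    def test_drop_third_position(self):
        a1, a2 = self._toy(2, 2), self._toy(3, 3)
        out, parts = concat_and_mask([a1, a2], drop_positions=[3])
        assert len(out[0]) == (2 + 3) * 2
        assert parts == {"g1": (0, 4), "g2": (4, 10)}

    def test_two_thirds_length_relation(self):
        alns = [self._toy(n, n) for n in (5, 7, 8)]
        full, _ = concat_and_mask(alns)
        masked, _ = concat_and_mask(alns, drop_positions=[3])
        assert len(masked[0]) * 3 == full.length * 2

    def test_label_mismatch_rejected(self):
        a = self._toy(2, 4)
        b = CodonAlignment(("p", "q"), a.rows)
        with pytest.raises(ValueError, match="label"):
            concat_and_mask([a, b])


class TestGeneDivergence:
    def test_fixture_pair_table(self, fixture_pair):
        f, m = fixture_pair
        res = {r.gene: r for r in gene_divergence(
            f, m, labels=["cox1", "rrnS"], bootstrap_replicates=100)}
        cox1 = res["cox1"]
        # male genes were evolved from female ones: divergence is moderate,
        # omega well below 1 (purifying-selection regime)
        assert 0.2 < cox1.pd_nt < 0.55
        assert cox1.pd_aa > cox1.pd_nt * 0.8
        assert 0.1 < cox1.omega < 0.6
        assert cox1.ks > cox1.ka
        rrns = res["rrnS"]
        assert rrns.ka is None
        assert rrns.pd_nt == pytest.approx(0.291, abs=0.03)
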