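"""Alignment, identity, variation counting, and NG86 dN/dS."""

import itertools

import numpy as np
import pytest
from Bio import Align

from mitocomp import (
    MITO_CODE,
    PairwiseAlignment,
    PhyloTree,
    brower_age,
    count_variation,
    global_align,
    ng86_dnds,
    percent_identity,
)
from mitocomp.genome import ValidationError


def biopython_score(a, b, match=1, mismatch=-1, gap_open=-5, gap_extend=-1):
    """Independent affine-gap global alignment score (dynamic programming)."""
    pa = Align.PairwiseAligner(
        match_score=match, mismatch_score=mismatch,
        open_gap_score=gap_open, extend_gap_score=gap_extend, mode="global",
    )
    return pa.score(a, b)


class TestGlobalAlign:
    def test_identical_strings_gap_free(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.seq_a == aln.seq_b == "ACGTACGT"
        assert aln.columns == 8

    def test_single_gap_column(self):
        aln = global_align("ACGT", "AGT", match=1, mismatch=-1,
                           gap_open=-1, gap_extend=-1)
        gaps = sum(1 for x, y in zip(aln.seq_a, aln.seq_b) if x == "-" or y == "-")
        assert gaps == 1

    def test_score_matches_independent_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 20, 2)
            a = "".join(rng.choice(list("ACGT"), n1))
            b = "".join(rng.choice(list("ACGT"), n2))
            aln = global_align(a, b)
            assert aln.score == pytest.approx(biopython_score(a, b))

    def test_traceback_score_is_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), rng.integers(2, 25)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(2, 25)))
            aln = global_align(a, b)
            score, state = 0.0, None
            for x, y in zip(aln.seq_a, aln.seq_b):
                if x == "-" or y == "-":
                    s = "a" if x == "-" else "b"
                    score += -1 if state == s else -5
                    state = s
                else:
                    score += 1 if x == y else -1
                    state = None
            assert score == pytest.approx(aln.score)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            global_align("", "ACGT")


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(global_align("ACGT", "ACGT")) == 100.0

    def test_ninety_nine_of_hundred(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        aln = PairwiseAlignment(seq_a=a, seq_b=b, score=0.0)
        assert percent_identity(aln) == pytest.approx(99.0)

    def test_internal_gap_in_denominator(self):
        aln = PairwiseAlignment(seq_a="AC-GT", seq_b="ACAGT", score=0.0)
        assert percent_identity(aln) == pytest.approx(100 * 4 / 5)

    def test_terminal_overhang_excluded(self):
        aln = PairwiseAlignment(seq_a="--ACGT", seq_b="GGACGT", score=0.0)
        assert percent_identity(aln) == pytest.approx(100.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), 60))
        b = "".join(rng.choice(list("ACGT"), 55))
        ab = percent_identity(global_align(a, b))
        ba = percent_identity(global_align(b, a))
        assert ab == pytest.approx(ba)


class TestCountVariation:
    def test_identical(self):
        assert count_variation(global_align("ACGT", "ACGT")) == (0, 0, 0)

    def test_gap_run_plus_mismatches(self):
        aln = PairwiseAlignment(seq_a="AAACCC---GGGT", seq_b="AAAGCCTTTGGGA", score=0)
        assert count_variation(aln) == (3, 2, 1)

    def test_planted_cr_events_recovered(self, genotype_pair):
        from mitocomp import extract_gene

        (g1, t1), (g2, t2) = genotype_pair
        cr1 = extract_gene(g1, t1.control_region)
        cr2 = extract_gene(g2, t2.control_region)
        aln = global_align(cr1, cr2)
        assert count_variation(aln) == (15, 6, 9)


def brute_force_pathways(c1, c2, code=MITO_CODE):
    """Enumerate substitution orderings explicitly; skip stop intermediates."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and nxt != c2:
                ok = False
                break
            if code.codon_to_aa[cur] == code.codon_to_aa[nxt] and not code.is_stop(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    return results


class TestNg86:
    def test_identical_sequences(self):
        r = ng86_dnds("ATGTTTGGA", "ATGTTTGGA")
        assert r.Nd == 0 and r.Sd == 0
        assert r.omega is None

    def test_synonymous_single_difference(self):
        r = ng86_dnds("TTT", "TTC")
        assert r.Sd == 1 and r.Nd == 0

    def test_site_count_invariant(self):
        rng = np.random.default_rng(2)
        sense = MITO_CODE.sense_codons
        for _ in range(20):
            codons = rng.choice(len(sense), 30)
            a = "".join(sense[i] for i in codons)
            b = "".join(sense[i] for i in rng.choice(len(sense), 30))
            r = ng86_dnds(a, b)
            assert r.N + r.S == pytest.approx(3 * r.codons)

    def test_two_difference_codons_match_pathway_enumeration(self):
        sense = MITO_CODE.sense_codons
        pairs = [
            (c1, c2)
            for c1 in sense
            for c2 in sense
            if sum(a != b for a, b in zip(c1, c2)) == 2
        ]
        for c1, c2 in pairs:
            r = ng86_dnds(c1, c2)
            paths = brute_force_pathways(c1, c2)
            if paths:
                syn = sum(p[0] for p in paths) / len(paths)
                nonsyn = sum(p[1] for p in paths) / len(paths)
                assert r.Sd == pytest.approx(syn), (c1, c2)
                assert r.Nd == pytest.approx(nonsyn), (c1, c2)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        sense = MITO_CODE.sense_codons
        a = "".join(sense[i] for i in rng.choice(len(sense), 40))
        b = "".join(sense[i] for i in rng.choice(len(sense), 40))
        r1, r2 = ng86_dnds(a, b), ng86_dnds(b, a)
        assert r1.dN == pytest.approx(r2.dN)
        assert r1.dS == pytest.approx(r2.dS)

    def test_n_codons_skipped(self):
        r = ng86_dnds("TTTNNN", "TTCAAA")
        assert r.codons == 1 and r.Sd == 1

    def test_neutral_simulation_brackets_one(self):
        """Under omega=1 the NG86 estimate should scatter around 1."""
        from mitocomp import CodonSimSpec, simulate_codon_alignment

        tree = PhyloTree.from_newick("(A:0.3,B:0.3);")
        omegas = []
        for rep in range(20):
            spec = CodonSimSpec(
                seed=1000 + rep, tree=tree, kappa=1.0,
                site_classes=((1.0, 1.0),), n_codons=2000,
            )
            aln = simulate_codon_alignment(spec)
            r = ng86_dnds(aln.codon_strings("A"), aln.codon_strings("B"))
            if r.omega is not None:
                omegas.append(r.omega)
        med = float(np.median(omegas))
        assert 0.8 <= med <= 1.25

    def test_omega_zero_simulation_all_differences_synonymous(self):
        """Under omega=0 every observed codon difference preserves the amino
        acid; NG86's pathway averaging may still attribute a small Nd when a
        minimal path between synonymous codons crosses another amino acid."""
        from mitocomp import CodonSimSpec, simulate_codon_alignment

        tree = PhyloTree.from_newick("(A:0.5,B:0.5);")
        spec = CodonSimSpec(seed=3, tree=tree, site_classes=((1.0, 0.0),), n_codons=500)
        aln = simulate_codon_alignment(spec)
        code = aln.code
        for ia, ib in zip(*aln.matrix):
            ca, cb = code.sense_codons[ia], code.sense_codons[ib]
            if ca != cb:
                assert code.codon_to_aa[ca] == code.codon_to_aa[cb]
        r = ng86_dnds(aln.codon_strings("A"), aln.codon_strings("B"))
        assert r.Nd / (r.Nd + r.Sd) < 0.02

    def test_gapped_input_rejected(self):
        with pytest.raises(ValidationError):
            ng86_dnds("AT-", "ATG")


class TestBrowerAge:
    def test_rate_definition(self):
        assert brower_age(2.3) == pytest.approx(1.0)

    def test_zero(self):
        assert brower_age(0.0) == 0.0

    def test_linearity(self):
        assert brower_age(4.6) == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            brower_age(-1.0)
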