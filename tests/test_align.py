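"""Alignment primitives against independent oracles.

Oracles here are deliberately different code paths from the implementation:
a hand-written exhaustive scan for repeats, interval arithmetic for block
merging, and Biopython's full dynamic-programming local aligner for the
seed-and-extend search.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from mobilomics._seq import revcomp
from mobilomics.align import (
    AlignmentBlock,
    KmerIndex,
    find_direct_repeats,
    find_inverted_repeats,
    in_silico_pcr,
    local_search,
    merge_blocks,
    protein_identity_coverage,
)

RNG = np.random.default_rng(42)


def rand_dna(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def rand_prot(n, rng=RNG):
    return "M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=n - 1))


def mutate(seq, k, rng=RNG, alphabet="ACGT"):
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = next(c for c in alphabet if c != s[pos])
    return "".join(s)


# ---------------------------------------------------------------------------
# Protein identity / coverage
# ---------------------------------------------------------------------------

class TestProteinIdentityCoverage:
    def test_identical_sequences(self):
        p = rand_prot(100)
        assert protein_identity_coverage(p, p) == (1.0, 1.0)

    def test_exact_prefix_gives_prefix_coverage(self):
        p = rand_prot(100)
        ident, cov = protein_identity_coverage(p, p[:70])
        assert ident == pytest.approx(1.0)
        assert cov == pytest.approx(0.70)

    def test_substitution_only_identity_matches_mismatch_count(self):
        # gapless optimum: identity is exactly the conserved fraction
        p = rand_prot(200)
        q = mutate(p, 20, alphabet="ACDEFGHIKLMNPQRSTVWY")
        ident, cov = protein_identity_coverage(p, q)
        assert cov == pytest.approx(1.0)
        assert ident == pytest.approx(0.90, abs=0.005)

    def test_divergent_transposases_pass_60_percent(self):
        p = rand_prot(300)
        q = mutate(p, 105, alphabet="ACDEFGHIKLMNPQRSTVWY")  # ~65% identity
        ident, _ = protein_identity_coverage(p, q)
        assert 0.60 <= ident <= 0.70

    def test_rejects_non_amino_acid_symbols(self):
        with pytest.raises(ValueError):
            protein_identity_coverage("MKV1LL", "MKVLL")


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

class TestKmerIndex:
    def test_forward_position_count(self):
        seq = rand_dna(100)
        idx = KmerIndex(seq, k=11)
        assert len(idx) <= 90
        assert sum(len(idx.positions(seq[i : i + 11])) >= 1 for i in range(90)) == 90

    def test_reverse_strand_lookup(self):
        seq = rand_dna(60)
        idx = KmerIndex(seq, k=12)
        kmer = seq[20:32]
        assert idx.positions(revcomp(kmer), strand="-") == idx.positions(kmer, strand="+")

    def test_planted_repeat_found_at_both_positions(self):
        rng = np.random.default_rng(5)
        repeat = rand_dna(20, rng)
        seq = rand_dna(200, rng) + repeat + rand_dna(150, rng) + repeat + rand_dna(100, rng)
        idx = KmerIndex(seq, k=20)
        # exhaustive scan oracle
        expected = [i for i in range(len(seq) - 19) if seq[i : i + 20] == repeat]
        assert idx.positions(repeat) == expected
        assert len(expected) == 2

    def test_k_range_enforced(self):
        with pytest.raises(ValueError):
            KmerIndex("ACGTACGTACGT", k=5)


# ---------------------------------------------------------------------------
# local_search vs an exhaustive DP oracle
# ---------------------------------------------------------------------------

def _dp_local(query: str, subject: str):
    """Independent full dynamic-programming local alignment (Biopython)."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -2
    aln = a.align(query, subject)[0]
    tseg, qseg = aln.aligned
    return int(tseg[0][0]), int(tseg[-1][1]), int(qseg[0][0]), int(qseg[-1][1]), aln.score


class TestLocalSearch:
    def test_exact_substring_single_block(self):
        rng = np.random.default_rng(7)
        subject = rand_dna(8000, rng)
        query = subject[2500:5500]
        blocks = local_search(query, subject, min_length=1000, min_identity=0.95)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.q_start, b.q_end, b.s_start, b.s_end) == (0, 3000, 2500, 5500)
        assert b.identity == 1.0 and b.strand == "+"

    def test_identity_threshold_excludes_85_percent_match(self):
        rng = np.random.default_rng(8)
        subject = rand_dna(4000, rng)
        elem = rand_dna(1000, rng)
        noisy = mutate(elem, 150, rng)  # 85% identity
        s = subject[:2000] + noisy + subject[2000:]
        assert local_search(elem, s, min_length=500, min_identity=0.90) == []
        assert len(local_search(elem, s, min_length=500, min_identity=0.80)) == 1

    def test_planted_loci_match_dp_oracle(self):
        rng = np.random.default_rng(9)
        elem = rand_dna(1200, rng)
        subject = rand_dna(50_000, rng)
        positions = [4000, 14_000, 24_000, 34_000, 44_000]
        noise = [0, 20, 40, 60, 0]
        s = subject
        for p, nz in zip(reversed(positions), reversed(noise)):
            copy = mutate(elem, nz, rng) if nz else elem
            s = s[:p] + copy + s[p:]
        blocks = local_search(elem, s, min_length=600, min_identity=0.90)
        assert len(blocks) == 5
        starts = sorted(b.s_start for b in blocks)
        expected = [p + i * 1200 for i, p in enumerate(positions)]
        assert starts == expected
        # per-locus comparison with the exhaustive DP aligner on <= 5 kb windows
        for b in blocks:
            lo = max(0, b.s_start - 1500)
            window = s[lo : b.s_start + 1200 + 1500]
            q0, q1, w0, w1, score = _dp_local(elem, window)
            assert abs((lo + w0) - b.s_start) <= 2
            assert abs((lo + w1) - b.s_end) <= 2
            assert (q0, q1) == (b.q_start, b.q_end)

    def test_reverse_strand_copy_flips_label_only(self):
        rng = np.random.default_rng(10)
        elem = rand_dna(900, rng)
        subject = rand_dna(6000, rng)
        s = subject[:3000] + revcomp(elem) + subject[3000:]
        fwd = local_search(elem, s, min_length=500, min_identity=0.95)
        rev = local_search(revcomp(elem), s, min_length=500, min_identity=0.95)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].strand == "-" and rev[0].strand == "+"
        assert (fwd[0].s_start, fwd[0].s_end) == (rev[0].s_start, rev[0].s_end) == (3000, 3900)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            local_search("", "ACGT" * 100, min_length=13, min_identity=0.9)


# ---------------------------------------------------------------------------
# merge_blocks
# ---------------------------------------------------------------------------

def _mk_block(qs, qe):
    return AlignmentBlock("q", "s", qs, qe, qs, qe, "+", 1.0, qe - qs)


class TestMergeBlocks:
    @pytest.mark.parametrize(
        "gap,expected",
        [(500, [(0, 2000)]), (100, [(0, 1000), (1200, 2000)])],
    )
    def test_gap_controls_merging(self, gap, expected):
        blocks = [_mk_block(0, 1000), _mk_block(1200, 2000)]
        assert merge_blocks(blocks, max_gap=gap) == expected

    def test_random_blocks_match_interval_arithmetic_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            blocks = []
            for _ in range(50):
                s = int(rng.integers(0, 20_000))
                blocks.append(_mk_block(s, s + int(rng.integers(50, 800))))
            gap = int(rng.integers(0, 1000))
            got = merge_blocks(blocks, max_gap=gap)
            # oracle: mark covered positions closed under gaps <= gap
            ivals = sorted((b.q_start, b.q_end) for b in blocks)
            expected = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s - expected[-1][1] <= gap:
                    expected[-1][1] = max(expected[-1][1], e)
                else:
                    expected.append([s, e])
            assert got == [tuple(x) for x in expected]
            # every input block contained in exactly one output interval
            for b in blocks:
                assert sum(1 for s, e in got if s <= b.q_start and b.q_end <= e) == 1


# ---------------------------------------------------------------------------
# Repeat scans
# ---------------------------------------------------------------------------

def _ir_oracle(seq, arm_min, arm_max, max_mismatch, window):
    """Naive exhaustive arm-pair scan."""
    n = len(seq)
    hits = []
    for L in range(arm_min, min(arm_max, n // 2) + 1):
        for i in range(0, min(window, n)):
            if i + L > n:
                break
            target = revcomp(seq[i : i + L])
            for j in range(max(i + L, n - window - L + 1), n - L + 1):
                if j + L <= n - window:
                    continue
                mm = sum(a != b for a, b in zip(seq[j : j + L], target))
                if mm <= max_mismatch:
                    hits.append((i, i + L, j, j + L, mm))
    return hits


class TestInvertedRepeats:
    def test_planted_terminal_ir(self):
        rng = np.random.default_rng(12)
        ir = rand_dna(14, rng)
        elem = ir + rand_dna(800, rng) + revcomp(ir)
        pairs = find_inverted_repeats(elem, arm_min=10, arm_max=30, max_mismatch=0, window=40)
        assert pairs
        top = pairs[0]
        assert top.repeat_length >= 14 and top.mismatches == 0
        assert top.left_start == 0 and top.right_end == len(elem)

    def test_random_sequence_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            seq = rand_dna(400, rng)
            got = find_inverted_repeats(seq, arm_min=12, arm_max=16, max_mismatch=0, window=60)
            oracle = _ir_oracle(seq, 12, 16, 0, 60)
            # every reported pair is a true pair; every maximal oracle pair is covered
            for p in got:
                arm = seq[p.left_start : p.left_end]
                other = seq[p.right_start : p.right_end]
                assert sum(a != b for a, b in zip(other, revcomp(arm))) == p.mismatches == 0
            for (i, ie, j, je, _mm) in oracle:
                assert any(
                    p.left_start <= i and p.left_end >= ie and p.right_start <= j and p.right_end >= je
                    for p in got
                ), "oracle pair missing"

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(14)
        ir = rand_dna(16, rng)
        elem = ir + rand_dna(500, rng) + revcomp(ir)
        fwd = find_inverted_repeats(elem, 10, 20, 0, 50)
        rev = find_inverted_repeats(revcomp(elem), 10, 20, 0, 50)
        n = len(elem)
        mirrored = {(n - p.right_end, n - p.right_start, n - p.left_end, n - p.left_start) for p in rev}
        assert (fwd[0].left_start, fwd[0].left_end, fwd[0].right_start, fwd[0].right_end) in mirrored


class TestDirectRepeats:
    ATT = "AGAAGTCCCAGT"

    def _island(self, rng, mism_right=0):
        att_r = mutate(self.ATT, mism_right, rng) if mism_right else self.ATT
        pre = rand_dna(600, rng)
        core = rand_dna(3000, rng)
        post = rand_dna(600, rng)
        seq = pre + self.ATT + core + att_r + post
        island = (600, 600 + 12 + 3000)  # [left att start, right att start)
        return seq, island

    def test_planted_att_found_exactly(self):
        rng = np.random.default_rng(15)
        seq, island = self._island(rng)
        pairs = find_direct_repeats(seq, island, repeat_length=12, max_mismatch=0, window=400)
        assert pairs
        top = pairs[0]
        assert top.repeat_length >= 12
        assert seq[top.left_start : top.left_start + 12] == self.ATT
        assert (top.left_start, top.right_start) == (600, 600 + 12 + 3000)

    def test_no_repeat_yields_empty(self):
        rng = np.random.default_rng(16)
        seq = rand_dna(4000, rng)
        assert (
            find_direct_repeats(seq, (1000, 3000), repeat_length=12, max_mismatch=0, window=300)
            == []
        )

    def test_mismatch_tolerance(self):
        rng = np.random.default_rng(17)
        seq, island = self._island(rng, mism_right=1)
        strict = find_direct_repeats(seq, island, 12, max_mismatch=0, window=400)
        loose = find_direct_repeats(seq, island, 12, max_mismatch=1, window=400)

        def covers(p):  # arm pair containing the planted att positions
            return (
                p.left_start <= 600 and p.left_end >= 612
                and p.right_start <= island[1] and p.right_end >= island[1] + 12
            )

        assert not any(covers(p) for p in strict)
        assert any(covers(p) for p in loose)


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

class TestInSilicoPcr:
    def _template(self, rng, n=1000):
        return rand_dna(n, rng)

    def test_linear_product_arithmetic(self):
        rng = np.random.default_rng(18)
        t = self._template(rng)
        fwd = t[100:120]
        rev = revcomp(t[580:600])
        products = in_silico_pcr(t, fwd, rev, max_product=2000, max_mismatch=0)
        assert len(products) == 1
        assert products[0].product_length == 500

    def test_outward_pair_needs_circular_template(self):
        rng = np.random.default_rng(19)
        t = self._template(rng, 3000)
        fwd = t[2500:2520]  # points right, near the end
        rev = revcomp(t[400:420])  # points left, near the start
        linear = in_silico_pcr(t, fwd, rev, max_product=3000, topology="linear")
        circular = in_silico_pcr(t, fwd, rev, max_product=3000, topology="circular")
        assert linear == []
        assert len(circular) == 1
        assert circular[0].product_length == (420 - 2500) % 3000
        assert circular[0].spans_origin

    def test_rotation_invariance_on_circular_template(self):
        rng = np.random.default_rng(20)
        t = self._template(rng, 2000)
        fwd = t[300:320]
        rev = revcomp(t[900:920])
        base = {p.product_length for p in in_silico_pcr(t, fwd, rev, max_product=2500, topology="circular")}
        for shift in (137, 555, 1501):
            rot = t[shift:] + t[:shift]
            got = {
                p.product_length
                for p in in_silico_pcr(rot, fwd, rev, max_product=2500, topology="circular")
            }
            assert got == base

    def test_three_prime_terminus_must_match(self):
        rng = np.random.default_rng(21)
        t = self._template(rng)
        fwd = t[100:120]
        bad_fwd = fwd[:-1] + next(c for c in "ACGT" if c != fwd[-1])
        rev = revcomp(t[580:600])
        assert in_silico_pcr(t, bad_fwd, rev, max_product=2000, max_mismatch=2)== []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            in_silico_pcr("ACGT" * 100, "ACGTACGTACGT", "ACGTACGTACGTACGTA")
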