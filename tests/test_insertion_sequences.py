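"""IS discovery, delimitation, census, disruption, composite transposons."""

from __future__ import annotations

import collections

import numpy as np
import pytest

from mobilomics._seq import revcomp
from mobilomics.genomes import GeneFeature, Genome, Replicon
from mobilomics.insertion_sequences import (
    AmbiguousBoundariesError,
    ISCopy,
    ISElement,
    confirm_multicopy,
    delimit_element,
    detect_composite_transposons,
    detect_gene_disruption,
    extract_candidate,
    find_transposase_anchors,
    mobile_annotation_counts,
)
from conftest import match_intervals

RNG = np.random.default_rng(77)


def rand_dna(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutate(seq, k, rng=RNG):
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = next(c for c in "ACGT" if c != s[pos])
    return "".join(s)


def _genome(seq, feats, strain="G1", topology="circular"):
    return Genome(strain, "Sp", [Replicon(f"chr_{strain}", seq, topology, feats)])


# ---------------------------------------------------------------------------
# Anchors and candidate extraction
# ---------------------------------------------------------------------------

class TestAnchors:
    def test_grouping_by_identical_translation_length(self):
        t1 = "M" + "A" * 99
        t2 = "M" + "C" * 99
        t3 = "M" + "D" * 49
        feats = [
            GeneFeature("a", "CDS", 100, 403, "+", "IS3 family transposase", t1),
            GeneFeature("b", "CDS", 1000, 1303, "+", "transposase", t2),
            GeneFeature("c", "CDS", 2000, 2303, "+", "mobile element protein", t1),
            GeneFeature("d", "CDS", 3000, 3153, "+", "transposase", t3),
            GeneFeature("e", "CDS", 4000, 4303, "+", "integrase", t1),
        ]
        g = _genome("ACGT" * 2000, feats)
        groups = find_transposase_anchors(g)
        assert {k: len(v) for k, v in groups.items()} == {100: 3, 50: 1}
        counts = mobile_annotation_counts(g)
        assert counts == {"transposases": 4, "integrases": 1}

    def test_keyword_free_genome_has_no_anchors(self):
        g = _genome("ACGT" * 500, [GeneFeature("x", "CDS", 10, 100, "+", "catalase", "M" * 30)])
        assert find_transposase_anchors(g) == {}


class TestExtractCandidate:
    def _anchor_genome(self, pre, cds_len=1200, post=5000):
        seq = rand_dna(pre) + rand_dna(cds_len) + rand_dna(post)
        f = GeneFeature("t1", "CDS", pre, pre + cds_len, "+", "transposase", "M" * (cds_len // 3 - 1))
        return _genome(seq, [f]), f

    def test_mid_chromosome_flank_arithmetic(self):
        g, f = self._anchor_genome(pre=3000)
        cand = extract_candidate(f, g, flank=1000)
        assert len(cand.sequence) == 3200
        assert cand.start == 2000
        assert cand.sequence == g.chromosome.sequence[2000:5200]

    def test_circular_wrap_keeps_full_length(self):
        g, f = self._anchor_genome(pre=300)
        cand = extract_candidate(f, g, flank=1000)
        assert len(cand.sequence) == 3200
        n = len(g.chromosome.sequence)
        assert cand.sequence == g.chromosome.sequence[n - 700 :] + g.chromosome.sequence[: 2500]

    def test_linear_contig_edge_truncates(self):
        seq = rand_dna(300) + rand_dna(1200) + rand_dna(5000)
        f = GeneFeature("t1", "CDS", 300, 1500, "+", "transposase", "M" * 399)
        g = _genome(seq, [f], topology="linear")
        cand = extract_candidate(f, g, flank=1000)
        assert cand.truncated and len(cand.sequence) == 2500


# ---------------------------------------------------------------------------
# Confirmation and delimitation
# ---------------------------------------------------------------------------

def _multi_copy_genome(element, positions, noise=0, rng=RNG, strain="G1", trunc_at=None):
    seq = rand_dna(60_000, rng)
    feats = []
    offset = 0
    for i, p in enumerate(sorted(positions)):
        copy = mutate(element, noise, rng) if noise else element
        if trunc_at == i:
            copy = copy[len(copy) * 2 // 5 :]  # 5'-truncated to 60%
        pos = p + offset
        seq = seq[:pos] + copy + seq[pos:]
        orf_start = pos + 60
        feats.append(
            GeneFeature(
                f"{strain}_t{i}", "CDS", orf_start, orf_start + 300, "+",
                "transposase", "M" + "A" * 99,
            )
        )
        offset += len(copy)
    return _genome(seq, feats, strain=strain)


class TestConfirmAndDelimit:
    def setup_method(self):
        self.rng = np.random.default_rng(123)
        ir = rand_dna(16, self.rng)
        self.element = ir + rand_dna(1160, self.rng) + revcomp(ir)

    def test_single_locus_candidate_is_not_an_is(self):
        g = _multi_copy_genome(self.element, [10_000], rng=self.rng)
        anchor = g.chromosome.features[0]
        cand = extract_candidate(anchor, g)
        assert confirm_multicopy(cand, [g]) == []

    def test_low_identity_copies_not_confirmed(self):
        g = _multi_copy_genome(self.element, [10_000, 35_000], noise=180, rng=self.rng)  # 85%
        anchor = g.chromosome.features[0]
        cand = extract_candidate(anchor, g)
        copies = confirm_multicopy(cand, [g], min_identity=0.90)
        # the two planted copies are ~70% identical to each other via
        # independent mutation; only self-locus remains -> not multi-copy
        assert copies == []

    def test_planted_copies_confirmed_and_delimited(self):
        g = _multi_copy_genome(self.element, [10_000, 25_000, 40_000], rng=self.rng)
        anchor = g.chromosome.features[0]
        cand = extract_candidate(anchor, g)
        copies = confirm_multicopy(cand, [g])
        assert sum(not c.partial for c in copies) == 3
        elem = delimit_element(cand, copies, name="ISx1")
        assert elem.length == len(self.element)
        assert elem.element_sequence == self.element
        # maximal arms: at least the planted 16 bp, anchored at the termini
        assert elem.left_ir[:16] == self.element[:16]
        assert elem.right_ir[-16:] == self.element[-16:]

    def test_truncated_copy_flagged_partial_boundaries_follow_intact(self):
        g = _multi_copy_genome(
            self.element, [10_000, 25_000, 40_000], rng=self.rng, trunc_at=1
        )
        anchor = g.chromosome.features[0]
        cand = extract_candidate(anchor, g)
        copies = confirm_multicopy(cand, [g])
        assert sum(c.partial for c in copies) == 1
        elem = delimit_element(cand, copies, name="ISx2")
        assert elem.element_sequence == self.element

    def test_no_ir_element_retained_with_empty_ir_fields(self):
        rng = np.random.default_rng(321)
        element = rand_dna(1200, rng)  # no terminal IRs planted
        g = _multi_copy_genome(element, [10_000, 30_000], rng=rng)
        anchor = g.chromosome.features[0]
        cand = extract_candidate(anchor, g)
        copies = confirm_multicopy(cand, [g])
        elem = delimit_element(cand, copies, ir_max_mismatch=0, arm_min=12)
        assert elem.element_sequence == element
        assert not elem.has_ir

    def test_wildly_disagreeing_copies_raise_ambiguity(self):
        cand_seq = rand_dna(3200)
        from mobilomics.insertion_sequences import CandidateIS

        candidate = CandidateIS(
            "G1", "chr_G1",
            GeneFeature("t", "CDS", 1000, 2200, "+", "transposase", "M" * 399),
            0, cand_seq,
        )
        copies = [
            ISCopy("G1", "chr_G1", 0, 3200, "+", 1.0, query_start=0, query_end=3200),
            ISCopy("G2", "chr_G2", 0, 700, "+", 0.95, query_start=0, query_end=700),
            ISCopy("G3", "chr_G3", 0, 690, "+", 0.95, query_start=2500, query_end=3200),
        ]
        with pytest.raises(AmbiguousBoundariesError):
            delimit_element(candidate, copies)


# ---------------------------------------------------------------------------
# Census / disruption / composites on the default suite (planted truth)
# ---------------------------------------------------------------------------

class TestSuiteRecovery:
    def test_census_equals_planted_copy_counts(self, suite, is_results):
        genomes, ledger = suite
        full = is_results["full"]
        library = is_results["library"]
        assert len(library) == len(ledger.is_elements)
        by_len = {v["length"]: k for k, v in ledger.is_elements.items()}
        planted = collections.Counter(
            (c["element"], c["genome"]) for c in ledger.is_copies
        )
        for e in library:
            truth_name = by_len[e.length]
            for g in genomes:
                assert int(full.loc[e.name, g.strain]) == planted.get(
                    (truth_name, g.strain), 0
                )
        assert is_results["partial"].to_numpy().sum() == 0
        # census row sums are the total confirmed loci
        assert (full.to_numpy() >= 0).all()
        assert full.to_numpy().sum() == len(ledger.is_copies)

    def test_copy_boundaries_within_5bp(self, suite, is_results):
        _, ledger = suite
        detected = [
            (c.genome, c.start, c.end)
            for name in is_results["copies"]
            for c in is_results["copies"][name]
        ]
        planted = [(c["genome"], c["start"], c["end"]) for c in ledger.is_copies]
        assert match_intervals(planted, detected, tol=5) == len(planted)
        assert len(detected) == len(planted)  # precision: nothing extra

    def test_disruption_calls_equal_planted(self, suite, is_results):
        genomes, ledger = suite
        all_copies = [c for n in is_results["copies"] for c in is_results["copies"][n]]
        records = detect_gene_disruption(all_copies, genomes)
        expected = {
            (c["genome"], c["disrupted_locus"])
            for c in ledger.is_copies
            if c["disrupted_locus"]
        }
        assert {(r.genome, r.locus_tag) for r in records} == expected
        # disruption calls are a subset of confirmed copies
        copy_keys = {(c.genome, c.start, c.end) for c in all_copies}
        assert all((r.genome, r.copy_start, r.copy_end) in copy_keys for r in records)

    def test_composites_equal_planted(self, suite, is_results):
        genomes, ledger = suite
        all_copies = [c for n in is_results["copies"] for c in is_results["copies"][n]]
        comps = detect_composite_transposons(
            all_copies, genomes, {e.name: e for e in is_results["library"]}
        )
        got = [(c.left.genome, c.cargo_start, c.cargo_end, tuple(sorted(c.cargo_genes))) for c in comps]
        want = [
            (c["genome"], c["cargo_start"], c["cargo_end"], tuple(sorted(c["cargo_genes"])))
            for c in ledger.composites
        ]
        assert got == want


# ---------------------------------------------------------------------------
# Composite thresholds on constructed elements
# ---------------------------------------------------------------------------

def _element_pair(tpase_identity: float, ir_identity: float, rng):
    prot = "M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=299))
    k = round((1 - tpase_identity) * 300)
    s = list(prot)
    for pos in rng.choice(300, size=k, replace=False):
        s[pos] = "ACDEFGHIKLMNPQRSTVWY"[(ord(s[pos]) + 3) % 20]
    prot2 = "".join(s)
    ir = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
    ir2 = mutate(ir, round((1 - ir_identity) * 30), rng)
    e1 = ISElement("EL", "G", ("G", "a"), prot, (0, 1200), "A" * 1200, ir, revcomp(ir))
    e2 = ISElement("ER", "G", ("G", "b"), prot2, (0, 1200), "C" * 1200, ir2, revcomp(ir2))
    return e1, e2


class TestCompositeThresholds:
    def _copies(self):
        return [
            ISCopy("G1", "chr_G1", 10_000, 11_200, "+", 1.0, element_name="EL"),
            ISCopy("G1", "chr_G1", 20_000, 21_200, "+", 1.0, element_name="ER"),
        ]

    def _genome(self):
        feats = [
            GeneFeature(f"c{i}", "CDS", 12_000 + 800 * i, 12_600 + 800 * i, "+", "iron ABC transporter permease", "M" * 50)
            for i in range(8)
        ]
        return _genome("ACGT" * 8000, feats)

    def test_divergent_pair_like_the_iron_transposon_passes(self):
        rng = np.random.default_rng(55)
        e1, e2 = _element_pair(0.65, 0.732, rng)  # 65% aa, 73.2% IR
        comps = detect_composite_transposons(
            self._copies(), [self._genome()], {"EL": e1, "ER": e2}
        )
        assert len(comps) == 1
        c = comps[0]
        assert c.transposase_identity >= 0.60 and c.ir_cross_identity >= 0.60
        assert len(c.cargo_genes) == 8

    def test_too_divergent_transposases_fail(self):
        rng = np.random.default_rng(56)
        e1, e2 = _element_pair(0.40, 0.90, rng)
        assert (
            detect_composite_transposons(self._copies(), [self._genome()], {"EL": e1, "ER": e2})
            == []
        )

    def test_isolated_single_copy_yields_nothing(self):
        rng = np.random.default_rng(57)
        e1, e2 = _element_pair(0.9, 0.9, rng)
        copies = self._copies()[:1]
        assert detect_composite_transposons(copies, [self._genome()], {"EL": e1, "ER": e2}) == []

    def test_cargo_gap_limit(self):
        rng = np.random.default_rng(58)
        e1, e2 = _element_pair(0.9, 0.9, rng)
        copies = self._copies()
        copies[1].start, copies[1].end = 40_000, 41_200  # gap > max_cargo
        assert (
            detect_composite_transposons(
                copies, [self._genome()], {"EL": e1, "ER": e2}, max_cargo=20_000
            )
            == []
        )
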