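"""Ortholog clustering and pan/core statistics against brute-force oracles."""

from __future__ import annotations

import warnings
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from mobilomics.genomes import GeneFeature, Genome, Replicon
from mobilomics.pangenome import (
    cluster_proteins,
    k_spectrum,
    orfan_positions,
    orfans_from_matrix,
    pan_core_curves,
    presence_matrix,
)
from mobilomics.align import protein_identity_coverage

AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_prot(rng, lo=40, hi=90):
    n = int(rng.integers(lo, hi))
    return "M" + "".join(AA[i] for i in rng.integers(0, 20, size=n - 1))


def mutate_prot(p, k, rng):
    s = list(p)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = AA[(AA.index(s[pos]) + 1 + int(rng.integers(0, 18))) % 20]
    return "".join(s)


def genome_of(strain, proteins):
    feats = []
    pos = 100
    for i, p in enumerate(proteins):
        ln = len(p) * 3 + 3
        feats.append(GeneFeature(f"{strain}_{i:03d}", "CDS", pos, pos + ln, "+", "protein", p))
        pos += ln + 150
    return Genome(strain, "Sp", [Replicon(f"c_{strain}", "ACGT" * ((pos + 400) // 4), "circular", feats)])


def greedy_oracle(named_proteins, min_identity=0.60, min_coverage=0.75):
    """Independent greedy clustering from the all-pairs threshold graph."""
    order = sorted(named_proteins, key=lambda t: (-len(t[2]), t[1], t[0]))
    passes = {}
    for i, a in enumerate(order):
        for b in order[: i]:
            ident, cov = protein_identity_coverage(a[2], b[2])
            passes[(a[:2], b[:2])] = ident >= min_identity and cov >= min_coverage
    centroids: list = []
    assign = {}
    for item in order:
        for c in centroids:
            if passes[(item[:2], c[:2])]:
                assign[item[:2]] = c[:2]
                break
        else:
            centroids.append(item)
            assign[item[:2]] = item[:2]
    return assign


class TestClustering:
    def test_identical_proteins_cluster_across_genomes(self):
        rng = np.random.default_rng(1)
        prots = [rand_prot(rng) for _ in range(3)]
        g1, g2 = genome_of("A", prots), genome_of("B", prots)
        clusters = cluster_proteins([g1, g2])
        assert len(clusters) == 3
        assert all(len(c.members) == 2 for c in clusters)

    def test_identity_threshold_splits_at_60_percent(self):
        rng = np.random.default_rng(2)
        base = rand_prot(rng, 100, 101)  # 100 aa
        below = mutate_prot(base, 41, rng)  # 59% conserved
        above = mutate_prot(base, 39, rng)  # 61% conserved
        # guard: the constructed pairs straddle the threshold
        id_below = protein_identity_coverage(base, below)[0]
        id_above = protein_identity_coverage(base, above)[0]
        assert id_below < 0.60 < id_above
        c_below = cluster_proteins([genome_of("A", [base]), genome_of("B", [below])])
        c_above = cluster_proteins([genome_of("A", [base]), genome_of("B", [above])])
        assert len(c_below) == 2 and len(c_above) == 1

    def test_coverage_threshold_on_longer_sequence(self):
        rng = np.random.default_rng(3)
        base = rand_prot(rng, 100, 101)
        prefix = base[:70]  # identity 1.0, coverage 0.70 < 0.75
        clusters = cluster_proteins([genome_of("A", [base]), genome_of("B", [prefix])])
        assert len(clusters) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(100 + seed)
        named = []
        families = [rand_prot(rng, 50, 90) for _ in range(8)]
        for gi, strain in enumerate(["GA", "GB", "GC", "GD"]):
            prots = []
            for j in range(10):
                fam = families[int(rng.integers(0, 8))]
                k = int(rng.integers(0, max(2, len(fam) // 3)))
                prots.append(mutate_prot(fam, k, rng))
            for li, p in enumerate(prots):
                named.append((strain, f"{strain}_{li:03d}", p))
        genomes = [
            genome_of(strain, [p for s, _, p in named if s == strain])
            for strain in ["GA", "GB", "GC", "GD"]
        ]
        clusters = cluster_proteins(genomes)
        got = {}
        for c in clusters:
            for m in c.members:
                got[m] = c.centroid
        oracle = greedy_oracle(named)
        assert got == oracle

    def test_partition_and_input_order_invariance(self):
        rng = np.random.default_rng(4)
        prots = [rand_prot(rng) for _ in range(6)]
        g1, g2 = genome_of("A", prots[:4]), genome_of("B", prots[2:])
        c12 = cluster_proteins([g1, g2])
        c21 = cluster_proteins([g2, g1])
        all_members = [m for c in c12 for m in c.members]
        assert len(all_members) == len(set(all_members)) == 8  # partition
        assert {frozenset(c.members) for c in c12} == {frozenset(c.members) for c in c21}


class TestMatrixAndCurves:
    def test_presence_matrix_tabulation(self):
        rng = np.random.default_rng(5)
        p = rand_prot(rng)
        q = rand_prot(rng)
        g1 = genome_of("A", [p, q, q])  # paralogous duplicate
        g2 = genome_of("B", [p])
        clusters = cluster_proteins([g1, g2])
        m = presence_matrix(clusters, [g1, g2])
        assert m.shape == (2, 2)
        assert m.to_numpy().tolist() in ([[1, 1], [1, 0]], [[1, 0], [1, 1]])

    def test_single_genome_pan_equals_core(self):
        m = pd.DataFrame({"A": [1, 1, 1]}, index=["c1", "c2", "c3"])
        pan, core = pan_core_curves(m)
        assert pan["mean"].iloc[0] == core["mean"].iloc[0] == 3

    def test_identical_genomes_give_flat_curves(self):
        m = pd.DataFrame(np.ones((5, 4), dtype=int), columns=list("ABCD"))
        pan, core = pan_core_curves(m)
        assert (pan["mean"] == 5).all() and (core["mean"] == 5).all()

    def test_exhaustive_orderings_match_manual_enumeration(self):
        rng = np.random.default_rng(6)
        M = (rng.random((12, 5)) < 0.6).astype(int)
        M[M.sum(axis=1) == 0, 0] = 1
        m = pd.DataFrame(M, columns=list("ABCDE"))
        pan, core = pan_core_curves(m)  # n! = 120 <= exhaustive limit
        # manual enumeration oracle
        pans = np.zeros((120, 5)), np.zeros((120, 5))
        for r, perm in enumerate(permutations(range(5))):
            u = np.zeros(12, dtype=bool)
            i = np.ones(12, dtype=bool)
            for t, gi in enumerate(perm):
                u |= M[:, gi].astype(bool)
                i &= M[:, gi].astype(bool)
                pans[0][r, t] = u.sum()
                pans[1][r, t] = i.sum()
        assert np.allclose(pan["mean"].to_numpy(), pans[0].mean(axis=0))
        assert np.allclose(core["mean"].to_numpy(), pans[1].mean(axis=0))

    @pytest.mark.parametrize("seed", range(5))
    def test_monotonicity_over_random_matrices(self, seed):
        rng = np.random.default_rng(30 + seed)
        M = (rng.random((40, 6)) < rng.uniform(0.2, 0.9)).astype(int)
        M[M.sum(axis=1) == 0, 0] = 1
        m = pd.DataFrame(M, columns=[f"g{i}" for i in range(6)])
        pan, core = pan_core_curves(m, n_orderings=30, seed=seed)
        for col in ("mean", "min", "max"):
            assert (np.diff(pan[col].to_numpy()) >= 0).all()
            assert (np.diff(core[col].to_numpy()) <= 0).all()
        spec = k_spectrum(m)
        assert spec.sum() == M.shape[0] == pan["mean"].iloc[-1]

    def test_k_spectrum_is_row_sum_histogram(self):
        m = pd.DataFrame([[1, 1, 1], [1, 0, 0]], columns=list("ABC"))
        spec = k_spectrum(m)
        assert spec.to_dict() == {1: 1, 2: 0, 3: 1}
        rng = np.random.default_rng(7)
        M = (rng.random((60, 4)) < 0.5).astype(int)
        M[M.sum(axis=1) == 0, 0] = 1
        spec = k_spectrum(pd.DataFrame(M, columns=list("ABCD")))
        sums = M.sum(axis=1)
        assert spec.to_dict() == {k: int((sums == k).sum()) for k in range(1, 5)}


class TestOrfanPositions:
    def _genome_with_orfans(self, positions, length=200_000):
        feats = [
            GeneFeature(f"o{i}", "CDS", p, p + 300, "+", "hypothetical protein", "M" + "A" * 99)
            for i, p in enumerate(positions)
        ]
        g = Genome("S", "Sp", [Replicon("c", "A" * length, "circular", feats)])
        return g, [("S", f.locus_tag) for f in feats]

    def test_single_window_peak(self):
        g, orfans = self._genome_with_orfans([150_100, 150_900, 151_700])
        prof = orfan_positions([g], orfans, window=50_000)["S"]
        assert prof.loc[150_000] == 3 and prof.sum() == 3

    def test_uniform_orfans_flat_profile(self):
        g, orfans = self._genome_with_orfans(list(range(5000, 200_000, 10_000)))
        prof = orfan_positions([g], orfans, window=50_000)["S"]
        assert prof.sum() == len(orfans)
        assert prof.max() - prof.min() <= 1

    def test_missing_locus_is_consistency_error(self):
        g, orfans = self._genome_with_orfans([1000])
        with pytest.raises(ValueError):
            orfan_positions([g], orfans + [("S", "nope")], window=50_000)

    def test_planted_hotspot_recovered_on_suite(self, recipients, pan_profile, suite):
        _, ledger = suite
        strain = "RA-05"  # no island or cargo confounders in this genome
        prof = orfan_positions(
            recipients, pan_profile.orfans, window=50_000
        )[strain]
        peak_window = int(prof.idxmax())
        center = ledger.orfan_hotspots[strain]["center"]
        assert peak_window <= center < peak_window + 50_000


def test_suite_spectrum_matches_planted_truth(recipients, pan_profile, suite):
    """On the default synthetic suite the recovered pan-genome equals the
    planted one: k-spectrum, core count, and ORFan membership."""
    _, ledger = suite
    strains = [g.strain for g in recipients]
    expected = ledger.expected_spectrum(strains)
    got = {int(k): int(v) for k, v in pan_profile.spectrum.items() if v}
    assert got == expected
    in_set = set(strains)
    expected_members = {
        frozenset((s, l) for s, l in members if s in in_set)
        for members in ledger.clusters.values()
        if any(s in in_set for s, _ in members)
    }
    got_members = {frozenset(c.members) for c in pan_profile.clusters}
    assert got_members == expected_members
    orfans = orfans_from_matrix(pan_profile.matrix, pan_profile.clusters)
    expected_orfans = sum(
        sum(1 for s, _ in members if s in in_set)
        for members in ledger.clusters.values()
        if len({s for s, _ in members if s in in_set}) == 1
    )
    assert len(orfans) == expected_orfans
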