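"""Ortholog clustering and pan/core-genome statistics.

Proteins from a genome set are clustered into orthologous groups by greedy
centroid clustering: proteins are visited in a fixed order (length
descending, ties by locus tag then genome) and each joins the first existing
centroid it matches at >= 60% identity with alignment covering >= 75% of the
longer protein, else founds a new cluster. The order is fixed because greedy
clustering is order-sensitive; fixing it makes the partition deterministic
and invariant to input file order.

From the cluster-by-genome presence/absence matrix the module derives gene
accumulation curves (pan and core genome size as genomes are added, averaged
over random orderings, exhaustively enumerated for small sets), the
k-spectrum (number of clusters present in exactly k genomes), the ORFan set
(clusters private to a single genome, k = 1), and the positional density of
ORFans along ori-normalized chromosome coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import edlib
import numpy as np
import pandas as pd

from .align import protein_identity_coverage
from .genomes import Genome

__all__ = [
    "OrthologCluster",
    "PanGenomeProfile",
    "cluster_proteins",
    "presence_matrix",
    "pan_core_curves",
    "k_spectrum",
    "orfans_from_matrix",
    "orfan_positions",
    "build_profile",
]

EXHAUSTIVE_ORDERING_LIMIT = 5000  # enumerate all n! orderings when feasible


@dataclass
class OrthologCluster:
    cluster_id: str
    centroid: tuple[str, str]  # (genome strain, locus_tag)
    members: list[tuple[str, str]] = field(default_factory=list)

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class PanGenomeProfile:
    clusters: list[OrthologCluster]
    matrix: pd.DataFrame  # clusters x genomes, 0/1
    pan_curve: pd.DataFrame
    core_curve: pd.DataFrame
    spectrum: pd.Series  # k -> cluster count
    orfans: list[tuple[str, str]]


def cluster_proteins(
    genomes: list[Genome],
    min_identity: float = 0.60,
    min_coverage: float = 0.75,
) -> list[OrthologCluster]:
    """Greedy centroid clustering of all translated CDS in the genome set.

    CDS without a translation are skipped (with a summary warning). The
    result is a partition: every protein belongs to exactly one cluster.
    """
    proteins: list[tuple[str, str, str]] = []  # (strain, locus_tag, translation)
    skipped = 0
    for g in genomes:
        n_cds = 0
        for _, f in g.all_features():
            if f.kind != "CDS":
                continue
            n_cds += 1
            if f.translation:
                proteins.append((g.strain, f.locus_tag, f.translation))
            else:
                skipped += 1
        if n_cds == 0:
            raise ValueError(f"genome {g.strain} has no CDS")
    if skipped:
        warnings.warn(f"cluster_proteins: skipped {skipped} CDS without translation")
    proteins.sort(key=lambda t: (-len(t[2]), t[1], t[0]))

    centroids: list[tuple[str, str, str]] = []
    memberships: list[list[tuple[str, str]]] = []
    # A pair can only reach the thresholds if the shorter protein is at least
    # min_identity * min_coverage of the longer one (matches <= len(shorter),
    # columns >= coverage span >= min_coverage * len(longer)).
    ratio_floor = min_identity * min_coverage
    for strain, locus, seq in proteins:
        placed = False
        for ci, (_, _, cseq) in enumerate(centroids):
            lo, hi = sorted((len(seq), len(cseq)))
            if lo < ratio_floor * hi:
                continue
            # admissible prune: in any alignment, matches <= (|a|+|b|-d)/2
            # with d the minimum edit distance, while a passing pair needs
            # matches >= min_identity * min_coverage * |longer|.
            d = edlib.align(seq, cseq, mode="NW", task="distance")["editDistance"]
            if (lo + hi - d) / 2 < ratio_floor * hi:
                continue
            ident, cov = protein_identity_coverage(seq, cseq)
            if ident >= min_identity and cov >= min_coverage:
                memberships[ci].append((strain, locus))
                placed = True
                break
        if not placed:
            centroids.append((strain, locus, seq))
            memberships.append([(strain, locus)])
    clusters = []
    width = max(4, len(str(len(centroids))))
    for i, ((strain, locus, _), members) in enumerate(zip(centroids, memberships)):
        clusters.append(OrthologCluster(f"OG{i:0{width}d}", (strain, locus), members))
    return clusters


def presence_matrix(clusters: list[OrthologCluster], genomes: list[Genome]) -> pd.DataFrame:
    """Binary clusters x genomes matrix; paralogs still yield a single 1."""
    strains = [g.strain if isinstance(g, Genome) else str(g) for g in genomes]
    data = np.zeros((len(clusters), len(strains)), dtype=int)
    col = {s: j for j, s in enumerate(strains)}
    for i, c in enumerate(clusters):
        for strain, _ in c.members:
            if strain in col:
                data[i, col[strain]] = 1
    return pd.DataFrame(data, index=[c.cluster_id for c in clusters], columns=strains)


def pan_core_curves(
    matrix: pd.DataFrame, n_orderings: int = 100, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene accumulation curves over random genome orderings.

    For each ordering, the pan value at step t is the size of the union of
    the first t genomes' cluster sets and the core value the size of their
    intersection. Means and ranges over orderings are returned; all n!
    orderings are enumerated when that is at most EXHAUSTIVE_ORDERING_LIMIT.
    """
    if n_orderings < 1:
        raise ValueError("n_orderings must be >= 1")
    M = matrix.to_numpy(dtype=bool)
    n = M.shape[1]
    if math.factorial(n) <= EXHAUSTIVE_ORDERING_LIMIT:
        orderings = [list(p) for p in permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        orderings = [list(rng.permutation(n)) for _ in range(n_orderings)]
    pan = np.empty((len(orderings), n), dtype=int)
    core = np.empty((len(orderings), n), dtype=int)
    for r, order in enumerate(orderings):
        acc_union = np.zeros(M.shape[0], dtype=bool)
        acc_inter = np.ones(M.shape[0], dtype=bool)
        for t, gi in enumerate(order):
            acc_union |= M[:, gi]
            acc_inter &= M[:, gi]
            pan[r, t] = int(acc_union.sum())
            core[r, t] = int(acc_inter.sum())
    steps = np.arange(1, n + 1)

    def _summary(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genomes": steps,
                "mean": a.mean(axis=0),
                "min": a.min(axis=0),
                "max": a.max(axis=0),
            }
        ).set_index("genomes")

    return _summary(pan), _summary(core)


def k_spectrum(matrix: pd.DataFrame) -> pd.Series:
    """Count of clusters present in exactly k genomes, k = 1..n."""
    n = matrix.shape[1]
    sums = matrix.to_numpy(dtype=bool).sum(axis=1)
    counts = {k: int((sums == k).sum()) for k in range(1, n + 1)}
    return pd.Series(counts, name="clusters").rename_axis("k")


def orfans_from_matrix(
    matrix: pd.DataFrame, clusters: list[OrthologCluster]
) -> list[tuple[str, str]]:
    """Members of clusters private to a single genome (k = 1)."""
    sums = matrix.to_numpy(dtype=bool).sum(axis=1)
    by_id = {c.cluster_id: c for c in clusters}
    out = []
    for cid, k in zip(matrix.index, sums):
        if k == 1:
            out.extend(by_id[cid].members)
    return out


def orfan_positions(
    genomes: list[Genome],
    orfans: list[tuple[str, str]],
    window: int = 50_000,
) -> dict[str, pd.Series]:
    """Sliding-window ORFan counts along each ori-normalized chromosome.

    Windows tile the chromosome; each ORFan gene is counted in the window
    containing its midpoint. Genomes are expected to be ori-normalized so
    offsets are comparable across strains.
    """
    by_strain: dict[str, list[str]] = {}
    for strain, locus in orfans:
        by_strain.setdefault(strain, []).append(locus)
    out: dict[str, pd.Series] = {}
    for g in genomes:
        chrom = g.chromosome
        n = len(chrom.sequence)
        n_windows = max(1, -(-n // window))
        counts = np.zeros(n_windows, dtype=int)
        loci = {f.locus_tag: f for f in chrom.features}
        plasmid_loci = {f.locus_tag for r in g.plasmids for f in r.features}
        for locus in by_strain.get(g.strain, []):
            f = loci.get(locus)
            if f is None:
                if locus in plasmid_loci:
                    continue  # plasmid genes have no chromosome offset
                raise ValueError(f"ORFan locus {locus} not found in genome {g.strain}")
            counts[f.midpoint(n) // window] += 1
        idx = pd.Index(np.arange(n_windows) * window, name="window_start")
        out[g.strain] = pd.Series(counts, index=idx, name="orfans")
    return out


def build_profile(
    genomes: list[Genome],
    min_identity: float = 0.60,
    min_coverage: float = 0.75,
    n_orderings: int = 100,
    seed: int = 0,
) -> PanGenomeProfile:
    """Cluster, tabulate and summarize a genome set in one call."""
    clusters = cluster_proteins(genomes, min_identity, min_coverage)
    matrix = presence_matrix(clusters, genomes)
    pan, core = pan_core_curves(matrix, n_orderings=n_orderings, seed=seed)
    spectrum = k_spectrum(matrix)
    orfans = orfans_from_matrix(matrix, clusters)
    return PanGenomeProfile(clusters, matrix, pan, core, spectrum, orfans)
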