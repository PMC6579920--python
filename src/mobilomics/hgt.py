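"""Cross-species homology blocks (putative HGT) and plasmid integration maps.

A horizontally transferred region is operationalized exactly as in manual
comparative screens: a nucleotide alignment block between a recipient genome
and a genome carrying a *different* species label that is longer than
2,000 bp and above 90% identity. Raw blocks are filtered against the
thresholds first, then merged per partner when separated by at most
``merge_gap`` on the recipient, so both raw and merged lengths are
reportable. Genes overlapping a region are attached with their coarse
functional category for downstream tabulation.

Plasmid integration mapping projects alignment blocks between a plasmid and
a set of genomes onto plasmid coordinates and reports the covered fraction
per genome together with the plasmid features left uncovered (for example,
replication genes absent from the integrated fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentBlock, KmerIndex, local_search
from .genomes import GeneFeature, Genome, Replicon, classify_product

__all__ = [
    "HGTRegion",
    "PlasmidIntegrationMap",
    "cross_species_regions",
    "classify_hgt_regions",
    "map_plasmid_integration",
]


@dataclass
class HGTRegion:
    recipient: str
    recipient_replicon: str
    start: int
    end: int
    partner: str  # partner strain
    partner_species: str
    partner_replicon: str
    partner_start: int
    partner_end: int
    identity: float  # length-weighted over member blocks
    genes: list[tuple[str, str, str]] = field(default_factory=list)  # locus, product, category
    label: str = ""
    raw_blocks: list[AlignmentBlock] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlasmidIntegrationMap:
    plasmid_id: str
    genome: str
    covered_intervals: list[tuple[int, int]]
    coverage_fraction: float
    missing_features: list[GeneFeature] = field(default_factory=list)

    @property
    def n_fragments(self) -> int:
        return len(self.covered_intervals)


def _merge_intervals(ivals: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def cross_species_regions(
    recipient: Genome,
    partners: list[Genome],
    min_length: int = 2000,
    min_identity: float = 0.90,
    merge_gap: int = 1000,
) -> list[HGTRegion]:
    """Putative HGT regions of ``recipient`` against other-species partners.

    Thresholds are strict, matching the verbal rule "larger than
    ``min_length`` and more than ``min_identity``": a 2,000 bp block or a
    block at exactly 90% identity does not qualify. Partners sharing the
    recipient's species label are excluded.
    """
    regions: list[HGTRegion] = []
    rchrom = recipient.chromosome
    for partner in partners:
        if partner.species_label == recipient.species_label:
            import warnings

            warnings.warn(
                f"cross_species_regions: partner {partner.strain} shares species "
                f"label {partner.species_label!r}; excluded"
            )
            continue
        for prep in partner.replicons:
            blocks = local_search(
                rchrom.sequence,
                prep,
                min_length=max(500, min_length // 4),
                min_identity=min_identity,
                query_id=rchrom.replicon_id,
            )
            kept = [
                b for b in blocks if b.length > min_length and b.identity > min_identity
            ]
            if not kept:
                continue
            for strand in ("+", "-"):
                sel = sorted(
                    (b for b in kept if b.strand == strand), key=lambda b: b.q_start
                )
                if not sel:
                    continue
                group: list[AlignmentBlock] = []
                for b in sel + [None]:  # type: ignore[list-item]
                    if group and (b is None or b.q_start - group[-1].q_end > merge_gap):
                        start = min(x.q_start for x in group)
                        end = max(x.q_end for x in group)
                        p_start = min(x.s_start for x in group)
                        p_end = max(x.s_end for x in group)
                        wsum = sum(x.identity * x.length for x in group)
                        lsum = sum(x.length for x in group)
                        genes = [
                            (f.locus_tag, f.product, classify_product(f.product))
                            for f in rchrom.features
                            if f.kind == "CDS" and f.start < end and f.end > start
                        ]
                        regions.append(
                            HGTRegion(
                                recipient=recipient.strain,
                                recipient_replicon=rchrom.replicon_id,
                                start=start,
                                end=end,
                                partner=partner.strain,
                                partner_species=partner.species_label,
                                partner_replicon=prep.replicon_id,
                                partner_start=p_start,
                                partner_end=p_end,
                                identity=wsum / lsum,
                                genes=genes,
                                raw_blocks=list(group),
                            )
                        )
                        group = []
                    if b is not None:
                        group.append(b)
    regions.sort(key=lambda r: (r.recipient, r.start, r.partner))
    return regions


def classify_hgt_regions(regions: list[HGTRegion]) -> pd.DataFrame:
    """Per-category gene counts and percentages over all region genes."""
    counts: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for r in regions:
        for locus, _product, category in r.genes:
            key = (r.recipient, locus)
            if key in seen:
                continue  # a gene may sit in regions against several partners
            seen.add(key)
            counts[category] = counts.get(category, 0) + 1
    total = sum(counts.values())
    rows = [
        {"category": c, "genes": n, "percent": 100.0 * n / total if total else 0.0}
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "genes", "percent"])


def map_plasmid_integration(
    plasmid: Replicon,
    genomes: list[Genome],
    min_identity: float = 0.95,
    min_block: int = 500,
) -> dict[str, PlasmidIntegrationMap]:
    """Coverage of a plasmid by homologous segments in each genome.

    Alignment blocks are projected onto plasmid coordinates and merged;
    the covered fraction and the plasmid features with no covered overlap
    are reported per genome.
    """
    out: dict[str, PlasmidIntegrationMap] = {}
    n = len(plasmid.sequence)
    for g in genomes:
        ivals: list[tuple[int, int]] = []
        for rep in g.replicons:
            if rep.replicon_id == plasmid.replicon_id:
                continue
            blocks = local_search(
                plasmid.sequence,
                rep,
                min_length=min_block,
                min_identity=min_identity,
                query_id=plasmid.replicon_id,
            )
            ivals.extend((b.q_start, b.q_end) for b in blocks if b.length >= min_block)
        merged = _merge_intervals(ivals, gap=0)
        covered = sum(e - s for s, e in merged)
        missing = []
        for f in plasmid.features:
            ov = sum(min(f.end, e) - max(f.start, s) for s, e in merged if min(f.end, e) > max(f.start, s))
            if ov < 0.5 * f.length:
                missing.append(f)
        out[g.strain] = PlasmidIntegrationMap(
            plasmid_id=plasmid.replicon_id,
            genome=g.strain,
            covered_intervals=merged,
            coverage_fraction=covered / n,
            missing_features=missing,
        )
    return out
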