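"""Synthetic annotated genome sets with a planted-truth ledger.

The generator emulates the statistical structure of a set of related
bacterial genomes as seen by identity-based mobilome analysis:

* a shared core gene pool plus partially shared shell genes and per-genome
  ORFans, with small within-cluster nucleotide divergence;
* multi-copy insertion sequences with terminal inverted repeats, a fraction
  of copies inserted inside genes (the host CDS is split into two
  translation-less fragments, as annotation pipelines do for pseudogenes);
* a composite transposon: two copies of one IS family flanking a cargo of
  iron-uptake genes;
* cross-species HGT blocks copied from donor genomes of other species at a
  controlled nucleotide identity (substitution count is exact, so the
  realized identity matches the target);
* an integrative and conjugative element (ICE)-like island integrated at the
  3' end of a host gene, flanked by a duplicated direct repeat (att site) and
  carrying a roster of signature genes;
* partial plasmid integration: fragments of a donor plasmid dispersed in a
  recipient chromosome.

Every planted structure is recorded in a :class:`TruthLedger` whose
coordinates track all subsequent edits, and genomes are returned already
rotated to the ori convention (position 0 upstream of dnaA) with ledger
coordinates in the same frame. Same-family IS copies are placed with a
minimum mutual spacing larger than the composite-transposon cargo window,
mirroring the sparsity of real IS copies relative to that window; without
it, "two related copies within the cargo window" would be true of almost
every copy pair on a short synthetic chromosome and composite calling would
be vacuous.

Intergenic background is i.i.d. uniform with configurable G+C (default
62.7%, the species range of the study system). There is no codon or
phylogenetic model: the detection methods exercised here are identity-based,
not composition-based.

Determinism: all randomness flows from per-subsystem children of one seed,
so identical configurations yield byte-identical genomes and ledgers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from Bio.Seq import Seq

from ._seq import revcomp
from .genomes import (
    GeneFeature,
    Genome,
    Replicon,
    _rotate_replicon,
    find_dnaa,
    ori_rotation_offset,
)

__all__ = [
    "SimulationError",
    "GenomePoolSpec",
    "ISSpec",
    "CompositeSpec",
    "HgtSpec",
    "IceSpec",
    "PlasmidSpec",
    "SimulationConfig",
    "TruthLedger",
    "simulate_genome_set",
    "default_suite",
]

STOPS = ("TAA", "TAG", "TGA")
AA20 = "ACDEFGHIKLMNPQRSTVWY"
CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

NEUTRAL_PRODUCTS = (
    "ABC transporter ATP-binding protein",
    "MFS transporter",
    "amino acid permease",
    "alcohol dehydrogenase",
    "aspartate aminotransferase",
    "glutamine synthetase",
    "serine protease",
    "aminopeptidase",
    "sugar kinase",
    "enoyl-CoA hydratase",
    "GntR family transcriptional regulator",
    "TetR family transcriptional regulator",
    "cold shock protein",
    "universal stress protein",
    "catalase",
    "DNA gyrase subunit A",
    "DNA ligase",
    "ribosomal protein L3",
    "tRNA ligase",
    "50S ribosomal protein L2",
    "iron ABC transporter substrate-binding protein",
    "phosphoglycerate mutase",
    "citrate synthase",
    "acyl-CoA dehydrogenase",
)

IRON_CARGO_PRODUCTS = (
    "iron ABC transporter permease",
    "iron ABC transporter ATP-binding protein",
    "iron ABC transporter substrate-binding protein",
    "siderophore biosynthesis protein",
    "AraC family transcriptional regulator",
    "iron siderophore uptake protein",
)

ICE_SIGNATURE_PRODUCTS = (
    "site-specific integrase",
    "integrase",
    "excisionase",
    "replicative DNA helicase",
    "DNA primase",
    "DNA polymerase III subunit alpha",
    "conjugal transfer protein",
    "conjugal transfer protein TrbL",
    "chromosome partitioning protein ParB",
    "type VI secretion protein",
    "single-stranded DNA-binding protein",
)

DNAA_PRODUCT = "chromosomal replication initiator protein DnaA"


class SimulationError(ValueError):
    """Infeasible configuration or failed structure placement."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomePoolSpec:
    strains: list[str]
    species: str
    core_genes: int = 100
    shell_genes: int = 0
    orfans_per_genome: int = 0
    chromosome_length: int = 450_000
    divergence: float = 0.01  # within-cluster nucleotide substitution rate
    orfan_hotspot_fraction: float | None = None  # chromosome position fraction
    orfan_hotspot_share: float = 0.6  # share of ORFans packed at the hotspot


@dataclass
class ISSpec:
    name: str
    family: str = "IS3"
    element_length: int = 1200
    ir_length: int = 16
    copies_per_genome: dict[str, tuple[int, int]] = field(default_factory=dict)
    in_gene_fraction: float = 0.0
    copy_divergence: float = 0.0  # per-copy substitution rate vs consensus


@dataclass
class CompositeSpec:
    strain: str
    is_name: str
    cargo_products: tuple[str, ...] = IRON_CARGO_PRODUCTS


@dataclass
class HgtSpec:
    recipient: str
    donor: str
    length: int = 8000
    identity: float = 0.97
    label: str = ""
    expect_detected: bool = True


@dataclass
class IceSpec:
    strain: str
    att: str = "AGAAGTCCCAGT"
    signature_products: tuple[str, ...] = ICE_SIGNATURE_PRODUCTS
    n_filler: int = 20


@dataclass
class PlasmidSpec:
    donor: str
    recipient: str
    # fragments of the integrated fraction stay individually below the 2 kb
    # HGT length rule, mirroring plasmid remnants too short to call as HGT
    length: int = 6000
    integrated_fraction: float = 0.80
    n_fragments: int = 3


@dataclass
class SimulationConfig:
    recipients: GenomePoolSpec
    donors: list[GenomePoolSpec] = field(default_factory=list)
    is_specs: list[ISSpec] = field(default_factory=list)
    composites: list[CompositeSpec] = field(default_factory=list)
    hgt: list[HgtSpec] = field(default_factory=list)
    ices: list[IceSpec] = field(default_factory=list)
    plasmids: list[PlasmidSpec] = field(default_factory=list)
    gc: float = 0.627
    protein_length: tuple[int, int] = (60, 180)
    is_spacing: int = 26_000  # min same-family copy spacing (> cargo window)
    seed: int = 0

    def validate(self) -> None:
        for pool in [self.recipients, *self.donors]:
            if pool.chromosome_length <= 0 or pool.core_genes <= 0:
                raise SimulationError(f"bad pool spec for {pool.strains}")
            if not 0.0 <= pool.divergence <= 0.2:
                raise SimulationError("divergence outside [0, 0.2]")
        for h in self.hgt:
            if not 0.80 <= h.identity <= 1.0:
                raise SimulationError(f"HGT identity {h.identity} outside [0.80, 1.0]")
        for s in self.is_specs:
            if not 0.0 <= s.copy_divergence <= 0.2:
                raise SimulationError("copy_divergence outside [0, 0.2]")
            if s.element_length < 2 * s.ir_length + 300:
                raise SimulationError(f"{s.name}: element too short for IRs + transposase")


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class TruthLedger:
    """Coordinates and memberships of every planted structure.

    Interval fields are half-open chromosome coordinates in the final
    (ori-rotated) frame. ``clusters`` lists the translated members of every
    planted ortholog cluster; genes later destroyed by an in-gene IS
    insertion are removed from their cluster.
    """

    genomes: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)
    is_elements: dict = field(default_factory=dict)
    is_copies: list = field(default_factory=list)
    composites: list = field(default_factory=list)
    hgt_blocks: list = field(default_factory=list)
    ices: list = field(default_factory=list)
    plasmid_integrations: list = field(default_factory=list)
    orfan_hotspots: dict = field(default_factory=dict)

    # -- cluster bookkeeping ------------------------------------------------
    def add_member(self, cluster_id: str, strain: str, locus: str) -> None:
        self.clusters.setdefault(cluster_id, []).append([strain, locus])

    def remove_member(self, strain: str, locus: str) -> None:
        for members in self.clusters.values():
            for m in list(members):
                if m[0] == strain and m[1] == locus:
                    members.remove(m)

    def expected_presence(self, strains: list[str]) -> dict[str, set[str]]:
        subset = set(strains)
        out = {}
        for cid, members in self.clusters.items():
            present = {s for s, _ in members if s in subset}
            if present:
                out[cid] = present
        return out

    def expected_spectrum(self, strains: list[str]) -> dict[int, int]:
        spec: dict[int, int] = {}
        for present in self.expected_presence(strains).values():
            k = len(present)
            spec[k] = spec.get(k, 0) + 1
        return dict(sorted(spec.items()))

    # -- coordinate maintenance ---------------------------------------------
    def _intervals(self, strain: str, replicon: str):
        """Yield (container, start_key, end_key) for every tracked interval."""
        for c in self.is_copies:
            if c["genome"] == strain and c["replicon"] == replicon:
                yield c, "start", "end"
        for c in self.composites:
            if c["genome"] == strain and c["replicon"] == replicon:
                for pre in ("left_", "right_", "cargo_"):
                    yield c, pre + "start", pre + "end"
        for h in self.hgt_blocks:
            if h["recipient"] == strain and h["recipient_replicon"] == replicon:
                yield h, "r_start", "r_end"
            if h["donor"] == strain and h["donor_replicon"] == replicon:
                yield h, "d_start", "d_end"
        for i in self.ices:
            if i["genome"] == strain and i["replicon"] == replicon:
                yield i, "start", "end"
        for p in self.plasmid_integrations:
            if p["recipient"] == strain and p["recipient_replicon"] == replicon:
                for fr in p["fragments"]:
                    yield fr, "r_start", "r_end"

    def shift(self, strain: str, replicon: str, pos: int, delta: int) -> None:
        for obj, ks, ke in self._intervals(strain, replicon):
            if obj[ks] >= pos:
                obj[ks] += delta
                obj[ke] += delta
        hs = self.orfan_hotspots.get(strain)
        if hs and hs["replicon"] == replicon and hs["center"] >= pos:
            hs["center"] += delta

    def rotate(self, strain: str, replicon: str, offset: int, length: int) -> None:
        """Apply a chromosome rotation: starts move by length-offset mod length,
        widths are preserved (no planted structure spans the rotation point)."""
        shift = (length - offset) % length
        for obj, ks, ke in self._intervals(strain, replicon):
            width = obj[ke] - obj[ks]
            obj[ks] = (obj[ks] + shift) % length
            obj[ke] = obj[ks] + width
        hs = self.orfan_hotspots.get(strain)
        if hs and hs["replicon"] == replicon:
            hs["center"] = (hs["center"] + shift) % length

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    # order A, C, G, T: G+C probability mass = gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "M" + "".join(AA20[i] for i in rng.integers(0, 20, size=n - 1))


def _orf_for(protein: str, rng: np.random.Generator) -> str:
    codons = [CODONS[a][int(rng.integers(0, len(CODONS[a])))] for a in protein]
    stop = STOPS[int(rng.integers(0, 3))]
    return "".join(codons) + stop


def _translate(dna: str) -> str:
    return str(Seq(dna).translate(table=11)).rstrip("*")


def _mutate_seq(
    seq: str,
    rng: np.random.Generator,
    rate: float = 0.0,
    exact_n: int | None = None,
    orfs: tuple[tuple[int, int, str], ...] = (),
    max_retry: int = 2000,
) -> tuple[str, int]:
    """Substitute bases; inside ORFs internal stop codons are avoided.

    Returns (mutated sequence, number of substitutions applied). With
    ``exact_n`` the substitution count is exact (needed for HGT identity
    targets); otherwise each position mutates independently at ``rate``.
    """
    s = list(seq)
    n = len(s)
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}

    def in_orf(pos: int):
        for a, b, strand in orfs:
            if a <= pos < b:
                return (a, b, strand)
        return None

    def codon_ok(pos: int) -> bool:
        o = in_orf(pos)
        if o is None:
            return True
        a, b, strand = o
        if strand == "+":
            ci = (pos - a) // 3
            codon = "".join(s[a + 3 * ci : a + 3 * ci + 3])
            if a + 3 * ci + 3 >= b:  # the stop codon itself: keep it a stop
                return codon in STOPS
            return codon not in STOPS
        # '-': codon read on the reverse complement
        off = (b - 1 - pos) // 3
        hi = b - 3 * off
        codon = revcomp("".join(s[hi - 3 : hi]))
        if hi - 3 <= a:
            return codon in STOPS
        return codon not in STOPS

    applied: set[int] = set()
    if exact_n is not None:
        want = min(exact_n, n)
        tries = 0
        while len(applied) < want and tries < max_retry + 10 * want:
            tries += 1
            pos = int(rng.integers(0, n))
            if pos in applied:
                continue
            old = s[pos]
            if old not in others:
                continue
            s[pos] = others[old][int(rng.integers(0, 3))]
            if codon_ok(pos):
                applied.add(pos)
            else:
                s[pos] = old
        return "".join(s), len(applied)
    if rate > 0:
        hits = np.nonzero(rng.random(n) < rate)[0]
        for pos in hits:
            pos = int(pos)
            old = s[pos]
            if old not in others:
                continue
            s[pos] = others[old][int(rng.integers(0, 3))]
            if codon_ok(pos):
                applied.add(pos)
            else:
                s[pos] = old
    return "".join(s), len(applied)


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass
class _GeneDef:
    cluster_id: str
    dna: str  # forward ORF (ATG..stop)
    translation: str
    product: str


def _build_chromosome(
    strain: str,
    rep_id: str,
    genes: list[_GeneDef],
    target_length: int,
    gc: float,
    rng: np.random.Generator,
    ledger: TruthLedger,
    hotspot: tuple[float, list[_GeneDef]] | None = None,
) -> Replicon:
    """Lay genes along a chromosome with random intergenic spacers.

    ``hotspot`` packs the given genes contiguously (short spacers) at the
    given position fraction; used for the ORFan positional-enrichment signal.
    """
    coding = sum(len(g.dna) for g in genes) + sum(
        len(g.dna) for g in (hotspot[1] if hotspot else [])
    )
    n_genes = len(genes) + (len(hotspot[1]) if hotspot else 0)
    free = target_length - coding - 2000  # keep a trailing feature-free tail
    if free <= 200 * n_genes:
        raise SimulationError(
            f"{strain}: {n_genes} genes do not fit in {target_length} bp"
        )
    mean_gap = free // (n_genes + 1)
    order = list(genes)
    rng.shuffle(order)  # type: ignore[arg-type]
    # dnaA first so the ori rotation lands in the trailing feature-free tail
    for i, g in enumerate(order):
        if g.product == DNAA_PRODUCT:
            order.insert(0, order.pop(i))
            break
    if hotspot is not None:
        frac, hot_genes = hotspot
        idx = max(1, min(len(order), int(round(frac * len(order)))))
        order = order[:idx] + list(hot_genes) + order[idx:]
        hot_set = {id(g) for g in hot_genes}
    else:
        hot_set = set()

    parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0
    counter = 1
    hot_positions: list[int] = []
    for g in order:
        if id(g) in hot_set:
            gap = int(rng.integers(100, 301))
        else:
            gap = int(rng.integers(max(150, mean_gap // 3), 2 * mean_gap - mean_gap // 3))
        parts.append(_random_dna(rng, gap, gc))
        pos += gap
        strand = "+" if (g.product == DNAA_PRODUCT or rng.random() < 0.5) else "-"
        dna = g.dna if strand == "+" else revcomp(g.dna)
        locus = f"{strain}_{counter:05d}"
        counter += 1
        feats.append(
            GeneFeature(locus, "CDS", pos, pos + len(dna), strand, g.product, g.translation)
        )
        ledger.add_member(g.cluster_id, strain, locus)
        if id(g) in hot_set:
            hot_positions.append(pos + len(dna) // 2)
        parts.append(dna)
        pos += len(dna)
    tail = max(1200, target_length - pos)
    parts.append(_random_dna(rng, tail, gc))
    rep = Replicon(rep_id, "".join(parts), "circular", feats, is_chromosome=True)
    if hot_positions:
        ledger.orfan_hotspots[strain] = {
            "replicon": rep_id,
            "center": int(np.mean(hot_positions)),
            "count": len(hot_positions),
        }
    return rep


def _build_pool(
    pool: GenomePoolSpec,
    cluster_prefix: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> list[Genome]:
    lo, hi = cfg.protein_length
    ancestral: list[_GeneDef] = []
    dnaa_prot = _random_protein(rng, 300, 380)
    ancestral.append(_GeneDef(f"{cluster_prefix}dnaa", _orf_for(dnaa_prot, rng), dnaa_prot, DNAA_PRODUCT))
    for i in range(pool.core_genes - 1):
        prot = _random_protein(rng, lo, hi)
        product = (
            "hypothetical protein"
            if rng.random() < 0.2
            else NEUTRAL_PRODUCTS[int(rng.integers(0, len(NEUTRAL_PRODUCTS)))]
        )
        ancestral.append(_GeneDef(f"{cluster_prefix}core_{i:04d}", _orf_for(prot, rng), prot, product))
    shells: list[tuple[_GeneDef, set[str]]] = []
    n_strains = len(pool.strains)
    for j in range(pool.shell_genes):
        prot = _random_protein(rng, lo, hi)
        product = (
            "hypothetical protein"
            if rng.random() < 0.3
            else NEUTRAL_PRODUCTS[int(rng.integers(0, len(NEUTRAL_PRODUCTS)))]
        )
        gd = _GeneDef(f"{cluster_prefix}shell_{j:04d}", _orf_for(prot, rng), prot, product)
        size = int(rng.integers(2, max(3, n_strains)))
        members = set(
            np.array(pool.strains)[rng.choice(n_strains, size=size, replace=False)]
        )
        shells.append((gd, members))

    genomes = []
    for strain in pool.strains:
        roster: list[_GeneDef] = []
        for gd in ancestral:
            dna, _ = _mutate_seq(
                gd.dna, rng, rate=pool.divergence, orfs=((0, len(gd.dna), "+"),)
            )
            roster.append(replace(gd, dna=dna, translation=_translate(dna)))
        for gd, members in shells:
            if strain in members:
                dna, _ = _mutate_seq(
                    gd.dna, rng, rate=pool.divergence, orfs=((0, len(gd.dna), "+"),)
                )
                roster.append(replace(gd, dna=dna, translation=_translate(dna)))
        orfans: list[_GeneDef] = []
        for k in range(pool.orfans_per_genome):
            prot = _random_protein(rng, lo, hi)
            product = (
                "hypothetical protein"
                if rng.random() < 0.7
                else NEUTRAL_PRODUCTS[int(rng.integers(0, len(NEUTRAL_PRODUCTS)))]
            )
            orfans.append(
                _GeneDef(f"orfan_{strain}_{k:03d}", _orf_for(prot, rng), prot, product)
            )
        hotspot = None
        if pool.orfan_hotspot_fraction is not None and orfans:
            n_hot = int(round(pool.orfan_hotspot_share * len(orfans)))
            hotspot = (pool.orfan_hotspot_fraction, orfans[:n_hot])
            roster.extend(orfans[n_hot:])
        else:
            roster.extend(orfans)
        rep = _build_chromosome(
            strain,
            f"chr_{strain}",
            roster,
            pool.chromosome_length,
            cfg.gc,
            rng,
            ledger,
            hotspot=hotspot,
        )
        genomes.append(Genome(strain, pool.species, [rep]))
        ledger.genomes[strain] = {
            "species": pool.species,
            "chromosome": rep.replicon_id,
            "length": len(rep.sequence),
        }
    return genomes


# ---------------------------------------------------------------------------
# Editing machinery
# ---------------------------------------------------------------------------

def _protected_intervals(ledger: TruthLedger, strain: str, replicon: str) -> list[tuple[int, int]]:
    return [(obj[ks], obj[ke]) for obj, ks, ke in ledger._intervals(strain, replicon)]


def _insert_segment(
    genome: Genome,
    replicon_id: str,
    pos: int,
    seq: str,
    rel_feats: list[GeneFeature],
    ledger: TruthLedger,
    split_host: bool = False,
) -> None:
    rep = next(r for r in genome.replicons if r.replicon_id == replicon_id)
    delta = len(seq)
    out: list[GeneFeature] = []
    for f in rep.features:
        if f.start >= pos:
            out.append(replace(f, start=f.start + delta, end=f.end + delta))
        elif f.end > pos:  # spanning feature
            if not (split_host and f.kind == "CDS"):
                raise SimulationError(
                    f"insertion at {pos} would fall inside feature {f.locus_tag}"
                )
            left = replace(f, end=pos, translation="")
            right = replace(
                f,
                locus_tag=f.locus_tag + "b",
                start=pos + delta,
                end=f.end + delta,
                translation="",
            )
            ledger.remove_member(genome.strain, f.locus_tag)
            out.extend([left, right])
        else:
            out.append(f)
    for nf in rel_feats:
        out.append(replace(nf, start=nf.start + pos, end=nf.end + pos))
    ledger.shift(genome.strain, replicon_id, pos, delta)
    rep.features = sorted(out, key=lambda f: (f.start, f.end))
    rep.sequence = rep.sequence[:pos] + seq + rep.sequence[pos:]


def _gaps(rep: Replicon, margin: int = 60) -> list[tuple[int, int]]:
    """Feature-free intervals between consecutive features (margins applied)."""
    out = []
    feats = rep.features
    for a, b in zip(feats, feats[1:]):
        lo, hi = a.end + margin, b.start - margin
        if hi > lo:
            out.append((lo, hi))
    return out


def _ok_pos(pos: int, protected: list[tuple[int, int]], pad: int = 100) -> bool:
    return all(not (s - pad < pos < e + pad) for s, e in protected)


def _random_site(rep: Replicon, protected: list[tuple[int, int]], rng: np.random.Generator) -> int:
    gaps = _gaps(rep)
    if not gaps:
        raise SimulationError("no intergenic space left")
    widths = np.array([hi - lo for lo, hi in gaps], dtype=float)
    for _ in range(300):
        gi = int(rng.choice(len(gaps), p=widths / widths.sum()))
        lo, hi = gaps[gi]
        pos = int(rng.integers(lo, hi))
        if _ok_pos(pos, protected):
            return pos
    raise SimulationError("could not place structure after 300 attempts")


def _site_near(
    rep: Replicon,
    target: int,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    radius: int = 8000,
    validator=None,
) -> int | None:
    gaps = _gaps(rep)
    cands: list[int] = []
    for lo, hi in gaps:
        lo2, hi2 = max(lo, target - radius), min(hi, target + radius)
        if hi2 > lo2:
            cands.extend({lo2, (lo2 + hi2) // 2, hi2 - 1, min(max(target, lo2), hi2 - 1)})
    cands = [
        p for p in cands if _ok_pos(p, protected) and (validator is None or validator(p))
    ]
    if not cands:
        if validator is None:
            return _random_site(rep, protected, rng)
        return None
    return min(cands, key=lambda p: abs(p - target))


def _leftmost_site(
    rep: Replicon,
    pos_min: int,
    protected: list[tuple[int, int]],
    validator=None,
) -> int | None:
    """Leftmost intergenic position >= pos_min passing all checks."""
    for lo, hi in _gaps(rep):
        if hi <= pos_min:
            continue
        p = max(lo, pos_min)
        while p < hi:
            if _ok_pos(p, protected) and (validator is None or validator(p)):
                return p
            # jump past whichever protected zone rejected this point
            nxt = p + 200
            for s, e in protected:
                if s - 100 < p < e + 100:
                    nxt = max(nxt, e + 101)
            p = nxt
        # validator failures (spacing to an off-plan copy) are resolved by
        # moving to later gaps
    return None


# ---------------------------------------------------------------------------
# Structure planting
# ---------------------------------------------------------------------------

def _make_is_element(spec: ISSpec, rng: np.random.Generator, gc: float) -> dict:
    ir = _random_dna(rng, spec.ir_length, gc)
    inner = spec.element_length - 2 * spec.ir_length
    pad_left = 40
    orf_len_max = inner - pad_left - 20
    prot_len = (orf_len_max - 3) // 3 - 1
    prot = _random_protein(rng, prot_len, prot_len)
    orf = _orf_for(prot, rng)
    pad_right = inner - pad_left - len(orf)
    seq = ir + _random_dna(rng, pad_left, gc) + orf + _random_dna(rng, pad_right, gc) + revcomp(ir)
    assert len(seq) == spec.element_length
    return {
        "name": spec.name,
        "family": spec.family,
        "sequence": seq,
        "ir": ir,
        "orf_start": spec.ir_length + pad_left,
        "orf_end": spec.ir_length + pad_left + len(orf),
        "transposase": prot,
        "product": f"{spec.family} family transposase",
    }


def _is_copy_payload(
    element: dict, spec: ISSpec, strain: str, counter: int, rng: np.random.Generator, strand: str
) -> tuple[str, list[GeneFeature], str]:
    """Mutated element copy, its transposase feature, and the locus tag."""
    seq, _ = _mutate_seq(
        element["sequence"],
        rng,
        rate=spec.copy_divergence,
        orfs=((element["orf_start"], element["orf_end"], "+"),),
    )
    orf_dna = seq[element["orf_start"] : element["orf_end"]]
    trans = _translate(orf_dna)
    locus = f"{strain}_{element['name']}_{counter:03d}"
    if strand == "+":
        feat = GeneFeature(
            locus, "CDS", element["orf_start"], element["orf_end"], "+", element["product"], trans
        )
        return seq, [feat], locus
    rseq = revcomp(seq)
    n = len(seq)
    feat = GeneFeature(
        locus,
        "CDS",
        n - element["orf_end"],
        n - element["orf_start"],
        "-",
        element["product"],
        trans,
    )
    return rseq, [feat], locus


def _plant_is_copies(
    genome: Genome,
    element: dict,
    spec: ISSpec,
    n_copies: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> None:
    rep = genome.chromosome
    strain = genome.strain
    n_existing = sum(
        1
        for c in ledger.is_copies
        if c["genome"] == strain and c["element"] == element["name"]
    )
    spacing = cfg.is_spacing
    prev_end = int(rng.integers(2000, 12000))  # randomized left margin
    for ci in range(n_copies):
        protected = _protected_intervals(ledger, strain, rep.replicon_id)
        placed_same = [
            (c["start"], c["end"])
            for c in ledger.is_copies
            if c["genome"] == strain and c["element"] == element["name"]
        ]

        def far_enough(p: int) -> bool:
            return all(p <= s - spacing or p >= e + spacing for s, e in placed_same)

        strand = "+" if rng.random() < 0.5 else "-"
        seq, feats, locus = _is_copy_payload(
            element, spec, strain, n_existing + ci + 1, rng, strand
        )
        pos_min = prev_end + spacing + int(rng.integers(0, 2001))
        in_gene = rng.random() < spec.in_gene_fraction
        host_locus = None
        pos = _leftmost_site(rep, pos_min, protected, validator=far_enough)
        if pos is None:
            raise SimulationError(
                f"{strain}: cannot place {element['name']} copy {ci + 1}/{n_copies} "
                f"with spacing {spacing}"
            )
        if in_gene:
            host = _pick_host_gene(
                rep, pos + 4000, protected, ledger, strain, rng,
                radius=4000, validator=far_enough,
            )
            if host is not None:
                pos = int(rng.integers(host.start + 45, host.end - 45))
                host_locus = host.locus_tag
        _insert_segment(genome, rep.replicon_id, pos, seq, feats, ledger, split_host=host_locus is not None)
        ledger.add_member(f"tpase_{element['name']}", strain, locus)
        ledger.is_copies.append(
            {
                "element": element["name"],
                "genome": strain,
                "replicon": rep.replicon_id,
                "start": pos,
                "end": pos + len(seq),
                "strand": strand,
                "disrupted_locus": host_locus,
                "divergence": spec.copy_divergence,
            }
        )
        prev_end = pos + len(seq)


def _pick_host_gene(
    rep: Replicon,
    target: int,
    protected: list[tuple[int, int]],
    ledger: TruthLedger,
    strain: str,
    rng: np.random.Generator,
    radius: int = 8000,
    validator=None,
):
    """A background gene near ``target`` suitable for disruption."""
    eligible_clusters = {
        cid
        for cid in ledger.clusters
        if cid.split("/")[-1].startswith(("core_", "shell_", "orfan_"))
    }
    locus_to_cluster = {
        (s, l): cid for cid, members in ledger.clusters.items() for s, l in members
    }
    cands = []
    for f in rep.features:
        if f.kind != "CDS" or not f.translation or f.length < 240:
            continue
        if abs(f.midpoint() - target) > radius:
            continue
        cid = locus_to_cluster.get((strain, f.locus_tag))
        if cid is None or cid not in eligible_clusters:
            continue
        if not (_ok_pos(f.start, protected) and _ok_pos(f.end, protected)):
            continue
        if validator is not None and not validator(f.midpoint()):
            continue
        cands.append(f)
    if not cands:
        return None
    return cands[int(rng.integers(0, len(cands)))]


def _genes_segment(
    genes: list[tuple[str, str]],  # (product, cluster_id)
    strain: str,
    tag: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ledger: TruthLedger,
    gap_range: tuple[int, int] = (120, 400),
) -> tuple[str, list[GeneFeature]]:
    """A gene cassette: alternating spacers and annotated forward/reverse ORFs."""
    lo, hi = cfg.protein_length
    parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0
    for i, (product, cluster_id) in enumerate(genes):
        gap = int(rng.integers(*gap_range))
        parts.append(_random_dna(rng, gap, cfg.gc))
        pos += gap
        prot = _random_protein(rng, lo, hi)
        dna = _orf_for(prot, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = dna if strand == "+" else revcomp(dna)
        locus = f"{strain}_{tag}_{i:03d}"
        feats.append(GeneFeature(locus, "CDS", pos, pos + len(placed), strand, product, prot))
        if cluster_id:
            ledger.add_member(cluster_id, strain, locus)
        parts.append(placed)
        pos += len(placed)
    parts.append(_random_dna(rng, int(rng.integers(*gap_range)), cfg.gc))
    return "".join(parts), feats


def _plant_composite(
    genome: Genome,
    element: dict,
    spec: CompositeSpec,
    is_spec: ISSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> None:
    rep = genome.chromosome
    strain = genome.strain
    cargo_seq, cargo_feats = _genes_segment(
        [(p, f"cargo_{strain}_{i:02d}") for i, p in enumerate(spec.cargo_products)],
        strain,
        "cargo",
        cfg,
        rng,
        ledger,
    )
    left_seq, left_feats, left_locus = _is_copy_payload(element, is_spec, strain, 901, rng, "+")
    right_seq, right_feats, right_locus = _is_copy_payload(element, is_spec, strain, 902, rng, "+")
    block = left_seq + cargo_seq + right_seq
    feats = list(left_feats)
    feats += [replace(f, start=f.start + len(left_seq), end=f.end + len(left_seq)) for f in cargo_feats]
    off = len(left_seq) + len(cargo_seq)
    feats += [replace(f, start=f.start + off, end=f.end + off) for f in right_feats]
    protected = _protected_intervals(ledger, strain, rep.replicon_id)
    pos = _random_site(rep, protected, rng)
    _insert_segment(genome, rep.replicon_id, pos, block, feats, ledger)
    for locus in (left_locus, right_locus):
        ledger.add_member(f"tpase_{element['name']}", strain, locus)
    lrange = (pos, pos + len(left_seq))
    crange = (pos + len(left_seq), pos + len(left_seq) + len(cargo_seq))
    rrange = (crange[1], crange[1] + len(right_seq))
    for rng_, locus in ((lrange, left_locus), (rrange, right_locus)):
        ledger.is_copies.append(
            {
                "element": element["name"],
                "genome": strain,
                "replicon": rep.replicon_id,
                "start": rng_[0],
                "end": rng_[1],
                "strand": "+",
                "disrupted_locus": None,
                "divergence": is_spec.copy_divergence,
            }
        )
    ledger.composites.append(
        {
            "genome": strain,
            "replicon": rep.replicon_id,
            "element": element["name"],
            "left_start": lrange[0],
            "left_end": lrange[1],
            "cargo_start": crange[0],
            "cargo_end": crange[1],
            "right_start": rrange[0],
            "right_end": rrange[1],
            "cargo_genes": [f.locus_tag for f in feats if "cargo" in f.locus_tag],
        }
    )


def _plant_hgt(
    recipient: Genome,
    donor: Genome,
    spec: HgtSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> None:
    dchrom = donor.chromosome
    dn = len(dchrom.sequence)
    # the segment must lie before the donor's last gene so the final ori
    # rotation (whose pivot is past every feature) cannot split it
    last_end = max(f.end for f in dchrom.features)
    upper = last_end - spec.length - 200
    if upper <= 2000:
        raise SimulationError(f"HGT block {spec.length} longer than donor gene span")
    protected_d = _protected_intervals(ledger, donor.strain, dchrom.replicon_id)
    for _ in range(200):
        a = int(rng.integers(2000, upper))
        if all(not (s < a + spec.length and e > a) for s, e in protected_d):
            break
    else:
        raise SimulationError("no clean donor segment found")
    seg = dchrom.sequence[a : a + spec.length]
    carried = [
        f for f in dchrom.features if f.start >= a and f.end <= a + spec.length and f.translation
    ]
    locus_to_cluster = {
        (s, l): cid for cid, members in ledger.clusters.items() for s, l in members
    }
    rel_orfs = tuple((f.start - a, f.end - a, f.strand) for f in carried)
    n_sub = int(round((1.0 - spec.identity) * spec.length))
    mut, applied = _mutate_seq(seg, rng, exact_n=n_sub, orfs=rel_orfs)
    realized = 1.0 - applied / spec.length
    rel_feats = []
    genes = []
    for i, f in enumerate(carried):
        s, e = f.start - a, f.end - a
        orf = mut[s:e] if f.strand == "+" else revcomp(mut[s:e])
        trans = _translate(orf)
        locus = f"{recipient.strain}_hgt{spec.label or spec.donor}_{i:03d}"
        rel_feats.append(GeneFeature(locus, "CDS", s, e, f.strand, f.product, trans))
        cid = locus_to_cluster.get((donor.strain, f.locus_tag))
        if cid:
            ledger.add_member(cid, recipient.strain, locus)
        genes.append(locus)
    rchrom = recipient.chromosome
    protected = _protected_intervals(ledger, recipient.strain, rchrom.replicon_id)
    pos = _random_site(rchrom, protected, rng)
    _insert_segment(recipient, rchrom.replicon_id, pos, mut, rel_feats, ledger)
    ledger.hgt_blocks.append(
        {
            "recipient": recipient.strain,
            "recipient_replicon": rchrom.replicon_id,
            "donor": donor.strain,
            "donor_replicon": dchrom.replicon_id,
            "r_start": pos,
            "r_end": pos + len(mut),
            "d_start": a,
            "d_end": a + spec.length,
            "identity_target": spec.identity,
            "identity_realized": realized,
            "label": spec.label,
            "expect_detected": spec.expect_detected,
            "genes": genes,
        }
    )


def _plant_ice(
    genome: Genome,
    spec: IceSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> None:
    rep = genome.chromosome
    strain = genome.strain
    products = list(spec.signature_products) + ["hypothetical protein"] * spec.n_filler
    order = np.array(products, dtype=object)
    rng.shuffle(order)
    genes = [(str(p), f"ice_{strain}_{i:02d}") for i, p in enumerate(order)]
    core_seq, core_feats = _genes_segment(
        genes, strain, "ice", cfg, rng, ledger, gap_range=(150, 600)
    )
    att = spec.att.upper()
    payload = att + core_seq + att
    rel_feats = [replace(f, start=f.start + len(att), end=f.end + len(att)) for f in core_feats]
    # integrate at the 3' end of a forward background gene
    protected = _protected_intervals(ledger, strain, rep.replicon_id)
    hosts = [
        f
        for f in rep.features
        if f.kind == "CDS" and f.strand == "+" and f.translation
        and _ok_pos(f.end, protected) and _ok_pos(f.end + 50, protected)
    ]
    if not hosts:
        raise SimulationError("no host gene available for the island")
    host = hosts[int(rng.integers(0, len(hosts)))]
    pos = host.end
    # pin the repeat arms: the bases adjacent to the planted att copies must
    # differ so the maximal direct-repeat pair is exactly the planted one
    seq = rep.sequence
    after = seq[pos] if pos < len(seq) else "A"
    before = seq[pos - 1]
    first = "G" if after != "G" else "T"
    last = "G" if before != "G" else "T"
    core_seq = first + core_seq[1:-1] + last
    payload = att + core_seq + att
    _insert_segment(genome, rep.replicon_id, pos, payload, rel_feats, ledger)
    signature = {cls: [] for cls in ("integration_excision", "replication", "conjugation")}
    from .ice import load_signature_table

    table = load_signature_table()
    for f in rel_feats:
        p = f.product.lower()
        for cls, pat in table:
            if pat in p:
                signature[cls].append(f.locus_tag)
                break
    ledger.ices.append(
        {
            "genome": strain,
            "replicon": rep.replicon_id,
            "start": pos,
            "end": pos + len(att) + len(core_seq),  # right att start
            "att": att,
            "host_gene": host.locus_tag,
            "signature": signature,
            "island_genes": [f.locus_tag for f in rel_feats],
        }
    )


def _plant_plasmid(
    donor: Genome,
    recipient: Genome,
    spec: PlasmidSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> None:
    strain = donor.strain
    products = [
        "replication protein RepA",
        "replication protein RepB",
        "plasmid partitioning protein ParA",
        "hypothetical protein",
        "hypothetical protein",
        "hypothetical protein",
        "replication protein",
        "hypothetical protein",
    ]
    genes = [(p, f"plasmid_{strain}_{i:02d}") for i, p in enumerate(products)]
    seq, feats = _genes_segment(genes, strain, "pl", cfg, rng, ledger, gap_range=(80, 250))
    if len(seq) < spec.length:
        seq = seq + _random_dna(rng, spec.length - len(seq), cfg.gc)
    pid = f"plasmid_{strain}"
    plasmid = Replicon(pid, seq, "circular", feats, is_chromosome=False)
    donor.replicons.append(plasmid)
    ledger.genomes[strain]["plasmid"] = {"replicon": pid, "length": len(seq)}

    n = len(seq)
    covered = int(round(spec.integrated_fraction * n))
    # dispersed plasmid intervals: covered bp split into n_fragments pieces
    # separated by uncovered gaps (the remainder also pads the plasmid end)
    nf = spec.n_fragments
    base = covered // nf
    jit = min(max(1, base // 5), 100)
    flens = [base + int(rng.integers(-jit, jit + 1)) for _ in range(nf - 1)]
    flens.append(covered - sum(flens))
    free = n - covered
    gap = free // (nf + 1)
    pieces = []
    pos_p = 0
    for fl in flens:
        pos_p += gap
        pieces.append((pos_p, pos_p + fl))
        pos_p += fl
    fragments = []
    rchrom = recipient.chromosome
    for s, e in pieces:
        frag = seq[s:e]
        protected = _protected_intervals(ledger, recipient.strain, rchrom.replicon_id)
        pos = _random_site(rchrom, protected, rng)
        rel_feats = []
        for i, f in enumerate(feats):
            if f.start >= s and f.end <= e and f.translation:
                locus = f"{recipient.strain}_plfrag_{s}_{i:02d}"
                rel_feats.append(replace(f, locus_tag=locus, start=f.start - s, end=f.end - s))
                cid = f"plasmid_{strain}_{i:02d}"
                ledger.add_member(cid, recipient.strain, locus)
        _insert_segment(recipient, rchrom.replicon_id, pos, frag, rel_feats, ledger)
        fragments.append({"p_start": s, "p_end": e, "r_start": pos, "r_end": pos + len(frag)})
    ledger.plasmid_integrations.append(
        {
            "plasmid": pid,
            "donor": strain,
            "recipient": recipient.strain,
            "recipient_replicon": rchrom.replicon_id,
            "fragments": fragments,
            "coverage_fraction": sum(f["p_end"] - f["p_start"] for f in fragments) / n,
        }
    )


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def simulate_genome_set(config: SimulationConfig) -> tuple[list[Genome], TruthLedger]:
    """Generate the configured genome set and its planted-truth ledger.

    Returns recipients first, then donors, all ori-rotated; the ledger's
    coordinates are in the returned (rotated) frame.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("pools", "elements", "is", "composite", "hgt", "ice", "plasmid"),
            ss.spawn(7),
        )
    }
    ledger = TruthLedger()
    recipients = _build_pool(config.recipients, "", config, streams["pools"], ledger)
    donors: list[Genome] = []
    for di, pool in enumerate(config.donors):
        donors.extend(_build_pool(pool, f"d{di}/", config, streams["pools"], ledger))
    by_strain = {g.strain: g for g in recipients + donors}

    elements = {
        spec.name: _make_is_element(spec, streams["elements"], config.gc)
        for spec in config.is_specs
    }
    for name, el in elements.items():
        ledger.is_elements[name] = {
            "family": el["family"],
            "length": len(el["sequence"]),
            "ir": el["ir"],
            "sequence": el["sequence"],
            "transposase_product": el["product"],
        }

    # big structures first so IS spacing can route around them
    for spec in config.ices:
        _plant_ice(by_strain[spec.strain], spec, config, streams["ice"], ledger)
    for spec in config.composites:
        _plant_composite(
            by_strain[spec.strain],
            elements[spec.is_name],
            spec,
            next(s for s in config.is_specs if s.name == spec.is_name),
            config,
            streams["composite"],
            ledger,
        )
    for spec in config.hgt:
        _plant_hgt(
            by_strain[spec.recipient],
            by_strain[spec.donor],
            spec,
            config,
            streams["hgt"],
            ledger,
        )
    for spec in config.plasmids:
        _plant_plasmid(
            by_strain[spec.donor], by_strain[spec.recipient], spec, config,
            streams["plasmid"], ledger,
        )
    for spec in config.is_specs:
        for strain, (lo, hi) in spec.copies_per_genome.items():
            n = int(streams["is"].integers(lo, hi + 1))
            if n > 0:
                _plant_is_copies(
                    by_strain[strain], elements[spec.name], spec, n, config,
                    streams["is"], ledger,
                )

    # rotate everything to the ori convention, ledger included
    out: list[Genome] = []
    for g in recipients + donors:
        chrom = g.chromosome
        dnaa = find_dnaa(chrom)
        if len(dnaa) != 1:
            raise SimulationError(f"{g.strain}: dnaA candidates {len(dnaa)}")
        offset = ori_rotation_offset(chrom, dnaa[0])
        rotated = _rotate_replicon(chrom, offset)
        ledger.rotate(g.strain, chrom.replicon_id, offset, len(chrom.sequence))
        reps = [rotated if r.is_chromosome else r for r in g.replicons]
        out.append(Genome(g.strain, g.species_label, reps, ori_offset=0))
    return out, ledger


def default_suite(
    seed: int = 0,
    is_copy_divergence: float = 0.0,
    n_recipients: int = 5,
) -> SimulationConfig:
    """The standard synthetic study set.

    Five recipient genomes of one species (shared core pool, shell genes,
    ten ORFans each with a positional hotspot), two single-genome donor
    species, two IS families (one at 5-13 copies per recipient genome with a
    single copy in one donor, one at 2-4 copies), a composite transposon
    with an iron-uptake cargo, three detectable HGT blocks plus one
    sub-threshold block, an ICE-like island with the canonical 12 bp att
    repeat, and a donor plasmid 80% of which is integrated in fragments in
    one recipient.
    """
    recips = [f"RA-{i:02d}" for i in range(1, n_recipients + 1)]
    recipients = GenomePoolSpec(
        strains=recips,
        species="SpeciesA",
        core_genes=100,
        shell_genes=40,
        orfans_per_genome=10,
        chromosome_length=450_000,
        divergence=0.01,
        orfan_hotspot_fraction=0.6,
        orfan_hotspot_share=0.6,
    )
    donor_b = GenomePoolSpec(
        strains=["DB-01"], species="SpeciesB", core_genes=60,
        chromosome_length=120_000, divergence=0.0,
    )
    donor_c = GenomePoolSpec(
        strains=["DC-01"], species="SpeciesC", core_genes=60,
        chromosome_length=120_000, divergence=0.0,
    )
    is_a = ISSpec(
        name="ISsynA",
        family="IS3",
        element_length=1200,
        ir_length=16,
        copies_per_genome={**{s: (5, 13) for s in recips}, "DB-01": (1, 1)},
        in_gene_fraction=0.2,
        copy_divergence=is_copy_divergence,
    )
    is_b = ISSpec(
        name="ISsynB",
        family="ISL3",
        element_length=950,
        ir_length=14,
        copies_per_genome={s: (2, 4) for s in recips},
        in_gene_fraction=0.0,
        copy_divergence=is_copy_divergence,
    )
    n = len(recips)
    return SimulationConfig(
        recipients=recipients,
        donors=[donor_b, donor_c],
        is_specs=[is_a, is_b],
        composites=[CompositeSpec(strain=recips[2 % n], is_name="ISsynB")],
        hgt=[
            HgtSpec(recipient=recips[0], donor="DB-01", length=8000, identity=0.97, label="R"),
            HgtSpec(recipient=recips[1 % n], donor="DB-01", length=5000, identity=0.95, label="IUT"),
            HgtSpec(recipient=recips[3 % n], donor="DC-01", length=12000, identity=0.93, label="LI"),
            HgtSpec(
                recipient=recips[1 % n], donor="DC-01", length=1500, identity=0.99,
                label="short", expect_detected=False,
            ),
        ],
        ices=[IceSpec(strain=recips[0])],
        plasmids=[PlasmidSpec(donor="DB-01", recipient=recips[1 % n])],
        seed=seed,
    )
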