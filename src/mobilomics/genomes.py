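"""Genome records, coordinate conventions, and product-keyword classification.

The in-memory model is deliberately simple: a :class:`Genome` is a set of
replicons (one flagged as the chromosome), each replicon a DNA string plus an
ordered list of :class:`GeneFeature` annotations. All coordinates are 0-based,
half-open, on the forward strand; GenBank's 1-based inclusive convention is
converted at the file boundary. Features of circular replicons that span the
origin are stored *unwrapped* — ``end`` may exceed the replicon length and the
``wraps`` flag is set — so every feature is a single contiguous interval and
interval arithmetic reduces modulo the replicon length.

Chromosome coordinates can be rotated to the *ori* convention used for
bacterial comparative maps: position 0 is placed at the start of the
intergenic region immediately upstream of the dnaA gene (the chromosomal
replication initiator), identified by its product annotation.

Functional categorization of product strings is a deterministic keyword-table
lookup. The table ships with the package as an editable two-column TSV
(category, pattern); it approximates coarse RAST-style subsystem groupings
without claiming equivalence to any curated annotation system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

__all__ = [
    "GeneFeature",
    "Replicon",
    "Genome",
    "GenomeParseError",
    "GenomeValidationError",
    "OriAnchorError",
    "read_genome",
    "write_genbank",
    "write_fasta",
    "write_gff3",
    "normalize_to_ori",
    "gc_content",
    "classify_product",
    "load_keyword_table",
    "FUNCTIONAL_CATEGORIES",
]

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "other")

FUNCTIONAL_CATEGORIES = (
    "hypothetical",
    "phage & mobile elements",
    "membrane transport",
    "iron acquisition & metabolism",
    "DNA/RNA metabolism",
    "transcriptional regulation",
    "carbohydrate/amino-acid/protein metabolism",
    "stress response",
    "miscellaneous",
    "putative",
)

DNAA_KEYWORDS = ("chromosomal replication initiator", "dnaa")


class GenomeParseError(ValueError):
    """Raised when an input file cannot be parsed as GenBank/FASTA."""


class GenomeValidationError(ValueError):
    """Raised when parsed coordinates violate the model invariants."""


class OriAnchorError(ValueError):
    """Raised when the dnaA anchor is absent or ambiguous."""


@dataclass
class GeneFeature:
    """One annotated feature on a replicon (0-based, half-open, unwrapped)."""

    locus_tag: str
    kind: str  # one of FEATURE_KINDS
    start: int
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    translation: str = ""
    wraps: bool = False  # end > replicon length on circular replicons

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            self.kind = "other"
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(f"{self.locus_tag}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"{self.locus_tag}: bad interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self, replicon_length: int | None = None) -> int:
        m = (self.start + self.end) // 2
        return m % replicon_length if replicon_length else m


@dataclass
class Replicon:
    replicon_id: str
    sequence: str
    topology: str = "circular"  # or 'linear'
    features: list[GeneFeature] = field(default_factory=list)
    is_chromosome: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeValidationError(f"{self.replicon_id}: empty sequence")
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            limit = 2 * n if (self.topology == "circular" and f.wraps) else n
            if f.end > limit:
                raise GenomeValidationError(
                    f"{self.replicon_id}:{f.locus_tag} end {f.end} exceeds length {n}"
                )
            if f.kind == "CDS" and f.translation:
                if len(f.translation) * 3 > f.length + 3:
                    raise GenomeValidationError(
                        f"{self.replicon_id}:{f.locus_tag} translation longer than CDS"
                    )

    def feature_sequence(self, f: GeneFeature) -> str:
        n = len(self.sequence)
        if f.end <= n:
            s = self.sequence[f.start : f.end]
        else:  # origin-spanning
            s = self.sequence[f.start :] + self.sequence[: f.end - n]
        return s if f.strand == "+" else revcomp(s)

    def subsequence(self, start: int, end: int) -> str:
        """Forward-strand slice with circular wrap (end may exceed length)."""
        n = len(self.sequence)
        if self.topology == "circular":
            span = end - start
            start %= n
            end = start + span
            if end <= n:
                return self.sequence[start:end]
            reps = self.sequence * (2 + (end - n) // n)
            return reps[start:end]
        return self.sequence[max(0, start) : min(n, end)]


@dataclass
class Genome:
    strain: str
    species_label: str
    replicons: list[Replicon]
    ori_offset: int = 0

    def __post_init__(self) -> None:
        chroms = [r for r in self.replicons if r.is_chromosome]
        if len(chroms) != 1:
            raise GenomeValidationError(
                f"{self.strain}: exactly one chromosome required, got {len(chroms)}"
            )

    @property
    def chromosome(self) -> Replicon:
        return next(r for r in self.replicons if r.is_chromosome)

    @property
    def plasmids(self) -> list[Replicon]:
        return [r for r in self.replicons if not r.is_chromosome]

    def all_features(self) -> Iterable[tuple[Replicon, GeneFeature]]:
        for rep in self.replicons:
            for f in rep.features:
                yield rep, f

    def get_feature(self, locus_tag: str) -> tuple[Replicon, GeneFeature]:
        for rep, f in self.all_features():
            if f.locus_tag == locus_tag:
                return rep, f
        raise KeyError(locus_tag)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def _feature_from_seqfeature(sf: SeqFeature, idx: int, replicon_len: int) -> GeneFeature | None:
    kind = sf.type if sf.type in ("CDS", "rRNA", "tRNA") else None
    if kind is None:
        return None
    q = sf.qualifiers
    locus = q.get("locus_tag", [f"feat{idx:05d}"])[0]
    product = q.get("product", [""])[0]
    translation = q.get("translation", [""])[0]
    strand = "-" if sf.location.strand == -1 else "+"
    loc = sf.location
    wraps = False
    parts = getattr(loc, "parts", [loc])
    if len(parts) > 1:
        # Detect an origin-spanning join: one part ends at the replicon end,
        # the following part starts at 0 (order may be flipped on '-').
        ps = sorted(parts, key=lambda p: int(p.start))
        if int(ps[-1].end) == replicon_len and int(ps[0].start) == 0 and len(ps) == 2:
            start = int(ps[-1].start)
            end = start + (replicon_len - start) + int(ps[0].end)
            wraps = True
        else:
            start, end = int(loc.start), int(loc.end)
    else:
        start, end = int(loc.start), int(loc.end)
    return GeneFeature(locus, kind, start, end, strand, product, translation, wraps)


def read_genome(
    path: str | Path,
    topology_hint: str = "circular",
    strain: str | None = None,
    species_label: str = "",
) -> Genome:
    """Read a GenBank flat file or FASTA into a :class:`Genome`.

    FASTA input yields replicons with empty feature lists. The largest record
    is flagged as the chromosome unless a record definition mentions
    'plasmid'.
    """
    path = Path(path)
    text_head = path.read_text(errors="replace").lstrip()[:1]
    fmt = "fasta" if text_head == ">" else "genbank"
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenomeParseError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"{path}: no records found")

    replicons: list[Replicon] = []
    for rec in records:
        seq = str(rec.seq).upper()
        topo = rec.annotations.get("topology", topology_hint) or topology_hint
        feats: list[GeneFeature] = []
        for i, sf in enumerate(rec.features):
            gf = _feature_from_seqfeature(sf, i, len(seq))
            if gf is not None:
                feats.append(gf)
        is_plasmid = "plasmid" in (rec.description or "").lower()
        rep = Replicon(rec.id, seq, topo, feats, is_chromosome=not is_plasmid)
        rep.validate()
        replicons.append(rep)

    chroms = [r for r in replicons if r.is_chromosome]
    if len(chroms) != 1:
        longest = max(replicons, key=len)
        for r in replicons:
            r.is_chromosome = r is longest
    g = Genome(
        strain=strain or records[0].id,
        species_label=species_label,
        replicons=replicons,
    )
    return g


def _to_seqrecord(rep: Replicon, genome: Genome) -> SeqRecord:
    rec = SeqRecord(Seq(rep.sequence), id=rep.replicon_id, name=rep.replicon_id[:16])
    rec.description = f"{genome.species_label} {genome.strain}".strip() + (
        " plasmid" if not rep.is_chromosome else ""
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = rep.topology
    n = len(rep.sequence)
    for f in rep.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps and f.end > n:
            loc = CompoundLocation(
                [FeatureLocation(f.start, n, strand), FeatureLocation(0, f.end - n, strand)]
            )
        else:
            loc = FeatureLocation(f.start, f.end, strand)
        quals: dict[str, list[str]] = {"locus_tag": [f.locus_tag]}
        if f.product:
            quals["product"] = [f.product]
        if f.translation:
            quals["translation"] = [f.translation]
        rec.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    return rec


def write_genbank(genome: Genome, path: str | Path) -> None:
    SeqIO.write([_to_seqrecord(r, genome) for r in genome.replicons], str(path), "genbank")


def write_fasta(genome: Genome, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.replicon_id, description="") for r in genome.replicons],
        str(path),
        "fasta",
    )


def write_gff3(genome: Genome, path: str | Path) -> None:
    """Minimal GFF3 export for browser inspection (wrapped features split)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            n = len(rep.sequence)
            fh.write(f"##sequence-region {rep.replicon_id} 1 {n}\n")
            for f in rep.features:
                attrs = f"ID={f.locus_tag};product={f.product}"
                segs = [(f.start, min(f.end, n))]
                if f.wraps and f.end > n:
                    segs.append((0, f.end - n))
                for s, e in segs:
                    fh.write(
                        f"{rep.replicon_id}\tmobilomics\t{f.kind}\t{s + 1}\t{e}\t.\t"
                        f"{f.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# ori normalization
# ---------------------------------------------------------------------------

def _rotate_replicon(rep: Replicon, offset: int) -> Replicon:
    """Rotate a circular replicon so that `offset` becomes position 0."""
    n = len(rep.sequence)
    offset %= n
    if offset == 0:
        return replace(rep, features=[replace(f) for f in rep.features])
    seq = rep.sequence[offset:] + rep.sequence[:offset]
    feats = []
    for f in rep.features:
        ns = (f.start - offset) % n
        ne = ns + f.length
        feats.append(replace(f, start=ns, end=ne, wraps=ne > n))
    return Replicon(rep.replicon_id, seq, rep.topology, feats, rep.is_chromosome)


def _revcomp_replicon(rep: Replicon) -> Replicon:
    n = len(rep.sequence)
    feats = []
    for f in rep.features:
        s, e = f.start, min(f.end, n + f.length)  # unwrapped coords
        ns = (n - e) % n
        ne = ns + f.length
        feats.append(
            replace(
                f,
                start=ns,
                end=ne,
                strand="-" if f.strand == "+" else "+",
                wraps=ne > n,
            )
        )
    return Replicon(rep.replicon_id, revcomp(rep.sequence), rep.topology, feats, rep.is_chromosome)


def find_dnaa(chromosome: Replicon) -> list[GeneFeature]:
    hits = []
    for f in chromosome.features:
        if f.kind != "CDS":
            continue
        p = f.product.lower()
        if any(k in p for k in DNAA_KEYWORDS):
            hits.append(f)
    return hits


def ori_rotation_offset(chrom: Replicon, dnaa: GeneFeature) -> int:
    """Rotation offset placing position 0 just upstream of a forward dnaA."""
    n = len(chrom.sequence)
    others = [f for f in chrom.features if f.locus_tag != dnaa.locus_tag]
    if not others:
        return dnaa.start

    def upstream_gap(f: GeneFeature) -> int:
        return (dnaa.start - (f.end % n)) % n

    upstream = min(others, key=upstream_gap)
    return upstream.end % n


def normalize_to_ori(genome: Genome) -> Genome:
    """Rotate the chromosome so position 0 sits just upstream of dnaA.

    The anchor is the unique CDS whose product matches the replication
    initiator keywords. If dnaA is on the reverse strand the chromosome is
    first reverse-complemented so dnaA reads forward. Position 0 is the first
    base of the intergenic region upstream of dnaA, i.e. the end of the
    preceding gene (cyclically). Raises :class:`OriAnchorError` when zero or
    several candidates exist — no silent choice is made.
    """
    chrom = genome.chromosome
    if chrom.topology != "circular":
        raise OriAnchorError(f"{genome.strain}: ori normalization needs a circular chromosome")
    cands = find_dnaa(chrom)
    if len(cands) != 1:
        raise OriAnchorError(
            f"{genome.strain}: expected exactly one dnaA candidate, found "
            f"{[c.locus_tag for c in cands]}"
        )
    dnaa = cands[0]
    if dnaa.strand == "-":
        chrom = _revcomp_replicon(chrom)
        dnaa = next(f for f in chrom.features if f.locus_tag == cands[0].locus_tag)

    offset = ori_rotation_offset(chrom, dnaa)
    rotated = _rotate_replicon(chrom, offset)
    new_reps = [rotated if r.is_chromosome else r for r in genome.replicons]
    return Genome(genome.strain, genome.species_label, new_reps, ori_offset=0)


# ---------------------------------------------------------------------------
# Simple statistics and classification
# ---------------------------------------------------------------------------

def gc_content(replicon: Replicon | str) -> float:
    """Percent G+C over unambiguous bases; N excluded from both sides."""
    seq = replicon.sequence if isinstance(replicon, Replicon) else replicon.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("gc_content undefined: no unambiguous bases")
    return 100.0 * gc / acgt


def load_keyword_table(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Load the (category, pattern) table; order encodes matching priority."""
    if path is None:
        text = (resources.files("mobilomics.data") / "functional_categories.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cat, _, pat = line.partition("\t")
        if not pat:
            warnings.warn(f"keyword table line without pattern: {line!r}")
            continue
        table.append((cat, pat.lower()))
    return table


_DEFAULT_TABLE: list[tuple[str, str]] | None = None


def classify_product(product: str, table: list[tuple[str, str]] | None = None) -> str:
    """Map a product string to a coarse functional category (first match wins)."""
    global _DEFAULT_TABLE
    if table is None:
        if _DEFAULT_TABLE is None:
            _DEFAULT_TABLE = load_keyword_table()
        table = _DEFAULT_TABLE
    p = product.lower()
    for cat, pat in table:
        if pat in p:
            return cat
    if any(m in p for m in ("hypothetical", "uncharacterized", "unknown")):
        return "hypothetical"
    return "miscellaneous"
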