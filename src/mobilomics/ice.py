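"""Genomic islands as candidate integrative and conjugative elements (ICEs).

An ICE integrated by site-specific recombination leaves a short direct
repeat (the att site) on both flanks. The module refines a seed interval to
the outermost flanking direct-repeat pair, screens island genes for the
three ICE signature-function classes (integration/excision, replication as
an extrachromosomal element, conjugation), and tests excision in silico:
from the integrated chromosome it constructs the excised circular island and
the re-sealed chromosome, then predicts PCR products for user primers on all
three template forms. Outward-pointing primers across the island yield a
product only from the excised circle — the classic excision assay logic.

Excision bookkeeping keeps one att copy on the circle and one on the
re-sealed chromosome, the standard recombination arithmetic, so

    len(circle) + len(re-sealed chromosome) = len(chromosome) + len(att).

Island coordinates follow the convention [left-repeat start, right-repeat
start): the interval carries exactly one att copy, and appending the att to
it yields the excised circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .align import RepeatPair, find_direct_repeats, in_silico_pcr
from ._seq import validate_dna
from .genomes import Genome, Replicon

__all__ = [
    "IceIsland",
    "Primer",
    "SIGNATURE_CLASSES",
    "load_signature_table",
    "find_island_boundaries",
    "screen_signature_genes",
    "excision_templates",
    "predict_excision_pcr",
    "read_primer_table",
]

SIGNATURE_CLASSES = ("integration_excision", "replication", "conjugation")


@dataclass
class Primer:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        validate_dna(self.sequence, f"primer {self.name}")
        if not 15 <= len(self.sequence) <= 35:
            raise ValueError(f"primer {self.name}: length {len(self.sequence)} outside 15-35 nt")


@dataclass
class IceIsland:
    genome: str
    replicon_id: str
    start: int  # left att start
    end: int  # right att start; the interval holds one att copy
    att_repeat: str = ""
    bounded: bool = True
    alternates: list[RepeatPair] = field(default_factory=list)
    signature_hits: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    excision_prediction: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def load_signature_table(path: str | Path | None = None) -> list[tuple[str, str]]:
    if path is None:
        text = (resources.files("mobilomics.data") / "ice_signature_keywords.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, _, pat = line.partition("\t")
        if pat:
            table.append((cls, pat.lower()))
    return table


def read_primer_table(path: str | Path) -> list[Primer]:
    """Read a two-column primer list (name<TAB>sequence; '#' comments)."""
    primers = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, seq = line.partition("\t")
        primers.append(Primer(name.strip(), seq.strip()))
    return primers


def find_island_boundaries(
    genome: Genome,
    seed_interval: tuple[int, int],
    repeat_length: int = 12,
    window: int = 500,
    max_mismatch: int = 0,
    replicon_id: str | None = None,
) -> IceIsland:
    """Refine a seed interval to the outermost flanking direct-repeat pair.

    When no repeat pair of at least ``repeat_length`` bp flanks the seed,
    the island is returned unbounded (flagged) with the seed coordinates.
    Inner repeat pairs are kept as alternates.
    """
    rep = genome.chromosome if replicon_id is None else next(
        r for r in genome.replicons if r.replicon_id == replicon_id
    )
    pairs = find_direct_repeats(
        rep.sequence, seed_interval, repeat_length=repeat_length,
        max_mismatch=max_mismatch, window=window,
    )
    if not pairs:
        return IceIsland(
            genome=genome.strain,
            replicon_id=rep.replicon_id,
            start=seed_interval[0],
            end=seed_interval[1],
            bounded=False,
        )
    outer = max(pairs, key=lambda p: p.right_end - p.left_start)
    alternates = [p for p in pairs if p is not outer]
    att = rep.sequence[outer.left_start : outer.left_end]
    return IceIsland(
        genome=genome.strain,
        replicon_id=rep.replicon_id,
        start=outer.left_start,
        end=outer.right_start,
        att_repeat=att,
        bounded=True,
        alternates=alternates,
    )


def screen_signature_genes(
    island: IceIsland,
    genome: Genome,
    table: list[tuple[str, str]] | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Assign island genes to the three ICE signature-function classes."""
    if table is None:
        table = load_signature_table()
    rep = next(r for r in genome.replicons if r.replicon_id == island.replicon_id)
    att_len = len(island.att_repeat)
    hits: dict[str, list[tuple[str, str]]] = {c: [] for c in SIGNATURE_CLASSES}
    for f in rep.features:
        if f.kind != "CDS":
            continue
        if f.start < island.start or f.end > island.end + att_len:
            continue
        p = f.product.lower()
        for cls, pat in table:
            if pat in p:
                hits[cls].append((f.locus_tag, f.product))
                break
    island.signature_hits = hits
    return hits


def excision_templates(
    genome: Genome, island: IceIsland
) -> dict[str, Replicon]:
    """Integrated chromosome, excised circular island, re-sealed chromosome.

    One att copy is kept on the circle and one on the chromosome.
    """
    if not island.bounded or not island.att_repeat:
        raise ValueError("excision requires an island bounded by att repeats")
    rep = next(r for r in genome.replicons if r.replicon_id == island.replicon_id)
    seq = rep.sequence
    l0, r0 = island.start, island.end
    att = island.att_repeat
    circle_seq = seq[l0:r0] + att
    resealed_seq = seq[:l0] + seq[r0:]
    return {
        "integrated": rep,
        "excised_circle": Replicon(
            f"{rep.replicon_id}_circle", circle_seq, "circular", [], is_chromosome=True
        ),
        "resealed": Replicon(
            f"{rep.replicon_id}_resealed", resealed_seq, rep.topology, [], is_chromosome=True
        ),
    }


def predict_excision_pcr(
    genome: Genome,
    island: IceIsland,
    primers: list[Primer],
    max_product: int = 5000,
    max_mismatch: int = 2,
) -> dict[tuple[str, str], dict[str, list[int]]]:
    """Predicted product sizes per primer pair on the three template forms.

    All unordered primer pairs are tested; the value maps each template form
    to the list of predicted product lengths (empty list = no product; a
    primer absent from every template is simply site-less there).
    """
    templates = excision_templates(genome, island)
    prediction: dict[tuple[str, str], dict[str, list[int]]] = {}
    for i in range(len(primers)):
        for j in range(i + 1, len(primers)):
            a, b = primers[i], primers[j]
            per_form: dict[str, list[int]] = {}
            for form, rep in templates.items():
                prods = in_silico_pcr(
                    rep, a.sequence, b.sequence,
                    max_product=max_product, max_mismatch=max_mismatch,
                )
                per_form[form] = sorted(p.product_length for p in prods)
            prediction[(a.name, b.name)] = per_form
    island.excision_prediction = prediction
    return prediction
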