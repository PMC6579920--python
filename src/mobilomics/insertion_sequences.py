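"""Insertion-sequence discovery, copy census, and composite transposons.

The discovery heuristic mirrors manual IS curation practice on annotated
genomes: transposase / mobile-element CDS are grouped by identical
translation length (multi-copy IS leave identical-length annotations), each
candidate is extracted with 1 kb of flanking sequence, and candidates are
confirmed by aligning them back to the whole genome set — an element counts
as an IS only when at least two loci match at high identity. Confirmed
elements are delimited to the maximal interval shared by all full-length
copies, then terminal inverted repeats (IRs) are sought in the terminal
windows; an element without detectable IRs is retained and flagged.

On top of the element library the module provides a per-genome copy census,
gene-disruption calls (an IS copy sitting inside a coding region, visible
either as a split CDS or as a copy contained in an intact CDS annotation),
and composite-transposon candidates: two related IS copies flanking a cargo
region, related meaning transposase amino-acid identity and IR
cross-identity above configurable floors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .align import (
    AlignmentBlock,
    KmerIndex,
    find_inverted_repeats,
    local_search,
    nucleotide_identity,
    protein_identity_coverage,
)
from ._seq import revcomp
from .genomes import GeneFeature, Genome, Replicon

__all__ = [
    "ISElement",
    "ISCopy",
    "CompositeTransposon",
    "DisruptionRecord",
    "CandidateIS",
    "MOBILE_ELEMENT_KEYWORDS",
    "INTEGRASE_KEYWORDS",
    "find_transposase_anchors",
    "mobile_annotation_counts",
    "extract_candidate",
    "confirm_multicopy",
    "delimit_element",
    "build_is_library",
    "is_census",
    "detect_gene_disruption",
    "detect_composite_transposons",
]

MOBILE_ELEMENT_KEYWORDS = (
    "transposase",
    "insertion sequence",
    "insertion element",
    "mobile element",
)
INTEGRASE_KEYWORDS = ("integrase",)


@dataclass
class CandidateIS:
    """A transposase CDS extracted with flanking sequence."""

    genome: str
    replicon_id: str
    anchor: GeneFeature
    start: int  # genome coordinate of candidate position 0 (mod length)
    sequence: str
    truncated: bool = False  # hit a linear contig edge


@dataclass
class ISCopy:
    genome: str
    replicon_id: str
    start: int
    end: int
    strand: str
    identity: float
    query_start: int = 0  # interval matched on the confirming query
    query_end: int = 0
    partial: bool = False
    element_name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ISElement:
    name: str
    source_genome: str
    transposase_locus: tuple[str, str]  # (genome, locus_tag)
    transposase_translation: str
    boundaries: tuple[int, int]  # on the source replicon
    element_sequence: str
    left_ir: str = ""
    right_ir: str = ""
    ir_mismatches: int = 0

    @property
    def has_ir(self) -> bool:
        return bool(self.left_ir)

    @property
    def length(self) -> int:
        return len(self.element_sequence)


@dataclass
class DisruptionRecord:
    genome: str
    replicon_id: str
    locus_tag: str
    product: str
    element_name: str
    copy_start: int
    copy_end: int
    insertion_offset: int  # bp from the gene start to the insertion point


@dataclass
class CompositeTransposon:
    left: ISCopy
    right: ISCopy
    cargo_start: int
    cargo_end: int
    cargo_genes: list[str] = field(default_factory=list)
    transposase_identity: float = 0.0
    ir_cross_identity: float = 0.0

    @property
    def total_span(self) -> tuple[int, int]:
        return self.left.start, self.right.end


class AmbiguousBoundariesError(ValueError):
    """Confirmed copies disagree too much to delimit one element."""


# ---------------------------------------------------------------------------
# Anchors and candidates
# ---------------------------------------------------------------------------

def _is_mobile(product: str) -> bool:
    p = product.lower()
    if any(k in p for k in INTEGRASE_KEYWORDS):
        return False  # integrases are tallied separately, not IS anchors
    return any(k in p for k in MOBILE_ELEMENT_KEYWORDS)


def find_transposase_anchors(genome: Genome) -> dict[int, list[GeneFeature]]:
    """Mobile-element CDS grouped by identical translation length.

    Groups of size >= 2 are multi-copy IS candidates; integrase annotations
    are excluded from the grouping (they are counted in the integrase tally
    instead).
    """
    groups: dict[int, list[GeneFeature]] = {}
    for _, f in genome.all_features():
        if f.kind == "CDS" and f.translation and _is_mobile(f.product):
            groups.setdefault(len(f.translation), []).append(f)
    return dict(sorted(groups.items(), reverse=True))


def mobile_annotation_counts(genome: Genome) -> dict[str, int]:
    """Counts of transposase-like and integrase annotations in a genome."""
    n_tpase = n_int = 0
    for _, f in genome.all_features():
        if f.kind != "CDS":
            continue
        p = f.product.lower()
        if any(k in p for k in INTEGRASE_KEYWORDS):
            n_int += 1
        elif any(k in p for k in MOBILE_ELEMENT_KEYWORDS):
            n_tpase += 1
    return {"transposases": n_tpase, "integrases": n_int}


def extract_candidate(anchor: GeneFeature, genome: Genome, flank: int = 1000) -> CandidateIS:
    """Extract an anchor CDS with flanking sequence (circular wrap honoured)."""
    rep = None
    for r in genome.replicons:
        if any(f is anchor or f.locus_tag == anchor.locus_tag for f in r.features):
            rep = r
            break
    if rep is None:
        raise KeyError(f"anchor {anchor.locus_tag} not found in {genome.strain}")
    n = len(rep.sequence)
    start, end = anchor.start - flank, anchor.end + flank
    truncated = False
    if rep.topology == "circular":
        seq = rep.subsequence(start, end)
        start %= n
    else:
        truncated = start < 0 or end > n
        start, end = max(0, start), min(n, end)
        seq = rep.sequence[start:end]
    return CandidateIS(genome.strain, rep.replicon_id, anchor, start, seq, truncated)


# ---------------------------------------------------------------------------
# Copy confirmation and element delimitation
# ---------------------------------------------------------------------------

def _blocks_to_loci(blocks: list[AlignmentBlock], merge_gap: int = 50):
    """Merge blocks into loci on subject coordinates (strand-aware, then
    collapsed across strands when intervals coincide)."""
    loci: list[dict] = []
    for strand in ("+", "-"):
        sel = sorted(
            (b for b in blocks if b.strand == strand), key=lambda b: b.s_start
        )
        cur = None
        for b in sel:
            if cur is not None and b.s_start - cur["s_end"] <= merge_gap:
                cur["s_end"] = max(cur["s_end"], b.s_end)
                cur["q_lo"] = min(cur["q_lo"], b.q_start)
                cur["q_hi"] = max(cur["q_hi"], b.q_end)
                cur["ident_num"] += b.identity * b.length
                cur["ident_den"] += b.length
            else:
                if cur is not None:
                    loci.append(cur)
                cur = {
                    "s_start": b.s_start,
                    "s_end": b.s_end,
                    "q_lo": b.q_start,
                    "q_hi": b.q_end,
                    "strand": strand,
                    "ident_num": b.identity * b.length,
                    "ident_den": b.length,
                }
        if cur is not None:
            loci.append(cur)
    # collapse the rare both-strand duplicate of a near-palindromic element
    loci.sort(key=lambda L: (L["s_start"], L["s_end"]))
    collapsed: list[dict] = []
    for L in loci:
        if collapsed:
            p = collapsed[-1]
            ov = min(p["s_end"], L["s_end"]) - max(p["s_start"], L["s_start"])
            if ov > 0.5 * (L["s_end"] - L["s_start"]):
                if L["ident_num"] / L["ident_den"] > p["ident_num"] / p["ident_den"]:
                    collapsed[-1] = L
                continue
        collapsed.append(L)
    return collapsed


def confirm_multicopy(
    candidate: CandidateIS,
    genomes: list[Genome],
    min_copies: int = 2,
    min_identity: float = 0.90,
    min_span: float = 0.80,
    min_block: int = 300,
    indexes: dict[str, KmerIndex] | None = None,
) -> list[ISCopy]:
    """Confirm a candidate by finding multiple high-identity loci.

    Returns the confirmed copies (the candidate's own locus included) or an
    empty list when fewer than ``min_copies`` loci share a common interval.
    ``min_span`` is measured against the shared (consensus) interval of the
    candidate, i.e. the element itself, not the flanks.
    """
    loci = []
    for g in genomes:
        for rep in g.replicons:
            idx = (indexes or {}).get(rep.replicon_id)
            blocks = local_search(
                candidate.sequence,
                rep,
                min_length=min_block,
                min_identity=min_identity,
                index=idx,
                query_id=candidate.anchor.locus_tag,
            )
            for L in _blocks_to_loci(blocks):
                L["genome"] = g.strain
                L["replicon_id"] = rep.replicon_id
                loci.append(L)
    if len(loci) < min_copies:
        return []
    # consensus: longest query interval covered by >= min_copies loci
    events: list[tuple[int, int]] = []
    for L in loci:
        events.append((L["q_lo"], 1))
        events.append((L["q_hi"], -1))
    events.sort()
    best = (0, 0)
    depth, run_start = 0, None
    for pos, delta in events:
        prev_depth = depth
        depth += delta
        if prev_depth < min_copies <= depth:
            run_start = pos
        elif prev_depth >= min_copies > depth and run_start is not None:
            if pos - run_start > best[1] - best[0]:
                best = (run_start, pos)
            run_start = None
    c_lo, c_hi = best
    c_len = c_hi - c_lo
    if c_len < min_block:
        return []
    copies = []
    for L in loci:
        ov = min(L["q_hi"], c_hi) - max(L["q_lo"], c_lo)
        if ov < 0.25 * c_len:
            continue
        copies.append(
            ISCopy(
                genome=L["genome"],
                replicon_id=L["replicon_id"],
                start=L["s_start"],
                end=L["s_end"],
                strand=L["strand"],
                identity=L["ident_num"] / L["ident_den"],
                query_start=max(L["q_lo"], 0),
                query_end=L["q_hi"],
                partial=ov < min_span * c_len,
            )
        )
    if sum(1 for c in copies if not c.partial) < min_copies:
        return []
    return copies


# IR acceptance: longer arms are required to justify mismatches, which keeps
# chance arm pairs in ~1.3 kb elements below the noise floor.
def _credible_ir(length: int, mismatches: int) -> bool:
    return length >= 10 + 2 * mismatches


def delimit_element(
    candidate: CandidateIS,
    copies: list[ISCopy],
    name: str = "IS",
    arm_min: int = 10,
    arm_max: int = 50,
    ir_max_mismatch: int = 3,
    ir_window: int = 150,
) -> ISElement:
    """Refine element boundaries to the interval shared by all full copies
    and annotate terminal inverted repeats when detectable."""
    full = [c for c in copies if not c.partial]
    if len(full) < 2:
        raise ValueError("delimit_element needs at least two full copies")
    # The source locus legitimately spans the whole candidate (element plus
    # flanks); disagreement is judged against the typical copy, comparing the
    # shared interval with the median span.
    spans = sorted(c.query_end - c.query_start for c in full)
    median_span = spans[len(spans) // 2]
    lo = max(c.query_start for c in full)
    hi = min(c.query_end for c in full)
    if hi - lo < 0.5 * median_span or hi - lo < arm_min * 2:
        raise AmbiguousBoundariesError(
            f"{name}: copies disagree by more than 50% in length "
            f"(shared [{lo}, {hi}), spans {spans})"
        )
    elem_seq = candidate.sequence[lo:hi]
    left_ir = right_ir = ""
    mism = 0
    pairs = find_inverted_repeats(
        elem_seq, arm_min=arm_min, arm_max=arm_max,
        max_mismatch=ir_max_mismatch, window=ir_window,
    )
    for p in pairs:
        if _credible_ir(p.repeat_length, p.mismatches):
            left_ir = elem_seq[p.left_start : p.left_end]
            right_ir = elem_seq[p.right_start : p.right_end]
            mism = p.mismatches
            break
    return ISElement(
        name=name,
        source_genome=candidate.genome,
        transposase_locus=(candidate.genome, candidate.anchor.locus_tag),
        transposase_translation=candidate.anchor.translation,
        boundaries=(candidate.start + lo, candidate.start + hi),
        element_sequence=elem_seq,
        left_ir=left_ir,
        right_ir=right_ir,
        ir_mismatches=mism,
    )


def build_is_library(
    genomes: list[Genome],
    flank: int = 1000,
    min_copies: int = 2,
    min_identity: float = 0.90,
    min_span: float = 0.80,
    collapse_identity: float = 0.95,
    name_prefix: str = "ISfnd",
) -> tuple[list[ISElement], dict[str, list[ISCopy]]]:
    """Full IS discovery over a genome set.

    Anchors are pooled across genomes by translation length; one candidate
    per group is confirmed and delimited; near-identical elements (either
    orientation) are collapsed at ``collapse_identity``. Returns the element
    library and the confirming copies per element name.
    """
    pooled: dict[int, list[tuple[str, GeneFeature, Genome]]] = {}
    for g in genomes:
        for length, feats in find_transposase_anchors(g).items():
            for f in feats:
                pooled.setdefault(length, []).append((g.strain, f, g))
    indexes = {
        rep.replicon_id: KmerIndex(rep.sequence)
        for g in genomes
        for rep in g.replicons
    }
    library: list[ISElement] = []
    copies_by_element: dict[str, list[ISCopy]] = {}
    counter = 1
    for length in sorted(pooled, reverse=True):
        group = sorted(pooled[length], key=lambda t: (t[0], t[1].locus_tag))
        if len(group) < 2:
            continue
        strain, anchor, g = group[0]
        cand = extract_candidate(anchor, g, flank=flank)
        copies = confirm_multicopy(
            cand, genomes, min_copies=min_copies, min_identity=min_identity,
            min_span=min_span, indexes=indexes,
        )
        if not copies:
            continue
        try:
            elem = delimit_element(cand, copies, name=f"{name_prefix}{counter}")
        except AmbiguousBoundariesError:
            continue
        dup = False
        for known in library:
            ratio = min(elem.length, known.length) / max(elem.length, known.length)
            if ratio < 0.8:
                continue
            ident = max(
                nucleotide_identity(elem.element_sequence, known.element_sequence),
                nucleotide_identity(revcomp(elem.element_sequence), known.element_sequence),
            )
            if ident >= collapse_identity:
                dup = True
                break
        if dup:
            continue
        for c in copies:
            c.element_name = elem.name
        library.append(elem)
        copies_by_element[elem.name] = copies
        counter += 1
    return library, copies_by_element


# ---------------------------------------------------------------------------
# Census, disruption, composite transposons
# ---------------------------------------------------------------------------

def is_census(
    library: list[ISElement],
    genomes: list[Genome],
    min_identity: float = 0.90,
    min_span: float = 0.80,
    indexes: dict[str, KmerIndex] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[ISCopy]]]:
    """Per-genome copy counts for each library element.

    Full copies must cover >= ``min_span`` of the element and have a locus
    length within ±20% of the element length; shorter matches are tallied
    separately as partial copies. Returns (full counts, partial counts,
    copies per element).
    """
    if indexes is None:
        indexes = {
            rep.replicon_id: KmerIndex(rep.sequence)
            for g in genomes
            for rep in g.replicons
        }
    strains = [g.strain for g in genomes]
    full = pd.DataFrame(0, index=[e.name for e in library], columns=strains)
    partial = pd.DataFrame(0, index=[e.name for e in library], columns=strains)
    copies_by_element: dict[str, list[ISCopy]] = {e.name: [] for e in library}
    for e in library:
        elen = e.length
        min_block = max(200, int(0.2 * elen))
        for g in genomes:
            for rep in g.replicons:
                blocks = local_search(
                    e.element_sequence,
                    rep,
                    min_length=min_block,
                    min_identity=min_identity,
                    index=indexes.get(rep.replicon_id),
                    query_id=e.name,
                )
                for L in _blocks_to_loci(blocks):
                    q_span = L["q_hi"] - L["q_lo"]
                    s_len = L["s_end"] - L["s_start"]
                    cp = ISCopy(
                        genome=g.strain,
                        replicon_id=rep.replicon_id,
                        start=L["s_start"],
                        end=L["s_end"],
                        strand=L["strand"],
                        identity=L["ident_num"] / L["ident_den"],
                        query_start=L["q_lo"],
                        query_end=L["q_hi"],
                        element_name=e.name,
                    )
                    if q_span >= min_span * elen and abs(s_len - elen) <= 0.2 * elen:
                        full.loc[e.name, g.strain] += 1
                    else:
                        cp.partial = True
                        partial.loc[e.name, g.strain] += 1
                    copies_by_element[e.name].append(cp)
    return full, partial, copies_by_element


def detect_gene_disruption(
    copies: list[ISCopy],
    genomes: list[Genome],
    boundary_tolerance: int = 25,
) -> list[DisruptionRecord]:
    """Call IS insertions inside coding regions.

    Two signals are recognized: (i) a copy contained in a single intact CDS
    annotation (overlap >= 90% of the copy), and (ii) a CDS split into two
    fragments with the same product abutting the copy boundaries.
    """
    by_strain = {g.strain: g for g in genomes}
    records: list[DisruptionRecord] = []
    for cp in copies:
        g = by_strain.get(cp.genome)
        if g is None:
            continue
        rep = next((r for r in g.replicons if r.replicon_id == cp.replicon_id), None)
        if rep is None:
            continue
        feats = [f for f in rep.features if f.kind == "CDS"]
        hit = None
        for f in feats:
            ov = min(f.end, cp.end) - max(f.start, cp.start)
            if ov >= 0.9 * cp.length and f.start < cp.start and f.end > cp.end:
                hit = DisruptionRecord(
                    cp.genome, cp.replicon_id, f.locus_tag, f.product,
                    cp.element_name, cp.start, cp.end, cp.start - f.start,
                )
                break
        if hit is None:
            tol = boundary_tolerance
            lefts = [f for f in feats if abs(f.end - cp.start) <= tol and f.start < cp.start]
            rights = [f for f in feats if abs(f.start - cp.end) <= tol and f.end > cp.end]
            for lf in lefts:
                for rf in rights:
                    if lf.product and lf.product == rf.product:
                        hit = DisruptionRecord(
                            cp.genome, cp.replicon_id, lf.locus_tag, lf.product,
                            cp.element_name, cp.start, cp.end, cp.start - lf.start,
                        )
                        break
                if hit:
                    break
        if hit:
            records.append(hit)
    return records


def detect_composite_transposons(
    copies: list[ISCopy],
    genomes: list[Genome],
    elements: dict[str, ISElement],
    max_cargo: int = 20000,
    min_tpase_identity: float = 0.60,
    min_ir_identity: float = 0.60,
) -> list[CompositeTransposon]:
    """Candidate composite transposons: two related IS copies flanking cargo.

    Every ordered pair of full copies on one replicon with a cargo gap of at
    most ``max_cargo`` bp is tested; the pair qualifies when the two
    elements' transposases share >= ``min_tpase_identity`` amino-acid
    identity and their IRs >= ``min_ir_identity`` nucleotide identity.
    """
    by_strain = {g.strain: g for g in genomes}
    tpase_cache: dict[tuple[str, str], float] = {}
    ir_cache: dict[tuple[str, str], float] = {}

    def _tpase_ident(a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        if key not in tpase_cache:
            ta = elements[a].transposase_translation
            tb = elements[b].transposase_translation
            tpase_cache[key] = protein_identity_coverage(ta, tb)[0] if ta and tb else 0.0
        return tpase_cache[key]

    def _ir_ident(a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        if key not in ir_cache:
            irs_a = [s for s in (elements[a].left_ir, elements[a].right_ir) if s]
            irs_b = [s for s in (elements[b].left_ir, elements[b].right_ir) if s]
            best = 0.0
            for x in irs_a:
                for y in irs_b:
                    best = max(best, nucleotide_identity(x, y))
            ir_cache[key] = best
        return ir_cache[key]

    out: list[CompositeTransposon] = []
    groups: dict[tuple[str, str], list[ISCopy]] = {}
    for cp in copies:
        if not cp.partial and cp.element_name in elements:
            groups.setdefault((cp.genome, cp.replicon_id), []).append(cp)
    for (strain, rep_id), grp in sorted(groups.items()):
        grp.sort(key=lambda c: c.start)
        g = by_strain.get(strain)
        rep = next((r for r in g.replicons if r.replicon_id == rep_id), None) if g else None
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                left, right = grp[i], grp[j]
                gap = right.start - left.end
                if gap <= 0 or gap > max_cargo:
                    continue
                ti = _tpase_ident(left.element_name, right.element_name)
                if ti < min_tpase_identity:
                    continue
                ii = _ir_ident(left.element_name, right.element_name)
                if ii < min_ir_identity:
                    continue
                cargo_genes = []
                if rep is not None:
                    cargo_genes = [
                        f.locus_tag
                        for f in rep.features
                        if f.kind == "CDS" and f.start >= left.end and f.end <= right.start
                    ]
                out.append(
                    CompositeTransposon(
                        left, right, left.end, right.start, cargo_genes, ti, ii
                    )
                )
    return out
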