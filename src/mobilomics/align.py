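"""Alignment and repeat-finding primitives.

This module provides the self-contained search machinery used by every
downstream stage:

* global protein alignment with identity/coverage statistics, used by the
  ortholog clustering thresholds (identity over alignment columns excluding
  terminal gaps; coverage measured against the longer sequence);
* a seed-and-extend local nucleotide search built on an exact k-mer index.
  Seeds are clustered by diagonal, each cluster is aligned with a banded
  bit-vector edit alignment (edlib), and the resulting column path is trimmed
  to its maximal-scoring subpath under megablast-like scores
  (match +1, mismatch -2, gap open -5, gap extend -2). Reported blocks carry
  query-forward half-open coordinates; strand '-' means the subject
  coordinates refer to the reverse complement of the query;
* interval merging of alignment blocks into contiguous regions;
* terminal inverted-repeat and flanking direct-repeat scans (exhaustive over
  the configured windows, vectorized with numpy);
* in-silico PCR on linear and circular templates with exact-3'-base matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import revcomp, validate_dna, validate_protein
from .genomes import Replicon

__all__ = [
    "AlignmentBlock",
    "RepeatPair",
    "PcrProduct",
    "AlignScores",
    "protein_identity_coverage",
    "nucleotide_identity",
    "KmerIndex",
    "local_search",
    "merge_blocks",
    "find_inverted_repeats",
    "find_direct_repeats",
    "in_silico_pcr",
]


@dataclass
class AlignScores:
    """Nucleotide scoring regime for seed-and-extend search."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    k: int = 13  # seed length


DEFAULT_SCORES = AlignScores()


@dataclass
class AlignmentBlock:
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # '+' or '-'
    identity: float  # fraction over aligned columns
    length: int  # aligned bp on the query

    def __post_init__(self) -> None:
        assert self.q_end - self.q_start >= 1, "empty block"
        assert 0.0 <= self.identity <= 1.0


@dataclass
class RepeatPair:
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    kind: str  # 'inverted' or 'direct'
    mismatches: int
    repeat_length: int


@dataclass
class PcrProduct:
    fwd_site: tuple[int, int]  # plus-strand primer site, half-open
    rev_site: tuple[int, int]  # minus-strand primer site, half-open
    product_length: int
    template_form: str  # 'linear' or 'circular'
    spans_origin: bool = False


# ---------------------------------------------------------------------------
# Protein identity / coverage
# ---------------------------------------------------------------------------

_PROT_ALIGNER: Align.PairwiseAligner | None = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        # terminal gaps are free: thresholds are about the aligned span
        new_names = (
            "open_end_insertion_score",
            "extend_end_insertion_score",
            "open_end_deletion_score",
            "extend_end_deletion_score",
        )
        old_names = (
            "target_end_open_gap_score",
            "target_end_extend_gap_score",
            "query_end_open_gap_score",
            "query_end_extend_gap_score",
        )
        names = new_names if hasattr(a, new_names[0]) else old_names
        for attr in names:
            setattr(a, attr, 0)
        _PROT_ALIGNER = a
    return _PROT_ALIGNER


def protein_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Global-align two proteins; return (identity, coverage).

    Identity is matches over alignment columns excluding terminal gaps.
    Coverage is the aligned (non-terminal-gap) span of the *longer* sequence
    divided by its length — a symmetric, conservative convention.
    """
    if not a or not b:
        raise ValueError("protein_identity_coverage requires non-empty sequences")
    a, b = a.upper().rstrip("*"), b.upper().rstrip("*")
    validate_protein(a, "first protein")
    validate_protein(b, "second protein")
    aln = _protein_aligner().align(a, b)[0]
    t_segs, q_segs = aln.aligned
    if len(t_segs) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(t_segs, q_segs):
        aligned_cols += te - ts
        matches += sum(x == y for x, y in zip(a[ts:te], b[qs:qe]))
    gap_cols = 0
    for i in range(1, len(t_segs)):
        gap_cols += t_segs[i][0] - t_segs[i - 1][1]
        gap_cols += q_segs[i][0] - q_segs[i - 1][1]
    columns = aligned_cols + gap_cols
    identity = matches / columns if columns else 0.0
    if len(a) >= len(b):
        span = t_segs[-1][1] - t_segs[0][0]
        coverage = span / len(a)
    else:
        span = q_segs[-1][1] - q_segs[0][0]
        coverage = span / len(b)
    return float(identity), float(coverage)


def nucleotide_identity(a: str, b: str) -> float:
    """Identity fraction of an end-to-end edit alignment of two DNA strings."""
    if not a or not b:
        raise ValueError("nucleotide_identity requires non-empty sequences")
    res = edlib.align(a.upper(), b.upper(), task="path", mode="NW")
    ops = _expand_cigar(res["cigar"])
    matches = sum(1 for op in ops if op == "=")
    return matches / len(ops) if ops else 0.0


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer position index over the forward strand of a sequence.

    Minus-strand queries are served by looking up the reverse complement, so
    the k-mer content of both strands is retrievable without doubling memory.
    k-mers containing N are skipped.
    """

    def __init__(self, sequence: str | Replicon, k: int = 13):
        if not 8 <= k <= 32:
            raise ValueError(f"k={k} outside supported range [8, 32]")
        seq = sequence.sequence if isinstance(sequence, Replicon) else sequence.upper()
        self.k = k
        self.length = len(seq)
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(i)
        self._index = index

    def positions(self, kmer: str, strand: str = "+") -> list[int]:
        if len(kmer) != self.k:
            raise ValueError(f"kmer length {len(kmer)} != k={self.k}")
        key = kmer if strand == "+" else revcomp(kmer)
        return self._index.get(key.upper(), [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._index.values())


# ---------------------------------------------------------------------------
# Seed-and-extend local search
# ---------------------------------------------------------------------------

def _expand_cigar(cigar: str) -> list[str]:
    ops: list[str] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.extend(ch * int(num))
            num = ""
    return ops


def _column_arrays(ops: list[str], scores: AlignScores):
    """Per-column score / consumption arrays for a cigar path.

    '=' and 'X' consume both sequences; 'I' consumes the query only and 'D'
    the subject only (edlib convention with query as first argument). Gap
    runs are charged open+extend on their first column.
    """
    n = len(ops)
    col_scores = np.empty(n, dtype=np.int32)
    dq = np.zeros(n, dtype=np.int32)
    ds = np.zeros(n, dtype=np.int32)
    is_match = np.zeros(n, dtype=bool)
    prev = ""
    open_extra = scores.gap_open
    for i, op in enumerate(ops):
        if op == "=":
            col_scores[i] = scores.match
            dq[i] = ds[i] = 1
            is_match[i] = True
        elif op == "X":
            col_scores[i] = scores.mismatch
            dq[i] = ds[i] = 1
        else:
            col_scores[i] = scores.gap_extend + (open_extra if op != prev else 0)
            if op == "I":
                dq[i] = 1
            else:
                ds[i] = 1
        prev = op
    return col_scores, dq, ds, is_match


def _best_subpath(col_scores: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring contiguous column run (Kadane); returns (lo, hi, score)."""
    cum = np.concatenate(([0], np.cumsum(col_scores)))
    best_score, best_lo, best_hi = 0, 0, 0
    min_val, min_idx = 0, 0
    for i in range(1, len(cum)):
        if cum[i - 1] < min_val:
            min_val, min_idx = cum[i - 1], i - 1
        sc = cum[i] - min_val
        if sc > best_score:
            best_score, best_lo, best_hi = sc, min_idx, i
    return best_lo, best_hi, int(best_score)


def _ungapped_end_extend(
    qseq: str, sseq: str, q: int, s: int, direction: int, scores: AlignScores, xdrop: int = 12
) -> tuple[int, int, int]:
    """Extend a block end without gaps; returns (steps, matches, columns).

    ``direction`` -1 extends leftward from (q, s) exclusive; +1 rightward
    from (q, s) inclusive. Extension stops at an x-drop and is trimmed back
    to the maximal-scoring point, so exact flanking copy boundaries are
    recovered even when the banded path scattered cost-neutral gaps.
    """
    best_gain = gain = 0
    best_d = d = 0
    matches = best_matches = 0
    while True:
        if direction < 0:
            qi, si = q - d - 1, s - d - 1
            if qi < 0 or si < 0:
                break
        else:
            qi, si = q + d, s + d
            if qi >= len(qseq) or si >= len(sseq):
                break
        if qseq[qi] == sseq[si]:
            gain += scores.match
            matches += 1
        else:
            gain += scores.mismatch
        d += 1
        if gain > best_gain:
            best_gain, best_d, best_matches = gain, d, matches
        if best_gain - gain > xdrop:
            break
    return best_d, best_matches, best_d


def _extend_cluster(
    qseq: str, sseq: str, qa: int, qb: int, sa: int, sb: int, scores: AlignScores
) -> tuple[int, int, int, int, float] | None:
    """Align padded cluster windows and trim to the best-scoring subpath."""
    res = edlib.align(qseq[qa:qb], sseq[sa:sb], task="path", mode="NW")
    if res["cigar"] is None:
        return None
    ops = _expand_cigar(res["cigar"])
    col_scores, dq, ds, is_match = _column_arrays(ops, scores)
    lo, hi, score = _best_subpath(col_scores)
    if score <= 0 or hi <= lo:
        return None
    cq = np.concatenate(([0], np.cumsum(dq)))
    cs = np.concatenate(([0], np.cumsum(ds)))
    q0, q1 = qa + int(cq[lo]), qa + int(cq[hi])
    s0, s1 = sa + int(cs[lo]), sa + int(cs[hi])
    if q1 <= q0 or s1 <= s0:
        return None
    matches = int(is_match[lo:hi].sum())
    columns = hi - lo
    # Banded edit alignment may park cost-neutral gaps against random flanks;
    # an exact ungapped sweep pins the block ends.
    dl, ml, cl = _ungapped_end_extend(qseq, sseq, q0, s0, -1, scores)
    q0, s0 = q0 - dl, s0 - dl
    dr, mr, cr = _ungapped_end_extend(qseq, sseq, q1, s1, +1, scores)
    q1, s1 = q1 + dr, s1 + dr
    matches += ml + mr
    columns += cl + cr
    ident = matches / columns if columns else 0.0
    return q0, q1, s0, s1, ident


def _cluster_seeds(
    seeds: list[tuple[int, int]], band: int, join_gap: int
) -> list[tuple[int, int, int, int]]:
    """Group (qpos, spos) seeds into diagonal clusters -> extents."""
    if not seeds:
        return []
    by_diag = sorted(seeds, key=lambda t: (t[1] - t[0], t[1]))
    clusters = []
    group: list[tuple[int, int]] = []
    d_start = None
    for q, s in by_diag:
        d = s - q
        if d_start is None or d - d_start > band:
            if group:
                clusters.extend(_split_group(group, join_gap))
            group = [(q, s)]
            d_start = d
        else:
            group.append((q, s))
    if group:
        clusters.extend(_split_group(group, join_gap))
    return clusters


def _split_group(group: list[tuple[int, int]], join_gap: int):
    group.sort(key=lambda t: t[1])
    out = []
    qlo, qhi = group[0][0], group[0][0]
    slo, shi = group[0][1], group[0][1]
    for q, s in group[1:]:
        if s - shi > join_gap:
            out.append((qlo, qhi, slo, shi))
            qlo = qhi = q
            slo = shi = s
        else:
            qlo, qhi = min(qlo, q), max(qhi, q)
            shi = s
            slo = min(slo, s)
    out.append((qlo, qhi, slo, shi))
    return out


def _contained(a: AlignmentBlock, b: AlignmentBlock) -> bool:
    return (
        a.strand == b.strand
        and a.q_start >= b.q_start
        and a.q_end <= b.q_end
        and a.s_start >= b.s_start
        and a.s_end <= b.s_end
    )


def local_search(
    query: str,
    subject: Replicon | str,
    min_length: int,
    min_identity: float,
    *,
    scores: AlignScores = DEFAULT_SCORES,
    index: KmerIndex | None = None,
    query_id: str = "query",
    subject_id: str | None = None,
    band: int = 48,
    join_gap: int = 400,
    pad: int = 64,
) -> list[AlignmentBlock]:
    """Find local alignments of ``query`` on both strands of ``subject``.

    Returns blocks with ``length >= min_length`` and ``identity >=
    min_identity``, none mutually contained. A prebuilt :class:`KmerIndex`
    of the subject can be supplied to amortize indexing across queries.
    """
    if not query:
        raise ValueError("empty query")
    if isinstance(subject, Replicon):
        sseq = subject.sequence
        sid = subject_id or subject.replicon_id
    else:
        sseq = subject.upper()
        sid = subject_id or "subject"
    if not sseq:
        raise ValueError("empty subject")
    query = query.upper()
    k = scores.k
    if min_length < k:
        raise ValueError(f"min_length {min_length} < seed size {k}")
    if index is None:
        index = KmerIndex(sseq, k)
    blocks: list[AlignmentBlock] = []
    qlen = len(query)
    for strand in ("+", "-"):
        qseq = query if strand == "+" else revcomp(query)
        seeds = []
        for i in range(0, len(qseq) - k + 1):
            kmer = qseq[i : i + k]
            if "N" in kmer:
                continue
            for j in index.positions(kmer):
                seeds.append((i, j))
        for qlo, qhi, slo, shi in _cluster_seeds(seeds, band, join_gap):
            qa, qb = max(0, qlo - pad), min(len(qseq), qhi + k + pad)
            sa, sb = max(0, slo - pad), min(len(sseq), shi + k + pad)
            ext = _extend_cluster(qseq, sseq, qa, qb, sa, sb, scores)
            if ext is None:
                continue
            q0, q1, s0, s1, ident = ext
            if q1 - q0 < min_length or ident < min_identity:
                continue
            if strand == "-":
                q0, q1 = qlen - q1, qlen - q0
            blocks.append(
                AlignmentBlock(query_id, sid, q0, q1, s0, s1, strand, ident, q1 - q0)
            )
    blocks.sort(key=lambda b: (-(b.q_end - b.q_start), b.q_start, b.s_start))
    kept: list[AlignmentBlock] = []
    for b in blocks:
        if any(_contained(b, kb) for kb in kept):
            continue
        # drop near-duplicates produced by adjacent seed clusters
        dup = False
        for kb in kept:
            if kb.strand != b.strand:
                continue
            qov = min(b.q_end, kb.q_end) - max(b.q_start, kb.q_start)
            sov = min(b.s_end, kb.s_end) - max(b.s_start, kb.s_start)
            if qov > 0.8 * b.length and sov > 0.8 * b.length:
                dup = True
                break
        if not dup:
            kept.append(b)
    kept.sort(key=lambda b: (b.q_start, b.s_start))
    return kept


def merge_blocks(
    blocks: Sequence[AlignmentBlock], max_gap: int
) -> list[tuple[int, int]]:
    """Merge query intervals of blocks separated by <= ``max_gap`` bp.

    Blocks are expected to share one (query, subject, strand) triple; output
    intervals are sorted and pairwise separated by more than ``max_gap``.
    """
    if not blocks:
        return []
    ivals = sorted((b.q_start, b.q_end) for b in blocks)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s - merged[-1][1] <= max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# Repeat scans
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_inverted_repeats(
    sequence: str,
    arm_min: int = 10,
    arm_max: int = 50,
    max_mismatch: int = 3,
    window: int = 150,
) -> list[RepeatPair]:
    """Exhaustive scan for terminal inverted-repeat arm pairs.

    The left arm must start within the first ``window`` bp and the right arm
    end within the last ``window`` bp; the right arm is the reverse
    complement of the left within ``max_mismatch``. Pairs are ranked by
    (arm length desc, mismatches asc, terminal proximity asc); arms nested
    inside an already-reported longer pair are suppressed.
    """
    n = len(sequence)
    if n < 2 * arm_min:
        return []
    window = min(window, n // 2)
    seq = sequence.upper()
    right_zone_start = max(0, n - window - arm_max)
    right_arr = _encode(seq[right_zone_start:])
    found: list[RepeatPair] = []
    for L in range(min(arm_max, n // 2), arm_min - 1, -1):
        if len(right_arr) < L:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(right_arr, L)
        starts = np.arange(len(wins)) + right_zone_start
        ends = starts + L
        valid = ends > n - window
        for i in range(0, window):
            if i + L > n:
                break
            target = _encode(revcomp(seq[i : i + L]))
            mism = (wins != target).sum(axis=1)
            ok = valid & (mism <= max_mismatch) & (starts >= i + L)
            for j, m in zip(starts[ok], mism[ok]):
                j = int(j)
                if any(
                    p.left_start <= i and p.left_end >= i + L
                    and p.right_start <= j and p.right_end >= j + L
                    for p in found
                ):
                    continue
                found.append(RepeatPair(i, i + L, j, j + L, "inverted", int(m), L))
    found.sort(
        key=lambda p: (-p.repeat_length, p.mismatches, p.left_start + (n - p.right_end))
    )
    return found


def find_direct_repeats(
    sequence: str,
    island: tuple[int, int],
    repeat_length: int = 12,
    max_mismatch: int = 0,
    window: int = 500,
) -> list[RepeatPair]:
    """Find forward-repeat pairs flanking an island interval.

    The left arm starts within ``window`` of the island start, the right arm
    ends within ``window`` of the island end. Matching cores of
    ``repeat_length`` bp are extended maximally (exact matching) in both
    directions; pairs are ranked by (repeat length desc, boundary proximity
    asc, mismatches asc).
    """
    s, e = island
    n = len(sequence)
    if not (0 <= s < e <= n):
        raise ValueError(f"island {island} outside sequence of length {n}")
    seq = sequence.upper()
    L = repeat_length
    left_lo, left_hi = max(0, s - window), min(n - L, s + window)
    right_lo, right_hi = max(0, e - window - L), min(n - L, e + window)
    if right_lo <= left_hi:  # keep arms on their own side of the island middle
        mid = (s + e) // 2
        left_hi = min(left_hi, mid - L)
        right_lo = max(right_lo, mid)
    if left_hi < left_lo or right_hi < right_lo:
        return []
    right_arr = _encode(seq[right_lo : right_hi + L])
    if len(right_arr) < L:
        return []
    wins = np.lib.stride_tricks.sliding_window_view(right_arr, L)
    starts = np.arange(len(wins)) + right_lo
    seen: set[tuple[int, int, int]] = set()
    found: list[RepeatPair] = []
    for i in range(left_lo, left_hi + 1):
        probe = _encode(seq[i : i + L])
        if len(probe) < L:
            break
        mism = (wins != probe).sum(axis=1)
        ok = (mism <= max_mismatch) & (starts >= i + L)
        for j, m in zip(starts[ok], mism[ok]):
            j = int(j)
            li, rj, length = i, j, L
            while li + length < j and rj + length < n and seq[li + length] == seq[rj + length]:
                length += 1
            while li > 0 and rj > li + length and seq[li - 1] == seq[rj - 1]:
                li -= 1
                rj -= 1
                length += 1
            key = (li, rj, length)
            if key in seen:
                continue
            seen.add(key)
            found.append(RepeatPair(li, li + length, rj, rj + length, "direct", int(m), length))
    found.sort(
        key=lambda p: (
            -p.repeat_length,
            abs(p.left_start - s) + abs(p.right_end - e),
            p.mismatches,
        )
    )
    return found


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _primer_sites(seq: str, primer: str, circular: bool, max_mismatch: int):
    """Plus and minus strand annealing sites (3'-terminal base exact)."""
    m = len(primer)
    n = len(seq)
    space = seq + seq[: m - 1] if circular else seq
    arr = _encode(space)
    if len(arr) < m:
        return [], []
    wins = np.lib.stride_tricks.sliding_window_view(arr, m)
    starts = np.arange(len(wins))

    def _scan(pattern: str, exact_pos: int):
        pat = _encode(pattern)
        mism = (wins != pat).sum(axis=1)
        exact = wins[:, exact_pos] == pat[exact_pos]
        ok = (mism <= max_mismatch) & exact
        return sorted({int(p) % n for p in starts[ok]})

    plus = _scan(primer, m - 1)  # 3' end is the rightmost base
    minus = _scan(revcomp(primer), 0)  # 3' end maps to the leftmost base
    return plus, minus


def in_silico_pcr(
    template: Replicon | str,
    fwd: str,
    rev: str,
    max_product: int = 10000,
    max_mismatch: int = 2,
    topology: str | None = None,
) -> list[PcrProduct]:
    """Predict PCR products of a primer pair on a linear or circular template.

    A product is emitted for every pair of annealing sites on opposite
    strands pointing toward each other with a product no longer than
    ``max_product``. Both primers may anneal on either strand. The 3'
    terminal base must match exactly; up to ``max_mismatch`` mismatches are
    tolerated elsewhere (annealing thermodynamics is not modelled). On a
    circular template, origin-spanning products are reported and the result
    is rotation-invariant.
    """
    if isinstance(template, Replicon):
        seq = template.sequence
        topo = template.topology
    else:
        seq = template.upper()
        topo = topology or "linear"
    for name, p in (("fwd", fwd), ("rev", rev)):
        validate_dna(p, f"{name} primer")
        if len(p) < 15:
            raise ValueError(f"{name} primer shorter than 15 nt")
    circular = topo == "circular"
    n = len(seq)
    fwd, rev = fwd.upper(), rev.upper()
    fp, fm = _primer_sites(seq, fwd, circular, max_mismatch)
    rp, rm = _primer_sites(seq, rev, circular, max_mismatch)
    products: list[PcrProduct] = []
    seen: set[tuple[int, int, int]] = set()

    def _emit(plus_start: int, plus_len: int, minus_start: int, minus_len: int) -> None:
        minus_end = minus_start + minus_len
        if circular:
            plen = ((minus_end - plus_start - 1) % n) + 1
            spans = minus_end <= plus_start or minus_end > n
        else:
            plen = minus_end - plus_start
            spans = False
        if plen < plus_len + minus_len or plen > max_product:
            return
        key = (plus_start, minus_start, plen)
        if key in seen:
            return
        seen.add(key)
        products.append(
            PcrProduct(
                fwd_site=(plus_start, plus_start + plus_len),
                rev_site=(minus_start % n, (minus_start % n) + minus_len),
                product_length=plen,
                template_form=topo,
                spans_origin=spans,
            )
        )

    for i in fp:
        for j in rm:
            _emit(i, len(fwd), j, len(rev))
    for i in rp:
        for j in fm:
            _emit(i, len(rev), j, len(fwd))
    products.sort(key=lambda p: (p.product_length, p.fwd_site))
    return products
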