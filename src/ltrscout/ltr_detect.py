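"""De novo detection of candidate LTR pairs.

An LTR retrotransposon leaves two similar direct repeats (the LTRs) bounding
the element. Detection proceeds in four stages per chromosome:

1. **Seeding** — exact ``seed_k``-mer matches between genome positions
   ``i < j`` whose spacing ``j - i`` lies within the element-length window.
   Because the two LTRs are direct repeats, seeds from a genuine pair share
   one spacing (diagonal), so seeds are grouped by spacing band.
2. **Chaining** — seeds in a band are clustered along the chromosome; each
   cluster delimits an approximate repeat.
3. **Boundary refinement** — ungapped maximal-scoring extension (match +1,
   mismatch -2) outward from the chained block; the maximal-score endpoint is
   the boundary estimate, then boundaries are snapped to the canonical
   ``TG...CA`` LTR termini when both copies agree within 3 bp.
4. **Verification** — Needleman-Wunsch global alignment of the two putative
   LTRs; the pair is kept iff identity >= ``min_similarity`` and both lengths
   lie within ``[min_len, max_len]``.

Overlapping candidates are resolved by keeping the higher
``similarity x total LTR length`` score. Output order is deterministic
(seq_id, then element start). Direct repeats are strand-symmetric, so a
single forward pass finds elements of both orientations; strand is assigned
later from PBS/domain evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np

from . import _align
from .core import GenomeSequence, GenomicInterval

#: canonical 5' and 3' LTR termini
_TERMINUS_5 = "TG"
_TERMINUS_3 = "CA"

_MISMATCH_PENALTY = 2.0
_XDROP = 20.0
_CHAIN_GAP = 1000  # max spacing between chained seeds of one repeat
_DIAG_BAND = 10  # seeds within this spacing difference share a band


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the LTR-pair search (lengths in bp, similarity in [0,1])."""

    min_len: int = 100
    max_len: int = 5000
    min_similarity: float = 0.80
    min_element_len: int = 1000
    max_element_len: int = 25000
    seed_k: int = 20

    def validate(self) -> None:
        if self.max_element_len < 2 * self.min_len:
            raise ParameterError(
                "max_element_len must be at least twice min_len "
                f"({self.max_element_len} < {2 * self.min_len})"
            )
        if self.min_len < self.seed_k:
            raise ParameterError("min_len must be >= seed_k")
        if not (0 < self.min_similarity <= 1):
            raise ParameterError("min_similarity must be in (0, 1]")


@dataclass(frozen=True)
class LTRCandidate:
    """A pair of similar direct repeats bounding a putative element."""

    seq_id: str
    five_ltr: GenomicInterval
    three_ltr: GenomicInterval
    ltr_similarity: float
    strand: str = "."

    def __post_init__(self) -> None:
        if self.five_ltr.seq_id != self.seq_id or self.three_ltr.seq_id != self.seq_id:
            raise ValueError("LTR intervals must lie on the candidate's sequence")
        if self.five_ltr.end > self.three_ltr.start:
            raise ValueError("5' LTR must precede (not overlap) 3' LTR")
        if not (0 <= self.ltr_similarity <= 1):
            raise ValueError("similarity out of [0, 1]")

    @property
    def element(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.five_ltr.start, self.three_ltr.end, self.strand
        )

    @property
    def internal(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.five_ltr.end, self.three_ltr.start, self.strand
        )


def align_ltr_pair(a: str, b: str) -> _align.PairAlignment:
    """Global (Needleman-Wunsch) alignment of an LTR pair.

    Identity counts matches over all columns, including gap columns.
    """
    return _align.global_nt(a, b)


# ---------------------------------------------------------------------------
# seeding


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Exact base-4 encoding of every k-mer (k <= 31); -1 where a window
    contains a non-ACGT character."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    window_valid = np.ones(n, dtype=bool)
    # a window is valid iff all k positions are valid
    cs = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    window_valid = (cs[k:] - cs[:-k]) == k
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    # rolling dot product via strided windows
    win = np.lib.stride_tricks.sliding_window_view(np.where(valid, codes, 0), k)
    hashes = win @ weights
    hashes[~window_valid] = -1
    return hashes


_MAX_KMER_OCCURRENCES = 25  # skip hyper-repetitive k-mers


def _seed_pairs(seq: str, params: DetectionParams) -> List[Tuple[int, int]]:
    """(i, j) positions of identical seed_k-mers with spacing inside the
    element window."""
    hashes = _kmer_hashes(seq, params.seed_k)
    if hashes.size == 0:
        return []
    order = np.argsort(hashes, kind="stable")
    sorted_h = hashes[order]
    # group boundaries of equal hashes
    starts = np.flatnonzero(np.concatenate([[True], sorted_h[1:] != sorted_h[:-1]]))
    starts = np.concatenate([starts, [sorted_h.size]])
    lo_d = max(2 * params.seed_k, params.min_element_len - params.max_len)
    hi_d = params.max_element_len
    pairs: List[Tuple[int, int]] = []
    for a, b in zip(starts[:-1], starts[1:]):
        if b - a < 2 or sorted_h[a] < 0 or b - a > _MAX_KMER_OCCURRENCES:
            continue
        pos = np.sort(order[a:b])
        for x in range(len(pos)):
            for y in range(x + 1, len(pos)):
                d = int(pos[y] - pos[x])
                if d > hi_d:
                    break
                if d >= lo_d:
                    pairs.append((int(pos[x]), d))
    return pairs


def _cluster_seeds(pairs: List[Tuple[int, int]], k: int) -> List[Tuple[int, int, int]]:
    """Group seeds into (i_start, i_end, spacing) repeat blocks.

    Seeds are bucketed into spacing bands of width ``_DIAG_BAND`` and then
    chained along the chromosome with gaps up to ``_CHAIN_GAP``.
    """
    by_band: Dict[int, List[Tuple[int, int]]] = {}
    for i, d in pairs:
        by_band.setdefault(d // _DIAG_BAND, []).append((i, d))
    blocks: List[Tuple[int, int, int]] = []
    for band in sorted(by_band):
        seeds = sorted(by_band[band])
        cur: List[Tuple[int, int]] = [seeds[0]]
        for s in seeds[1:]:
            if s[0] - cur[-1][0] <= _CHAIN_GAP:
                cur.append(s)
            else:
                blocks.append(_finish_block(cur, k))
                cur = [s]
        blocks.append(_finish_block(cur, k))
    return blocks


def _finish_block(seeds: List[Tuple[int, int]], k: int) -> Tuple[int, int, int]:
    i0 = seeds[0][0]
    i1 = max(i for i, _ in seeds) + k
    # modal spacing of the block
    ds = [d for _, d in seeds]
    d = sorted(ds)[len(ds) // 2]
    return (i0, i1, d)


# ---------------------------------------------------------------------------
# boundary refinement


def _extend(seq: str, start: int, d: int, step: int, limit: int) -> int:
    """Ungapped maximal-score extension comparing seq[p] with seq[p + d].

    Walks from ``start`` in direction ``step`` (+1/-1) while the running
    score (match +1, mismatch -2) stays within ``_XDROP`` of its maximum;
    returns the offset (in steps) of the maximal-scoring position, i.e. how
    far the repeat extends beyond ``start``.
    """
    score = 0.0
    best = 0.0
    best_off = 0
    off = 0
    p = start
    n = len(seq)
    while True:
        p += step
        q = p + d
        if p < 0 or q < 0 or p >= n or q >= n:
            break
        off += 1
        if off > limit:
            break
        score += 1.0 if seq[p] == seq[q] else -_MISMATCH_PENALTY
        if score > best:
            best = score
            best_off = off
        if best - score > _XDROP:
            break
    return best_off


_SNAP_WINDOW = 8
_SNAP_DELTAS = tuple(
    d for off in range(_SNAP_WINDOW + 1) for d in ((off, -off) if off else (0,))
)


def _snap_termini(seq: str, left: int, right: int, d: int) -> Tuple[int, int]:
    """Prefer boundaries giving canonical TG...CA termini, searching outward
    within +-``_SNAP_WINDOW`` bp (nearest offset wins).

    Agreement of both repeat copies is required first (chance snaps are
    rare outside the repeat); when no offset satisfies both — typically
    because a terminal base of the younger copy mutated — a single-copy
    terminus is accepted as fallback.
    """
    n = len(seq)

    def find(base: int, want: str, at_end: bool) -> int:
        for both in (True, False):
            for delta in _SNAP_DELTAS:
                p = base + delta
                t = p - 2 if at_end else p
                if t < 0 or t + d + 2 > n:
                    continue
                hit1 = seq[t : t + 2] == want
                hit2 = seq[t + d : t + d + 2] == want
                if (hit1 and hit2) if both else (hit1 or hit2):
                    return p
        return base

    left = find(left, _TERMINUS_5, at_end=False)
    right = find(right, _TERMINUS_3, at_end=True)
    return left, right


# ---------------------------------------------------------------------------
# top level


def find_ltr_pairs(
    genome: GenomeSequence, params: DetectionParams | None = None
) -> List[LTRCandidate]:
    """Detect candidate LTR pairs in every sequence of ``genome``.

    Deterministic: identical input and parameters give identical output.
    """
    params = params or DetectionParams()
    params.validate()
    if len(genome) == 0:
        raise ValueError("empty genome")
    out: List[LTRCandidate] = []
    for seq_id, seq in genome.items():
        out.extend(_find_in_sequence(seq_id, seq, params))
    out.sort(key=lambda c: (c.seq_id, c.element.start, c.element.end))
    return out


def _find_in_sequence(seq_id: str, seq: str, params: DetectionParams) -> List[LTRCandidate]:
    pairs = _seed_pairs(seq, params)
    if not pairs:
        return []
    raw: List[LTRCandidate] = []
    seen: set = set()
    for i0, i1, d in _cluster_seeds(pairs, params.seed_k):
        cand = _refine_and_verify(seq_id, seq, i0, i1, d, params)
        if cand is None:
            continue
        key = (cand.five_ltr.start, cand.five_ltr.end, cand.three_ltr.start)
        if key not in seen:
            seen.add(key)
            raw.append(cand)
    return _resolve_overlaps(raw)


def _refine_and_verify(
    seq_id: str, seq: str, i0: int, i1: int, d: int, params: DetectionParams
) -> LTRCandidate | None:
    limit = params.max_len - (i1 - i0)
    if limit < 0:
        return None
    left = i0 - _extend(seq, i0, d, -1, limit)
    right = i1 + _extend(seq, i1 - 1, d, +1, limit)
    left, right = _snap_termini(seq, left, right, d)
    ltr_len = right - left
    if not (params.min_len <= ltr_len <= params.max_len):
        return None
    if ltr_len > d:  # LTR copies would overlap
        return None
    element_len = d + ltr_len
    if not (params.min_element_len <= element_len <= params.max_element_len):
        return None
    a = seq[left:right]
    b = seq[left + d : right + d]
    aln = align_ltr_pair(a, b)
    if aln.identity < params.min_similarity:
        return None
    return LTRCandidate(
        seq_id=seq_id,
        five_ltr=GenomicInterval(seq_id, left, right),
        three_ltr=GenomicInterval(seq_id, left + d, right + d),
        ltr_similarity=aln.identity,
    )


def _resolve_overlaps(cands: List[LTRCandidate]) -> List[LTRCandidate]:
    """Resolve element-overlapping candidates deterministically.

    Each candidate scores similarity x total LTR length; the kept subset is
    the mutually non-overlapping set maximizing total score (weighted
    interval scheduling). Between two overlapping candidates this keeps the
    higher-scoring one, and it is robust to spurious long-range "bridge"
    repeats (e.g. between the internal cassettes of two related elements)
    that would otherwise knock out both genuine pairs flanking them.
    """

    def score(c: LTRCandidate) -> float:
        return c.ltr_similarity * (c.five_ltr.length + c.three_ltr.length)

    kept: List[LTRCandidate] = []
    from bisect import bisect_right

    by_seq: dict = {}
    for c in cands:
        by_seq.setdefault(c.seq_id, []).append(c)
    for seq_id in sorted(by_seq):
        items = sorted(by_seq[seq_id], key=lambda c: (c.element.end, c.element.start))
        ends = [c.element.end for c in items]
        n = len(items)
        # p[i]: number of candidates ending at or before items[i] starts
        p = [bisect_right(ends, items[i].element.start) for i in range(n)]
        best = [0.0] * (n + 1)
        take = [False] * n
        for i in range(n):
            include = score(items[i]) + best[p[i]]
            if include >= best[i]:
                best[i + 1] = include
                take[i] = True
            else:
                best[i + 1] = best[i]
        i = n
        chosen: List[LTRCandidate] = []
        while i > 0:
            if take[i - 1]:
                chosen.append(items[i - 1])
                i = p[i - 1]
            else:
                i -= 1
        kept.extend(chosen)
    kept.sort(key=lambda c: (c.seq_id, c.element.start))
    return kept


def candidates_to_bed(cands: Iterable[LTRCandidate]) -> str:
    """BED (0-based half-open) of element and LTR intervals, for inspection."""
    lines = []
    for n, c in enumerate(cands):
        name = f"cand{n:04d}"
        e = c.element
        lines.append(f"{e.seq_id}\t{e.start}\t{e.end}\t{name}\t0\t{c.strand}")
        lines.append(
            f"{c.seq_id}\t{c.five_ltr.start}\t{c.five_ltr.end}\t{name}_5ltr\t0\t{c.strand}"
        )
        lines.append(
            f"{c.seq_id}\t{c.three_ltr.start}\t{c.three_ltr.end}\t{name}_3ltr\t0\t{c.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
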