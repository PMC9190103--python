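"""ALE-seq evidence: per-element read counting, normalization, the
5' LTR - PBS junction signature, and activity calls.

ALE-seq libraries amplify the extrachromosomal linear DNA (eclDNA)
intermediate of retrotransposition, so reads from a genuinely active element
pile up on its 5' LTR and primer-binding site. The pipeline counts uniquely
mapped fragments per element over the custom annotation (ambiguous overlaps
discarded, paired mates count once), normalizes to reads per million
uniquely mapped fragments (RPM), counts fragments intersecting the
5' LTR - PBS junction window, and tiers elements into strong / moderate /
no activity: a strong call needs both a high normalized value and abundant
junction reads; a moderate call needs only an intermediate normalized value.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Fragment, GenomicInterval, ReadAlignment
from .io import AnnotatedElement
from .ltr_detect import ParameterError

DEFAULT_WINDOW_UP = 50
DEFAULT_WINDOW_DOWN = 30


@dataclass(frozen=True)
class ElementReadStats:
    """Per-element ALE-seq read evidence and the resulting activity call."""

    element_id: str
    raw_count: int
    normalized: float  # reads per million uniquely mapped fragments
    junction_reads: int
    call: str = "none"  # strong | moderate | none

    def __post_init__(self) -> None:
        if self.raw_count < 0 or self.junction_reads < 0 or self.normalized < 0:
            raise ValueError("negative read statistics")
        if self.call not in ("strong", "moderate", "none"):
            raise ValueError(f"invalid call {self.call!r}")


# ---------------------------------------------------------------------------
# fragments


def fragments_from_alignments(alignments: Sequence[ReadAlignment]) -> List[Fragment]:
    """Collapse mate pairs into template fragments (union span); a fragment
    is unique iff every contributing alignment is unique."""
    groups: Dict[str, List[ReadAlignment]] = {}
    for aln in alignments:
        groups.setdefault(aln.read_id, []).append(aln)
    out: List[Fragment] = []
    for rid in groups:
        alns = groups[rid]
        by_seq: Dict[str, List[ReadAlignment]] = {}
        for a in alns:
            by_seq.setdefault(a.interval.seq_id, []).append(a)
        for seq_id, sub in sorted(by_seq.items()):
            start = min(a.interval.start for a in sub)
            end = max(a.interval.end for a in sub)
            unique = all(a.is_unique for a in sub)
            out.append(Fragment(rid, GenomicInterval(seq_id, start, end), unique))
    out.sort(key=lambda f: (f.interval.seq_id, f.interval.start, f.frag_id))
    return out


def _unique_fragments(alignments_or_fragments) -> List[Fragment]:
    items = list(alignments_or_fragments)
    if items and isinstance(items[0], ReadAlignment):
        items = fragments_from_alignments(items)
    return [f for f in items if f.is_unique]


class _IntervalIndex:
    """Per-sequence sorted non-overlapping intervals with O(log n) queries."""

    def __init__(self, intervals: Sequence[Tuple[str, GenomicInterval]]):
        self._by_seq: Dict[str, Tuple[List[int], List[int], List[str]]] = {}
        per_seq: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
        for key, iv in intervals:
            per_seq.setdefault(iv.seq_id, []).append((iv, key))
        for seq_id, items in per_seq.items():
            items.sort(key=lambda x: x[0].start)
            for (a, _), (b, _) in zip(items, items[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping intervals on {seq_id}: {a} and {b}"
                    )
            self._by_seq[seq_id] = (
                [iv.start for iv, _ in items],
                [iv.end for iv, _ in items],
                [key for _, key in items],
            )

    def overlapping(self, iv: GenomicInterval) -> List[str]:
        entry = self._by_seq.get(iv.seq_id)
        if entry is None:
            return []
        starts, ends, keys = entry
        lo = bisect_right(ends, iv.start)
        hi = bisect_left(starts, iv.end)
        return keys[lo:hi]


# ---------------------------------------------------------------------------
# counting and normalization


def count_reads(
    alignments: Sequence[ReadAlignment] | Sequence[Fragment],
    elements: Sequence[AnnotatedElement],
    references: Optional[Sequence[str]] = None,
) -> Dict[str, int]:
    """Fragment counts per element.

    Only uniquely mapped fragments count; a fragment counts for an element
    iff it overlaps the element interval by >= 1 bp; a fragment overlapping
    two elements counts for neither (ambiguous). When ``references`` (the
    alignment header's sequence names) is given, every element sequence id
    must appear in it.
    """
    if references is not None:
        missing = sorted({e.interval.seq_id for e in elements} - set(references))
        if missing:
            raise ValueError(f"element sequences absent from alignments: {missing}")
    index = _IntervalIndex([(e.element_id, e.interval) for e in elements])
    counts = {e.element_id: 0 for e in elements}
    for frag in _unique_fragments(alignments):
        hits = index.overlapping(frag.interval)
        if len(hits) == 1:
            counts[hits[0]] += 1
    return counts


def normalize(counts: Dict[str, int], total_unique_mapped: int) -> Dict[str, float]:
    """Reads per million uniquely mapped fragments (RPM)."""
    if total_unique_mapped < 1:
        raise ValueError("total_unique_mapped must be >= 1")
    return {k: c * 1e6 / total_unique_mapped for k, c in counts.items()}


# ---------------------------------------------------------------------------
# junction signature


def junction_window(
    element: AnnotatedElement,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> GenomicInterval:
    """Genomic window covering the biological 5' LTR end through the PBS.

    Requires PBS evidence on the element.
    """
    if element.pbs_interval is None:
        raise ValueError(f"element {element.element_id} has no PBS evidence")
    ltr5 = element.five_ltr_bio
    pbs = element.pbs_interval
    if element.strand == "-":
        lo = pbs.start - window_down
        hi = ltr5.start + window_up
    else:
        lo = ltr5.end - window_up
        hi = pbs.end + window_down
    seq_id = element.interval.seq_id
    return GenomicInterval(seq_id, max(0, lo), hi)


def junction_signature(
    alignments: Sequence[ReadAlignment] | Sequence[Fragment],
    element: AnnotatedElement,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> int:
    """Unique fragments whose span intersects the 5' LTR - PBS junction
    window — the eclDNA-specific signal."""
    win = junction_window(element, window_up, window_down)
    frags = _unique_fragments(alignments)
    return sum(1 for f in frags if f.interval.overlaps(win))


def junction_signatures(
    fragments: Sequence[Fragment],
    elements: Sequence[AnnotatedElement],
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> Dict[str, int]:
    """Batch junction counts over pre-built fragments (sorted-array search)."""
    per_seq: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    frags = [f for f in fragments if f.is_unique]
    by_seq: Dict[str, List[Fragment]] = {}
    for f in frags:
        by_seq.setdefault(f.interval.seq_id, []).append(f)
    for seq_id, items in by_seq.items():
        starts = np.sort(np.array([f.interval.start for f in items]))
        ends = np.sort(np.array([f.interval.end for f in items]))
        per_seq[seq_id] = (starts, ends)
    out: Dict[str, int] = {}
    for e in elements:
        win = junction_window(e, window_up, window_down)
        entry = per_seq.get(win.seq_id)
        if entry is None:
            out[e.element_id] = 0
            continue
        starts, ends = entry
        n_start_before = int(np.searchsorted(starts, win.end, side="left"))
        n_end_before = int(np.searchsorted(ends, win.start, side="right"))
        out[e.element_id] = n_start_before - n_end_before
    return out


# ---------------------------------------------------------------------------
# activity calls


def call_active(
    stats: Sequence[ElementReadStats],
    strong_rpm: float,
    moderate_rpm: float,
    min_junction: int,
) -> List[ElementReadStats]:
    """Tier elements: strong needs normalized >= strong_rpm AND
    junction_reads >= min_junction; moderate needs normalized >= moderate_rpm
    (and not strong); else none. Deterministic."""
    if strong_rpm <= 0 or moderate_rpm <= 0:
        raise ParameterError("thresholds must be strictly positive")
    if strong_rpm <= moderate_rpm:
        raise ParameterError("strong_rpm must exceed moderate_rpm")
    out = []
    for s in stats:
        if s.normalized >= strong_rpm and s.junction_reads >= min_junction:
            call = "strong"
        elif s.normalized >= moderate_rpm:
            call = "moderate"
        else:
            call = "none"
        out.append(replace(s, call=call))
    return out


def compute_element_stats(
    alignments: Sequence[ReadAlignment] | Sequence[Fragment],
    elements: Sequence[AnnotatedElement],
    strong_rpm: float,
    moderate_rpm: float,
    min_junction: int,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
    references: Optional[Sequence[str]] = None,
) -> List[ElementReadStats]:
    """Full ALE-seq evidence per element: count, RPM, junction reads, call."""
    frags = _unique_fragments(alignments)
    counts = count_reads(frags, elements, references=references)
    total = len(frags)
    rpm = normalize(counts, total) if total else {k: 0.0 for k in counts}
    junctions = junction_signatures(frags, elements, window_up, window_down)
    stats = [
        ElementReadStats(
            element_id=e.element_id,
            raw_count=counts[e.element_id],
            normalized=rpm[e.element_id],
            junction_reads=junctions[e.element_id],
        )
        for e in elements
    ]
    return call_active(stats, strong_rpm, moderate_rpm, min_junction)


# ---------------------------------------------------------------------------
# coverage


def coverage_track(
    alignments: Sequence[ReadAlignment] | Sequence[Fragment],
    seq_id: str,
    seq_len: int,
) -> np.ndarray:
    """Per-base unique-fragment coverage; overlapping mates count once per
    position (fragment-union rule)."""
    cov = np.zeros(seq_len + 1, dtype=np.int64)
    for f in _unique_fragments(alignments):
        iv = f.interval
        if iv.seq_id != seq_id:
            continue
        cov[min(iv.start, seq_len)] += 1
        cov[min(iv.end, seq_len)] -= 1
    return np.cumsum(cov[:-1])
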