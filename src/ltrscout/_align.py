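"""Thin wrappers around Biopython's PairwiseAligner.

One place defines the scoring schemes used throughout:

* nucleotide global (Needleman-Wunsch): match +1, mismatch -1,
  gap open -2, gap extend -1 — used to verify and score LTR pairs.
* protein global / local (Smith-Waterman): BLOSUM62, gap open -11,
  gap extend -1 (the BLAST defaults) — used for domain scanning,
  family classification and RT distance matrices.

Identity is always matches / aligned columns, counting gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class PairAlignment:
    """A pairwise alignment as two equal-length gapped strings."""

    a: str
    b: str
    identity: float
    score: float

    @property
    def columns(self) -> int:
        return len(self.a)


@lru_cache(maxsize=1)
def _nt_global() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


@lru_cache(maxsize=2)
def _protein(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def identity_from_gapped(a: str, b: str) -> float:
    """Matches over all columns (gap columns count in the denominator)."""
    if len(a) != len(b):
        raise ValueError("gapped strings differ in length")
    if not a:
        raise ValueError("empty alignment")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def global_nt(a: str, b: str) -> PairAlignment:
    """Needleman-Wunsch on nucleotides under the package scoring scheme."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aln = _nt_global().align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairAlignment(ga, gb, identity_from_gapped(ga, gb), float(aln.score))


def global_protein(a: str, b: str) -> PairAlignment:
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aln = _protein("global").align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairAlignment(ga, gb, identity_from_gapped(ga, gb), float(aln.score))


@dataclass(frozen=True)
class LocalHit:
    """A local protein alignment of a query reference inside a target frame."""

    target_start: int  # residue coordinates in the target (frame translation)
    target_end: int
    query_start: int
    query_end: int
    score: float
    identity: float
    columns: int


def local_protein(target: str, query: str) -> LocalHit | None:
    """Best Smith-Waterman local alignment of ``query`` within ``target``.

    Returns ``None`` when no positive-scoring alignment exists.
    """
    if not target or not query:
        return None
    alns = _protein("local").align(target, query)
    try:
        aln = alns[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    matches = 0
    cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        cols += te - ts
        matches += sum(1 for x, y in zip(target[ts:te], query[qs:qe]) if x == y)
    # inter-block jumps are gap columns
    for k in range(1, len(t_blocks)):
        cols += int(t_blocks[k][0] - t_blocks[k - 1][1])
        cols += int(q_blocks[k][0] - q_blocks[k - 1][1])
    if cols == 0:
        return None
    return LocalHit(
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        score=float(aln.score),
        identity=matches / cols,
        columns=cols,
    )
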