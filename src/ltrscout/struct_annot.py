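"""Structural intactness filter for candidate LTR pairs.

A transpositionally competent LTR retrotransposon carries, besides its two
similar LTRs: a target-site duplication (TSD) flanking the element, a
primer-binding site (PBS) complementary to a tRNA 3' end just inside the
5' LTR, a polypurine tract (PPT) just inside the 3' LTR, and an ordered
protein-domain cassette (GAG, AP, INT, RT, RNaseH). This module detects each
piece of evidence, classifies elements into the Copia/Gypsy superfamilies by
pol-domain order and into families by nearest RT exemplar, and accepts a
candidate as *intact* only when every piece of evidence is present.

Detection rules and their defaults:

* TSD: the 5-bp flanks immediately outside the element match at >= 60%
  (>= 3 of 5 positions, compared positionally — no alignment at 5 bp).
* PBS: best ungapped match, within 10 bp of the 5' LTR end, between the
  element strand and the reverse complement of a supplied tRNA's 3'-terminal
  region; 8-40 bp long at >= 90% complementarity.
* PPT: longest 8-40 bp run with purine fraction >= 0.94 ending within 30 bp
  of the 3' LTR start.
* Domains: Smith-Waterman (BLOSUM62) of each six-frame translation of the
  internal region against bundled references; hits need >= 35% identity over
  >= 50 aligned columns.

Candidates are annotated on the forward orientation first; when no PBS is
found there, the reverse complement is tried (the PBS adjacent to the 5' LTR
defines element strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

from Bio.Seq import Seq

from . import _align, refs
from .age import AgeEstimate, KimuraResult
from .core import GenomeSequence, GenomicInterval, reverse_complement
from .ltr_detect import LTRCandidate, ParameterError

_PURINES = frozenset("AG")

#: rejection reason codes
NO_TSD = "NO_TSD"
NO_PBS = "NO_PBS"
NO_PPT = "NO_PPT"
NO_RT = "NO_RT"
LOW_LTR_SIMILARITY = "LOW_LTR_SIMILARITY"


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationParams:
    """Tunables of every structural detector (lengths in bp)."""

    tsd_len: int = 5
    tsd_min_homology: float = 0.60
    pbs_min: int = 8
    pbs_max: int = 40
    pbs_max_offset: int = 10
    pbs_min_complementarity: float = 0.90
    ppt_min: int = 8
    ppt_max: int = 40
    ppt_min_purine: float = 0.94
    ppt_window: int = 30
    domain_min_identity: float = 0.35
    domain_min_len: int = 50
    min_ltr_similarity: float = 0.80


@dataclass(frozen=True)
class TSDEvidence:
    left_flank: str
    right_flank: str
    homology: float


@dataclass(frozen=True)
class PBSEvidence:
    interval: GenomicInterval
    trna_id: str
    match_len: int
    offset: int
    complementarity: float


@dataclass(frozen=True)
class PPTEvidence:
    interval: GenomicInterval
    length: int
    purine_fraction: float


@dataclass(frozen=True)
class DomainHit:
    name: str
    interval: GenomicInterval
    frame: int  # -3..+3 excluding 0, relative to the internal region
    score: float
    identity: float
    protein: str  # translated element segment that matched
    ref_id: str


@dataclass
class IntactLTRRT:
    """A candidate that passed every structural filter."""

    candidate: LTRCandidate
    tsd: TSDEvidence
    pbs: PBSEvidence
    ppt: PPTEvidence
    domains: List[DomainHit]
    superfamily: str
    family: str
    strand: str = "+"
    kimura: Optional[KimuraResult] = None
    age: Optional[AgeEstimate] = None
    saturated: bool = False
    element_id: Optional[str] = None

    @property
    def interval(self) -> GenomicInterval:
        e = self.candidate.element
        return GenomicInterval(e.seq_id, e.start, e.end, self.strand)

    @property
    def rt_hit(self) -> DomainHit:
        for d in self.domains:
            if d.name == "RT":
                return d
        raise ClassificationError("RT required")


@dataclass(frozen=True)
class Rejection:
    """A candidate that failed the intactness filter, with every failed
    criterion as a reason code."""

    candidate: LTRCandidate
    reason_codes: frozenset


# ---------------------------------------------------------------------------
# individual detectors


def detect_tsd(
    genome: GenomeSequence,
    candidate: LTRCandidate,
    tsd_len: int = 5,
    min_homology: float = 0.60,
) -> Optional[TSDEvidence]:
    """Positional comparison of the ``tsd_len``-bp flanks outside the element.

    Absent (None) when homology < ``min_homology`` or a flank runs off the
    sequence edge. TSD presence is orientation-symmetric.
    """
    e = candidate.element
    seq = genome[e.seq_id]
    if e.start - tsd_len < 0 or e.end + tsd_len > len(seq):
        return None  # edge
    left = seq[e.start - tsd_len : e.start]
    right = seq[e.end : e.end + tsd_len]
    matches = sum(1 for x, y in zip(left, right) if x == y)
    homology = matches / tsd_len
    if homology < min_homology:
        return None
    return TSDEvidence(left_flank=left, right_flank=right, homology=homology)


def detect_pbs(
    genome: GenomeSequence,
    candidate: LTRCandidate,
    trnas: GenomeSequence,
    pbs_min: int = 8,
    pbs_max: int = 40,
    max_offset: int = 10,
    min_complementarity: float = 0.90,
) -> Optional[PBSEvidence]:
    """Best ungapped complementary match to a tRNA 3' end just inside the
    5' LTR, on the candidate's forward orientation.

    The genomic PBS equals the reverse complement of the tRNA's 3'-terminal
    ``L``-mer; matches are scored positionally. Best hit by (number of
    complementary bases, then complementarity, then tRNA id lexicographic —
    smaller id wins); ranking on matched bases rather than raw window length
    keeps a perfect match ahead of the same match padded with a mismatch.
    """
    if len(trnas) == 0:
        raise ParameterError("empty tRNA set")
    seq = genome[candidate.seq_id]
    region_start = candidate.five_ltr.end
    internal_len = candidate.three_ltr.start - region_start
    if internal_len <= pbs_min:
        return None
    best: Optional[PBSEvidence] = None
    best_key: Tuple = ()
    for trna_id in sorted(trnas.ids()):
        trna = trnas[trna_id]
        max_l = min(pbs_max, len(trna))
        for length in range(max_l, pbs_min - 1, -1):
            probe = reverse_complement(trna[-length:])
            for offset in range(0, max_offset + 1):
                s = region_start + offset
                e = s + length
                if e > candidate.three_ltr.start or e > len(seq):
                    continue
                window = seq[s:e]
                matches = sum(1 for x, y in zip(window, probe) if x == y)
                comp = matches / length
                if comp < min_complementarity:
                    continue
                key = (matches, comp, tuple(-ord(c) for c in trna_id))
                if best is None or key > best_key:
                    best = PBSEvidence(
                        interval=GenomicInterval(candidate.seq_id, s, e),
                        trna_id=trna_id,
                        match_len=length,
                        offset=offset,
                        complementarity=comp,
                    )
                    best_key = key
    return best


def detect_ppt(
    genome: GenomeSequence,
    candidate: LTRCandidate,
    ppt_min: int = 8,
    ppt_max: int = 40,
    min_purine: float = 0.94,
    window: int = 30,
) -> Optional[PPTEvidence]:
    """Longest purine-rich run ending within ``window`` bp of the 3' LTR
    start, on the candidate's forward orientation.

    Ties on length are broken toward the run closest to the 3' LTR.
    """
    seq = genome[candidate.seq_id]
    lo = candidate.five_ltr.end
    hi = candidate.three_ltr.start
    if hi - lo <= window:
        return None
    # prefix sums of purine indicators over the internal region
    prefix = [0]
    for c in seq[lo:hi]:
        prefix.append(prefix[-1] + (1 if c in _PURINES else 0))
    best: Optional[PPTEvidence] = None
    for length in range(min(ppt_max, hi - lo), ppt_min - 1, -1):
        if best is not None:
            break  # longest wins
        for end in range(hi, max(hi - window, lo + length) - 1, -1):
            s, e = end - length - lo, end - lo
            if s < 0:
                continue
            frac = (prefix[e] - prefix[s]) / length
            if frac >= min_purine:
                best = PPTEvidence(
                    interval=GenomicInterval(candidate.seq_id, end - length, end),
                    length=length,
                    purine_fraction=frac,
                )
                break  # closest to the LTR at this length
    return best


# ---------------------------------------------------------------------------
# domain scan


_MIN_INTERNAL_FOR_SCAN = 300


def _six_frames(internal: str) -> Dict[int, str]:
    frames: Dict[int, str] = {}
    rc = reverse_complement(internal)
    for f in (1, 2, 3):
        for sign, src in ((1, internal), (-1, rc)):
            sub = src[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sign * f] = str(Seq(sub).translate()) if sub else ""
    return frames


def _hit_interval(
    internal_iv: GenomicInterval, frame: int, res_start: int, res_end: int
) -> GenomicInterval:
    f = abs(frame)
    if frame > 0:
        s = internal_iv.start + (f - 1) + 3 * res_start
        e = internal_iv.start + (f - 1) + 3 * res_end
    else:
        e = internal_iv.end - (f - 1) - 3 * res_start
        s = internal_iv.end - (f - 1) - 3 * res_end
    return GenomicInterval(internal_iv.seq_id, s, e)


def scan_domains(
    genome: GenomeSequence,
    candidate: LTRCandidate,
    references: Optional[Dict[str, Dict[str, str]]] = None,
    min_identity: float = 0.35,
    min_aln_len: int = 50,
) -> List[DomainHit]:
    """Translated Smith-Waterman scan of the internal region.

    Six-frame translation aligned locally (BLOSUM62, affine gaps) against
    each reference protein; hits with identity >= ``min_identity`` over
    >= ``min_aln_len`` aligned columns are reported. Overlapping hits of the
    same domain name are resolved to the best score. Output ordered by
    genomic start.
    """
    if references is None:
        references = refs.domain_references()
    if not references:
        raise ValueError("missing domain reference set")
    internal_iv = candidate.internal
    internal = genome.fetch(
        GenomicInterval(internal_iv.seq_id, internal_iv.start, internal_iv.end)
    )
    if len(internal) < _MIN_INTERNAL_FOR_SCAN:
        return []
    frames = _six_frames(internal)
    raw: List[DomainHit] = []
    for frame, protein in frames.items():
        if not protein:
            continue
        for name, ref_map in references.items():
            for ref_id in sorted(ref_map):
                hit = _align.local_protein(protein, ref_map[ref_id])
                if hit is None:
                    continue
                if hit.identity < min_identity or hit.columns < min_aln_len:
                    continue
                raw.append(
                    DomainHit(
                        name=name,
                        interval=_hit_interval(
                            internal_iv, frame, hit.target_start, hit.target_end
                        ),
                        frame=frame,
                        score=hit.score,
                        identity=hit.identity,
                        protein=protein[hit.target_start : hit.target_end],
                        ref_id=ref_id,
                    )
                )
    return _resolve_domain_overlaps(raw)


def _resolve_domain_overlaps(hits: List[DomainHit]) -> List[DomainHit]:
    kept: List[DomainHit] = []
    by_name: Dict[str, List[DomainHit]] = {}
    for h in hits:
        by_name.setdefault(h.name, []).append(h)
    for name in sorted(by_name):
        group = sorted(
            by_name[name], key=lambda h: (-h.score, h.interval.start, h.ref_id)
        )
        chosen: List[DomainHit] = []
        for h in group:
            if not any(h.interval.overlaps(c.interval) for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.interval.start, h.interval.end, h.name))
    return kept


# ---------------------------------------------------------------------------
# classification


def _element_strand_from_frames(domains: List[DomainHit]) -> str:
    plus = sum(1 for d in domains if d.frame > 0)
    minus = len(domains) - plus
    return "+" if plus >= minus else "-"


def classify(
    domains: List[DomainHit], strand: Optional[str] = None
) -> Tuple[str, str]:
    """Superfamily and family from the domain cassette.

    Superfamily is read off the pol-domain order on the element strand:
    INT upstream of RT is Copia, RT upstream of INT is Gypsy, INT absent is
    unknown. Family is the nearest bundled RT exemplar by global protein
    identity, constrained to the assigned superfamily; ties break
    lexicographically. Requires an RT hit.
    """
    rts = [d for d in domains if d.name == "RT"]
    if not rts:
        raise ClassificationError("RT required")
    # when a name has several (non-overlapping) hits, the cassette position
    # of that domain is the best-scoring one — weak spurious hits must not
    # flip the pol-domain order
    rt = max(rts, key=lambda d: d.score)
    if strand is None:
        strand = _element_strand_from_frames(domains)
    ints = [d for d in domains if d.name == "INT"]
    if not ints:
        superfamily = "unknown"
    else:
        int_best = max(ints, key=lambda d: d.score)
        int_first = (int_best.interval.start < rt.interval.start) ^ (strand == "-")
        superfamily = "Copia" if int_first else "Gypsy"
    exemplars = refs.family_rt_exemplars()
    if superfamily == "Copia":
        families = refs.COPIA_FAMILIES
    elif superfamily == "Gypsy":
        families = refs.GYPSY_FAMILIES
    else:
        families = refs.ALL_FAMILIES
    best_family = None
    best_key: Tuple = ()
    for fam in sorted(families):
        ident = _align.global_protein(rt.protein, exemplars[fam]).identity
        key = (ident, tuple(-ord(c) for c in fam))
        if best_family is None or key > best_key:
            best_family, best_key = fam, key
    return superfamily, best_family


# ---------------------------------------------------------------------------
# the intactness filter


def filter_intact(
    candidate: LTRCandidate,
    tsd: Optional[TSDEvidence],
    pbs: Optional[PBSEvidence],
    ppt: Optional[PPTEvidence],
    domains: List[DomainHit],
    min_ltr_similarity: float = 0.80,
    strand: str = "+",
) -> Union[IntactLTRRT, Rejection]:
    """Accept iff TSD, PBS, PPT, an RT domain, and sufficient LTR similarity
    are all present; a rejection carries *every* failed criterion."""
    reasons = set()
    if tsd is None:
        reasons.add(NO_TSD)
    if pbs is None:
        reasons.add(NO_PBS)
    if ppt is None:
        reasons.add(NO_PPT)
    has_rt = any(d.name == "RT" for d in domains)
    if not has_rt:
        reasons.add(NO_RT)
    if candidate.ltr_similarity < min_ltr_similarity:
        reasons.add(LOW_LTR_SIMILARITY)
    if reasons:
        return Rejection(candidate=candidate, reason_codes=frozenset(reasons))
    superfamily, family = classify(domains, strand=strand)
    return IntactLTRRT(
        candidate=candidate,
        tsd=tsd,
        pbs=pbs,
        ppt=ppt,
        domains=domains,
        superfamily=superfamily,
        family=family,
        strand=strand,
    )


# ---------------------------------------------------------------------------
# orientation handling


_FLIP_MARGIN = 20


def annotate_candidate(
    genome: GenomeSequence,
    candidate: LTRCandidate,
    trnas: GenomeSequence,
    params: AnnotationParams | None = None,
) -> Union[IntactLTRRT, Rejection]:
    """Run every structural detector on a candidate, trying the forward
    orientation first and the reverse complement when no forward PBS exists.

    TSD evidence is orientation-symmetric and always computed on the forward
    strand; PBS/PPT/domain evidence from a reverse-orientation pass is mapped
    back to forward-genome coordinates with strand '-'.
    """
    params = params or AnnotationParams()
    tsd = detect_tsd(genome, candidate, params.tsd_len, params.tsd_min_homology)

    def _evidence(g: GenomeSequence, c: LTRCandidate):
        pbs = detect_pbs(
            g, c, trnas, params.pbs_min, params.pbs_max,
            params.pbs_max_offset, params.pbs_min_complementarity,
        )
        ppt = detect_ppt(
            g, c, params.ppt_min, params.ppt_max,
            params.ppt_min_purine, params.ppt_window,
        )
        domains = scan_domains(
            g, c, min_identity=params.domain_min_identity,
            min_aln_len=params.domain_min_len,
        )
        return pbs, ppt, domains

    pbs, ppt, domains = _evidence(genome, candidate)
    strand = "+"
    if pbs is None:
        flipped = _flipped_candidate(genome, candidate)
        if flipped is not None:
            fgenome, fcand, w0, w1 = flipped
            fpbs, fppt, fdomains = _evidence(fgenome, fcand)
            if fpbs is not None:
                seq_id = candidate.seq_id

                def back(iv: GenomicInterval) -> GenomicInterval:
                    return GenomicInterval(
                        seq_id, w0 + (w1 - w0) - iv.end, w0 + (w1 - w0) - iv.start, "-"
                    )

                pbs = PBSEvidence(
                    interval=back(fpbs.interval), trna_id=fpbs.trna_id,
                    match_len=fpbs.match_len, offset=fpbs.offset,
                    complementarity=fpbs.complementarity,
                )
                ppt = (
                    PPTEvidence(
                        interval=back(fppt.interval), length=fppt.length,
                        purine_fraction=fppt.purine_fraction,
                    )
                    if fppt is not None
                    else None
                )
                domains = [
                    DomainHit(
                        name=d.name, interval=back(d.interval), frame=-d.frame,
                        score=d.score, identity=d.identity, protein=d.protein,
                        ref_id=d.ref_id,
                    )
                    for d in fdomains
                ]
                domains.sort(key=lambda h: (h.interval.start, h.interval.end, h.name))
                strand = "-"
    return filter_intact(
        candidate, tsd, pbs, ppt, domains,
        min_ltr_similarity=params.min_ltr_similarity, strand=strand,
    )


def _flipped_candidate(
    genome: GenomeSequence, candidate: LTRCandidate
) -> Optional[Tuple[GenomeSequence, LTRCandidate, int, int]]:
    """Reverse-complemented local view of the candidate region.

    Returns (view genome, view candidate, window start, window end); the two
    LTRs swap roles in the view. None when the window degenerates.
    """
    seq = genome[candidate.seq_id]
    e = candidate.element
    w0 = max(0, e.start - _FLIP_MARGIN)
    w1 = min(len(seq), e.end + _FLIP_MARGIN)
    local = reverse_complement(seq[w0:w1])
    L = w1 - w0

    def loc(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(candidate.seq_id, L - (iv.end - w0), L - (iv.start - w0))

    try:
        view_cand = LTRCandidate(
            seq_id=candidate.seq_id,
            five_ltr=loc(candidate.three_ltr),
            three_ltr=loc(candidate.five_ltr),
            ltr_similarity=candidate.ltr_similarity,
        )
    except ValueError:
        return None
    view_genome = GenomeSequence({candidate.seq_id: local})
    # view coordinates are window-local: translate back via w0 + (L - x)
    return view_genome, view_cand, w0, w1
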