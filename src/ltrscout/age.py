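"""Insertion dating from LTR divergence.

At integration the two LTRs of an element are identical; they then diverge
neutrally, so the Kimura two-parameter (K2P) distance k between the aligned
LTR pair, divided by twice the per-site substitution rate r, estimates the
insertion age: T = k / (2 r). The default rate is 1.3e-8 substitutions per
site per year, the standard rate for rice intergenic DNA.

K2P separates transitions (A<->G, C<->T; proportion P) from transversions
(proportion Q) over the ungapped, N-free columns of the alignment:

    k = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Gapped columns and columns containing N are excluded from both numerator and
denominator. When 1 - 2P - Q <= 0 or 1 - 2Q <= 0 the distance is undefined
(saturation); saturated elements are flagged, not dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, TYPE_CHECKING

from .core import GenomeSequence

if TYPE_CHECKING:  # pragma: no cover
    from .struct_annot import IntactLTRRT

DEFAULT_SUBSTITUTION_RATE = 1.3e-8  # substitutions / site / year

_PURINES = frozenset("AG")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: observed divergence beyond the model's range."""


@dataclass(frozen=True)
class KimuraResult:
    """Transition/transversion proportions and K2P divergence of an LTR pair."""

    P: float
    Q: float
    k: float
    compared_sites: int

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1:
            raise ValueError("invalid P/Q proportions")
        if self.k < 0:
            raise ValueError("negative divergence")


@dataclass(frozen=True)
class AgeEstimate:
    T: float  # years
    r: float  # substitutions / site / year

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("negative age")
        if self.r <= 0:
            raise ValueError("rate must be positive")


def is_transition(x: str, y: str) -> bool:
    """A<->G or C<->T."""
    return x != y and ((x in _PURINES) == (y in _PURINES))


def kimura2p(aligned_a: str, aligned_b: str) -> KimuraResult:
    """K2P divergence over the ungapped, N-free columns of a pair alignment."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    sites = transitions = transversions = 0
    for x, y in zip(aligned_a, aligned_b):
        if x not in _VALID or y not in _VALID:
            continue  # gap or N column
        sites += 1
        if x == y:
            continue
        if is_transition(x, y):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no ungapped comparable columns")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P distance undefined at P={P:.4f}, Q={Q:.4f} (saturation)"
        )
    k = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    if k == 0.0:
        k = 0.0  # normalize -0.0 when P = Q = 0
    return KimuraResult(P=P, Q=Q, k=k, compared_sites=sites)


def insertion_age(k: float, r: float = DEFAULT_SUBSTITUTION_RATE) -> AgeEstimate:
    """T = k / (2 r), in years."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    return AgeEstimate(T=k / (2.0 * r), r=r)


def date_element(
    genome: GenomeSequence,
    element: "IntactLTRRT",
    r: float = DEFAULT_SUBSTITUTION_RATE,
) -> Tuple[Optional[KimuraResult], Optional[AgeEstimate], bool]:
    """Align an element's LTR pair and date the insertion.

    Returns ``(kimura, age, saturated)``; a saturated pair yields
    ``(None, None, True)`` — the element is reported, its age undefined.
    """
    from .ltr_detect import align_ltr_pair  # local import avoids a cycle

    cand = element.candidate
    a = genome.fetch(cand.five_ltr)
    b = genome.fetch(cand.three_ltr)
    aln = align_ltr_pair(a, b)
    try:
        kim = kimura2p(aln.a, aln.b)
    except SaturationError:
        return None, None, True
    return kim, insertion_age(kim.k, r), False
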