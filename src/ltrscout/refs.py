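"""Bundled reference sequences: domain consensus proteins, per-family RT
exemplars, and a small tRNA set for PBS screening.

All sequences here are SYNTHETIC. They are generated deterministically from a
fixed internal seed so that classification ("nearest RT exemplar") and the
simulator (which builds its coding cassettes from the same exemplars) agree
across runs and machines. They stand in for curated domain databases, which
cannot be redistributed with the package; users with their own references can
pass them anywhere a reference set is accepted.

Domain vocabulary follows the canonical LTR retrotransposon cassette:
GAG (capsid), AP (aspartic protease), INT (integrase), RT (reverse
transcriptase), RNaseH. Copia-superfamily elements carry INT upstream of RT;
Gypsy-superfamily elements carry RT/RNaseH upstream of INT.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, Tuple

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DOMAIN_NAMES: Tuple[str, ...] = ("GAG", "AP", "INT", "RT", "RNaseH")

DOMAIN_LENGTHS = {"GAG": 150, "AP": 100, "INT": 200, "RT": 250, "RNaseH": 130}

COPIA_FAMILIES: Tuple[str, ...] = ("Oryco", "Retrofit", "Sire", "Tork")
GYPSY_FAMILIES: Tuple[str, ...] = ("Crm", "Del", "Reina", "Tat")
ALL_FAMILIES: Tuple[str, ...] = COPIA_FAMILIES + GYPSY_FAMILIES

#: pol-region domain order that distinguishes the two superfamilies
DOMAIN_ORDER = {
    "Copia": ("GAG", "AP", "INT", "RT", "RNaseH"),
    "Gypsy": ("GAG", "AP", "RT", "RNaseH", "INT"),
}

# Fixed internal seed for the synthetic reference set; changing it changes the
# bundled references, so it is a constant, not a knob.
_REF_SEED = 761042

# Per-family divergence from the superfamily RT backbone: fraction of
# positions substituted. Keeps within-superfamily exemplars ~55-60% identical
# and elements built at >=90% of an exemplar unambiguously closest to it.
_FAMILY_DIVERGENCE = 0.25


def superfamily_of(family: str) -> str:
    if family in COPIA_FAMILIES:
        return "Copia"
    if family in GYPSY_FAMILIES:
        return "Gypsy"
    raise KeyError(f"unknown family {family!r}")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, length)])


def mutate_protein(protein: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute ``fraction`` of positions with a different residue."""
    n = len(protein)
    k = int(round(fraction * n))
    sites = rng.choice(n, size=k, replace=False)
    chars = list(protein)
    for s in sites:
        choices = [a for a in AMINO_ACIDS if a != chars[s]]
        chars[s] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


@lru_cache(maxsize=1)
def _reference_bundle():
    rng = np.random.default_rng(_REF_SEED)
    backbone = {
        sf: {name: _random_protein(rng, DOMAIN_LENGTHS[name]) for name in DOMAIN_NAMES}
        for sf in ("Copia", "Gypsy")
    }
    exemplars = {}
    for family in ALL_FAMILIES:
        base = backbone[superfamily_of(family)]["RT"]
        exemplars[family] = mutate_protein(base, _FAMILY_DIVERGENCE, rng)
    return backbone, exemplars


def domain_references() -> Dict[str, Dict[str, str]]:
    """Reference proteins per domain name: ``{domain: {ref_id: protein}}``.

    RT carries one exemplar per family so that diverged family members still
    reach the reporting thresholds of the translated domain scan.
    """
    backbone, exemplars = _reference_bundle()
    refs: Dict[str, Dict[str, str]] = {}
    for name in DOMAIN_NAMES:
        if name == "RT":
            refs[name] = {f"RT:{fam}": seq for fam, seq in exemplars.items()}
        else:
            refs[name] = {
                f"{name}:Copia": backbone["Copia"][name],
                f"{name}:Gypsy": backbone["Gypsy"][name],
            }
    return refs


def family_rt_exemplars() -> Dict[str, str]:
    """RT protein exemplar per family (synthetic), for nearest-exemplar
    classification and as simulator cassette material."""
    return dict(_reference_bundle()[1])


def superfamily_cassette(family: str) -> Tuple[Tuple[str, str], ...]:
    """Ordered (domain name, protein) cassette for an element of ``family``."""
    backbone, exemplars = _reference_bundle()
    sf = superfamily_of(family)
    out = []
    for name in DOMAIN_ORDER[sf]:
        out.append((name, exemplars[family] if name == "RT" else backbone[sf][name]))
    return tuple(out)


@lru_cache(maxsize=1)
def trna_set() -> Dict[str, str]:
    """Small synthetic tRNA set (76 nt, CCA 3' end) for PBS screening."""
    rng = np.random.default_rng(_REF_SEED + 1)
    names = ("tRNA-Met-syn", "tRNA-Lys-syn", "tRNA-Trp-syn",
             "tRNA-Gly-syn", "tRNA-Asn-syn", "tRNA-Ser-syn")
    bases = np.array(list("ACGT"))
    out = {}
    for name in names:
        body = "".join(bases[rng.integers(0, 4, 73)])
        out[name] = body + "CCA"
    return out
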