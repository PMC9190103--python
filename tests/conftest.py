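"""Shared fixtures: small simulated genomes and their annotations.

Heavy scenario fixtures are session-scoped so the structural-annotation
pipeline runs once per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ltrscout import pipeline, refs
from ltrscout.config import RunConfig
from ltrscout.core import GenomeSequence
from ltrscout.simulate import SimulationConfig, build_genome

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


#: the 2-Mb annotation-recovery scenario: 30 intact (mixed families and
#: divergences) + 20 decoys across the three decoy classes
ANNOTATION_SCENARIO = SimulationConfig(
    seed=1,
    chrom_lengths=(("chr1", 1_000_000), ("chr2", 1_000_000)),
    n_intact=30,
    n_solo_ltr=7,
    n_truncated=7,
    n_no_tsd=6,
    n_background_fragments=0,
)


@pytest.fixture(scope="session")
def trnas() -> GenomeSequence:
    return GenomeSequence(refs.trna_set())


@pytest.fixture(scope="session")
def annotation_scenario():
    """(genome, truth) of the 2-Mb 30-intact/20-decoy scenario."""
    return build_genome(ANNOTATION_SCENARIO)


@pytest.fixture(scope="session")
def annotated_scenario(annotation_scenario, trnas):
    """Full pipeline result on the annotation scenario (runs once)."""
    genome, truth = annotation_scenario
    result = pipeline.annotate_genome(genome, trnas, RunConfig())
    return genome, truth, result


@pytest.fixture(scope="session")
def tiny_element_genome():
    """A 150-kb single-chromosome genome carrying two intact elements
    (one Copia-order, one Gypsy-order) and no decoys."""
    cfg = SimulationConfig(
        seed=40,
        chrom_lengths=(("chr1", 150_000),),
        n_intact=2,
        family_mix=("Oryco", "Tat"),
        divergence_levels=(0.0, 0.01),
        n_background_fragments=0,
        n_active=0,
    )
    return build_genome(cfg), cfg


def match_truth(elements, truth_element, tol=5):
    """The annotated element matching a truth element within ``tol`` bp."""
    for el in elements:
        iv = el.interval
        if (
            iv.seq_id == truth_element.interval.seq_id
            and abs(iv.start - truth_element.interval.start) <= tol
            and abs(iv.end - truth_element.interval.end) <= tol
        ):
            return el
    return None
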