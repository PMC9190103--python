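import math

import numpy as np
import pytest

from ltrscout import age, refs
from ltrscout.core import GenomeSequence, reverse_complement
from ltrscout.simulate import (
    SimulationConfig,
    TruthSet,
    build_genome,
    generate_aleseq_reads,
    mutate_k2p,
    truth_to_annotated,
)

SMALL = SimulationConfig(
    seed=3,
    chrom_lengths=(("chr1", 400_000),),
    n_intact=8,
    n_solo_ltr=2,
    n_truncated=2,
    n_no_tsd=2,
    n_active=2,
    n_junction_fragments=50,
    n_background_fragments=2000,
)


class TestMutateK2P:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(0)
        s = "ACGT" * 100
        assert mutate_k2p(s, 0.0, 2.0, rng) == s

    def test_estimator_round_trip_within_three_standard_errors(self):
        rng = np.random.default_rng(1)
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        m = mutate_k2p(s, 0.02, 2.0, rng)
        res = age.kimura2p(s, m)
        se = math.sqrt(0.02 / 10_000)  # Poisson-scale error on k-hat
        assert abs(res.k - 0.02) < 3 * se

    def test_transition_transversion_ratio_follows_kappa(self):
        """With kappa = alpha/beta = 4 the expected observed ts:tv ratio is
        kappa/2 = 2 (two transversion targets per transition target)."""
        rng = np.random.default_rng(2)
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200_000)])
        m = mutate_k2p(s, 0.05, 4.0, rng)
        res = age.kimura2p(s, m)
        assert res.P / res.Q == pytest.approx(2.0, rel=0.1)

    def test_saturation_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="saturation"):
            mutate_k2p("ACGT" * 100, 50.0, 2.0, rng)

    def test_n_positions_left_untouched(self):
        rng = np.random.default_rng(4)
        assert mutate_k2p("NNNN", 0.5, 2.0, rng) == "NNNN"


class TestBuildGenome:
    def test_zero_divergence_element_has_identical_ltrs(self):
        cfg = SimulationConfig(
            seed=5, chrom_lengths=(("chr1", 100_000),), n_intact=1,
            divergence_levels=(0.0,), n_background_fragments=0, n_active=0,
        )
        genome, truth = build_genome(cfg)
        te = truth.intact()[0]
        assert genome.fetch(te.ltr5) == genome.fetch(te.ltr3)

    def test_truth_entries_are_complete_and_disjoint(self):
        genome, truth = build_genome(SMALL)
        intact = truth.intact()
        assert len(intact) == SMALL.n_intact
        assert len(truth.decoys()) == 6
        ivs = sorted((t.interval.seq_id, t.interval.start, t.interval.end)
                     for t in truth.elements)
        for a, b in zip(ivs, ivs[1:]):
            assert a[0] != b[0] or a[2] <= b[1]

    def test_pbs_is_reverse_complement_of_trna_three_prime_end(self):
        genome, truth = build_genome(SMALL)
        trnas = refs.trna_set()
        for te in truth.intact():
            planted = genome.fetch(te.pbs)
            assert planted == reverse_complement(trnas[te.trna_id][-12:])

    def test_tsd_duplicated_on_both_flanks_of_intact_elements(self):
        genome, truth = build_genome(SMALL)
        for te in truth.intact():
            seq = genome[te.interval.seq_id]
            left = seq[te.interval.start - 5 : te.interval.start]
            right = seq[te.interval.end : te.interval.end + 5]
            assert left == right == te.tsd

    def test_no_tsd_decoy_flanks_fully_mismatch(self):
        genome, truth = build_genome(SMALL)
        found = False
        for te in truth.decoys():
            if te.decoy_class != "no_tsd":
                continue
            found = True
            seq = genome[te.interval.seq_id]
            left = seq[te.interval.start - 5 : te.interval.start]
            right = seq[te.interval.end : te.interval.end + 5]
            assert all(x != y for x, y in zip(left, right))
        assert found

    def test_ltr_termini_are_canonical(self):
        genome, truth = build_genome(SMALL)
        te = truth.intact()[0]
        five = genome.fetch(te.ltr5)
        assert five.startswith("TG") and five.endswith("CA")

    def test_genome_too_small_errors(self):
        cfg = SimulationConfig(
            seed=6, chrom_lengths=(("chr1", 5_000),), n_intact=10,
            n_background_fragments=0, n_active=0,
        )
        with pytest.raises(ValueError, match="too small"):
            build_genome(cfg)

    def test_unknown_active_id_errors(self):
        cfg = SimulationConfig(
            seed=7, chrom_lengths=(("chr1", 100_000),), n_intact=1,
            active_ids=("nope",), n_background_fragments=0,
        )
        with pytest.raises(ValueError, match="active_ids"):
            build_genome(cfg)


class TestGenerateReads:
    def test_planted_junction_fragment_counts(self):
        genome, truth = build_genome(SMALL)
        reads = generate_aleseq_reads(genome, truth, SMALL)
        active = [e for e in truth.elements if e.active]
        assert len(active) == 2
        for e in active:
            n = sum(
                1 for f, src in truth.fragment_sources.items() if src == e.element_id
            )
            assert n == SMALL.n_junction_fragments
        n_bg = sum(1 for src in truth.fragment_sources.values() if src == "background")
        assert n_bg == SMALL.n_background_fragments

    def test_junction_fragments_span_ltr_pbs_junction(self):
        genome, truth = build_genome(SMALL)
        reads = generate_aleseq_reads(genome, truth, SMALL)
        by_id = {e.element_id: e for e in truth.elements}
        for f in reads.fragments:
            src = truth.fragment_sources[f.frag_id]
            if src == "background":
                continue
            e = by_id[src]
            assert f.interval.start >= e.ltr5.start
            assert f.interval.start < e.ltr5.end
            assert f.interval.end >= e.pbs.end
            assert f.interval.length <= SMALL.max_template

    def test_zero_active_elements_gives_background_only(self):
        cfg = SimulationConfig(
            seed=8, chrom_lengths=(("chr1", 200_000),), n_intact=3, n_active=0,
            n_background_fragments=100,
        )
        genome, truth = build_genome(cfg)
        reads = generate_aleseq_reads(genome, truth, cfg)
        assert set(truth.fragment_sources.values()) == {"background"}
        assert len(reads.fragments) == 100


class TestDeterminismAndSerialization:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        outs = []
        for run in ("a", "b"):
            genome, truth = build_genome(SMALL)
            reads = generate_aleseq_reads(genome, truth, SMALL)
            sam = tmp_path / f"{run}.sam"
            reads.write_sam(sam)
            outs.append(
                (
                    "".join(f">{n}\n{s}\n" for n, s in genome.items()),
                    truth.to_json(),
                    sam.read_bytes(),
                )
            )
        assert outs[0] == outs[1]

    def test_truth_set_json_round_trip_is_lossless(self):
        genome, truth = build_genome(SMALL)
        generate_aleseq_reads(genome, truth, SMALL)
        back = TruthSet.from_json(truth.to_json())
        assert back.to_json() == truth.to_json()
        assert back.elements == truth.elements
        assert back.fragment_sources == truth.fragment_sources

    def test_sam_round_trip_preserves_fragment_structure(self, tmp_path):
        from ltrscout import io as lio
        from ltrscout.aleseq import fragments_from_alignments

        cfg = SimulationConfig(
            seed=9, chrom_lengths=(("chr1", 150_000),), n_intact=2, n_active=1,
            n_junction_fragments=20, n_background_fragments=200,
        )
        genome, truth = build_genome(cfg)
        reads = generate_aleseq_reads(genome, truth, cfg)
        sam = tmp_path / "truth.sam"
        reads.write_sam(sam)
        parsed = lio.read_alignments(sam)
        frags = fragments_from_alignments(parsed)
        want = {
            (f.interval.seq_id, f.interval.start, f.interval.end)
            for f in reads.fragments
        }
        got = {(f.interval.seq_id, f.interval.start, f.interval.end) for f in frags}
        assert got == want
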