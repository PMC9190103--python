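import itertools

import numpy as np
import pytest

from ltrscout import refs, struct_annot
from ltrscout.core import GenomeSequence, GenomicInterval, reverse_complement
from ltrscout.ltr_detect import LTRCandidate, ParameterError
from ltrscout.struct_annot import (
    LOW_LTR_SIMILARITY,
    NO_PBS,
    NO_PPT,
    NO_RT,
    NO_TSD,
    AnnotationParams,
    DomainHit,
    IntactLTRRT,
    PBSEvidence,
    PPTEvidence,
    Rejection,
    TSDEvidence,
    annotate_candidate,
    classify,
    detect_pbs,
    detect_ppt,
    detect_tsd,
    filter_intact,
    scan_domains,
)

from conftest import match_truth


def _candidate(seq, ltr5, ltr3, sim=1.0, seq_id="c1"):
    return LTRCandidate(
        seq_id=seq_id,
        five_ltr=GenomicInterval(seq_id, *ltr5),
        three_ltr=GenomicInterval(seq_id, *ltr3),
        ltr_similarity=sim,
    )


def _genome_with_flanks(left, right, core_len=300):
    rng = np.random.default_rng(0)
    core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, core_len)])
    seq = "T" * 20 + left + core + right + "T" * 20
    start = 20 + len(left)
    return GenomeSequence({"c1": seq}), start, start + core_len


class TestDetectTSD:
    @pytest.mark.parametrize(
        "left,right,expected_homology",
        [("ACGTA", "ACGTA", 1.0), ("ACGTA", "ACGAA", 0.8)],
    )
    def test_matching_flanks_detected(self, left, right, expected_homology):
        genome, s, e = _genome_with_flanks(left, right)
        cand = _candidate(None, (s, s + 100), (e - 100, e))
        tsd = detect_tsd(genome, cand)
        assert tsd is not None
        assert tsd.homology == pytest.approx(expected_homology)
        assert (tsd.left_flank, tsd.right_flank) == (left, right)

    def test_dissimilar_flanks_absent(self):
        genome, s, e = _genome_with_flanks("ACGTA", "TGCCG")
        cand = _candidate(None, (s, s + 100), (e - 100, e))
        assert detect_tsd(genome, cand) is None

    def test_element_at_sequence_edge_absent(self):
        g = GenomeSequence({"c1": "ACGT" * 100})
        cand = _candidate(None, (0, 100), (300, 400))
        assert detect_tsd(g, cand) is None


class TestDetectPBS:
    def _setup(self, offset, match_len=12, trna_idx=0):
        trnas = GenomeSequence(refs.trna_set())
        trna_id = sorted(trnas.ids())[trna_idx]
        pbs = reverse_complement(trnas[trna_id][-match_len:])
        rng = np.random.default_rng(1)
        filler = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        seq = "T" * 200 + "A" * offset + pbs + filler + "T" * 200
        cand = _candidate(None, (100, 200), (len(seq) - 200, len(seq) - 100))
        return GenomeSequence({"c1": seq}), cand, trnas, trna_id

    def test_planted_exact_complement_found(self):
        genome, cand, trnas, trna_id = self._setup(offset=2)
        pbs = detect_pbs(genome, cand, trnas)
        assert pbs is not None
        assert pbs.match_len == 12
        assert pbs.offset == 2
        assert pbs.trna_id == trna_id

    def test_random_internal_region_has_no_match(self):
        """A region exhaustively verified to lack any >= 8-nt complementary
        run must come back PBS-absent."""
        trnas = GenomeSequence(refs.trna_set())
        rng = np.random.default_rng(99)
        for _ in range(50):
            filler = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
            seq = "T" * 200 + filler + "T" * 200
            window = filler[: 10 + 40]
            # exhaustive scan oracle over every tRNA suffix and offset
            found = False
            for tid in trnas.ids():
                for L in range(8, 41):
                    probe = reverse_complement(trnas[tid][-L:])
                    for off in range(0, 11):
                        seg = window[off : off + L]
                        if len(seg) < L:
                            continue
                        m = sum(1 for x, y in zip(seg, probe) if x == y)
                        if m / L >= 0.90:
                            found = True
            if found:
                continue  # resample: this filler does contain a chance match
            cand = _candidate(None, (100, 200), (len(seq) - 200, len(seq) - 100))
            assert detect_pbs(GenomeSequence({"c1": seq}), cand, trnas) is None
            return
        pytest.fail("no chance-match-free filler found in 50 draws")

    def test_offset_beyond_window_excluded(self):
        genome, cand, trnas, _ = self._setup(offset=11)
        assert detect_pbs(genome, cand, trnas, max_offset=10) is None

    def test_empty_trna_set_is_parameter_error(self):
        genome, cand, trnas, _ = self._setup(offset=0)
        with pytest.raises(ParameterError, match="tRNA"):
            detect_pbs(genome, cand, GenomeSequence({}))


class TestDetectPPT:
    def _cand_with_tail(self, tail):
        rng = np.random.default_rng(2)
        filler = "".join(np.array(list("CT"))[rng.integers(0, 2, 400)])
        seq = "T" * 200 + filler + tail + "T" * 200
        e = len(seq) - 200
        cand = _candidate(None, (100, 200), (e, e + 100))
        return GenomeSequence({"c1": seq}), cand, e

    def test_pure_purine_run_found(self):
        genome, cand, e = self._cand_with_tail("GAGAGAAAGGGA")
        ppt = detect_ppt(genome, cand)
        assert ppt is not None
        assert ppt.length == 12
        assert ppt.purine_fraction == 1.0
        assert ppt.interval.end == e

    def test_run_below_minimum_length_absent(self):
        genome, cand, _ = self._cand_with_tail("GAGAGA")  # 6 < ppt_min
        assert detect_ppt(genome, cand) is None

    def test_purine_fraction_floor_is_enforced(self):
        # 11/12 purines = 0.917 < 0.94
        genome, cand, _ = self._cand_with_tail("GAGAGACAGAGA")
        ppt = detect_ppt(genome, cand, min_purine=0.94)
        assert ppt is None or ppt.purine_fraction >= 0.94 and ppt.length < 12


class TestScanDomains:
    def test_planted_cassette_recovered_in_order(self, tiny_element_genome):
        (genome, truth), _ = tiny_element_genome
        te = truth.intact()[0]
        cand = _candidate(
            None,
            (te.ltr5.start, te.ltr5.end),
            (te.ltr3.start, te.ltr3.end),
            seq_id=te.interval.seq_id,
        )
        hits = scan_domains(genome, cand)
        strong = [h for h in hits if h.identity > 0.9]
        assert [h.name for h in strong] == [n for n, _ in te.domains]
        for h, (_, iv) in zip(strong, te.domains):
            assert h.interval.start == iv.start
            assert h.interval.end == iv.end

    def test_random_internal_region_hits_respect_floors(self):
        rng = np.random.default_rng(8)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        g = GenomeSequence({"c1": "T" * 200 + seq + "T" * 200})
        cand = _candidate(None, (100, 200), (3200, 3300))
        for h in scan_domains(g, cand):
            assert h.identity >= 0.35
        # and any hit is rare: strong hits are impossible on random sequence
        assert all(h.identity < 0.6 for h in scan_domains(g, cand))

    def test_missing_reference_set_errors(self, tiny_element_genome):
        (genome, truth), _ = tiny_element_genome
        te = truth.intact()[0]
        cand = _candidate(
            None,
            (te.ltr5.start, te.ltr5.end),
            (te.ltr3.start, te.ltr3.end),
            seq_id=te.interval.seq_id,
        )
        with pytest.raises(ValueError, match="reference"):
            scan_domains(genome, cand, references={})


def _hit(name, start, end, frame=1, score=100.0, protein="M" * 60):
    return DomainHit(
        name=name,
        interval=GenomicInterval("c1", start, end),
        frame=frame,
        score=score,
        identity=0.95,
        protein=protein,
        ref_id=f"{name}:x",
    )


class TestClassify:
    def _cassette(self, order, rt_protein):
        hits = []
        pos = 0
        for name in order:
            protein = rt_protein if name == "RT" else "M" * 60
            hits.append(_hit(name, pos, pos + 300, protein=protein))
            pos += 300
        return hits

    def test_int_before_rt_is_copia(self):
        rt = refs.family_rt_exemplars()["Oryco"]
        sf, fam = classify(self._cassette(("GAG", "AP", "INT", "RT", "RNaseH"), rt))
        assert sf == "Copia"

    def test_rt_before_int_is_gypsy(self):
        rt = refs.family_rt_exemplars()["Tat"]
        sf, fam = classify(self._cassette(("GAG", "AP", "RT", "RNaseH", "INT"), rt))
        assert sf == "Gypsy"

    def test_family_is_nearest_exemplar(self):
        rng = np.random.default_rng(5)
        rt = refs.mutate_protein(refs.family_rt_exemplars()["Oryco"], 0.05, rng)
        sf, fam = classify(self._cassette(("GAG", "AP", "INT", "RT", "RNaseH"), rt))
        assert (sf, fam) == ("Copia", "Oryco")

    def test_no_int_gives_unknown_superfamily(self):
        rt = refs.family_rt_exemplars()["Tork"]
        sf, _ = classify(self._cassette(("GAG", "AP", "RT", "RNaseH"), rt))
        assert sf == "unknown"

    def test_rt_required(self):
        with pytest.raises(struct_annot.ClassificationError, match="RT"):
            classify(self._cassette(("GAG", "AP", "INT"), "M" * 60))

    def test_strand_invariance_on_reverse_complemented_genome(
        self, tiny_element_genome, trnas
    ):
        """Reverse-complementing the genome flips coordinates but not the
        superfamily/family assignment."""
        (genome, truth), _ = tiny_element_genome
        te = truth.intact()[0]
        L = len(genome[te.interval.seq_id])
        rc = GenomeSequence(
            {te.interval.seq_id: reverse_complement(genome[te.interval.seq_id])}
        )
        fwd_cand = _candidate(
            None, (te.ltr5.start, te.ltr5.end), (te.ltr3.start, te.ltr3.end),
            seq_id=te.interval.seq_id,
        )
        rc_cand = _candidate(
            None,
            (L - te.ltr3.end, L - te.ltr3.start),
            (L - te.ltr5.end, L - te.ltr5.start),
            seq_id=te.interval.seq_id,
        )
        fwd = annotate_candidate(genome, fwd_cand, trnas)
        rev = annotate_candidate(rc, rc_cand, trnas)
        assert isinstance(fwd, IntactLTRRT) and isinstance(rev, IntactLTRRT)
        assert fwd.strand == "+" and rev.strand == "-"
        assert (fwd.superfamily, fwd.family) == (rev.superfamily, rev.family)


class TestFilterIntact:
    def _evidence(self):
        tsd = TSDEvidence("ACGTA", "ACGTA", 1.0)
        pbs = PBSEvidence(GenomicInterval("c1", 210, 222), "t1", 12, 2, 1.0)
        ppt = PPTEvidence(GenomicInterval("c1", 950, 962), 12, 1.0)
        rt = refs.family_rt_exemplars()["Oryco"]
        domains = [
            _hit("GAG", 300, 500),
            _hit("AP", 500, 600),
            _hit("INT", 600, 700),
            _hit("RT", 700, 850, protein=rt),
            _hit("RNaseH", 850, 950),
        ]
        return tsd, pbs, ppt, domains

    def test_conjunction_over_all_presence_combinations(self):
        """filter_intact accepts exactly when every detector accepted:
        enumerate all 2^4 presence/absence combinations."""
        cand = _candidate(None, (100, 200), (1000, 1100))
        tsd, pbs, ppt, domains = self._evidence()
        no_rt = [d for d in domains if d.name != "RT"]
        for has_tsd, has_pbs, has_ppt, has_rt in itertools.product(
            (True, False), repeat=4
        ):
            result = filter_intact(
                cand,
                tsd if has_tsd else None,
                pbs if has_pbs else None,
                ppt if has_ppt else None,
                domains if has_rt else no_rt,
            )
            should_accept = has_tsd and has_pbs and has_ppt and has_rt
            assert isinstance(result, IntactLTRRT) == should_accept
            if not should_accept:
                expected = set()
                if not has_tsd:
                    expected.add(NO_TSD)
                if not has_pbs:
                    expected.add(NO_PBS)
                if not has_ppt:
                    expected.add(NO_PPT)
                if not has_rt:
                    expected.add(NO_RT)
                assert result.reason_codes == frozenset(expected)

    def test_low_similarity_is_its_own_reason(self):
        cand = _candidate(None, (100, 200), (1000, 1100), sim=0.7)
        result = filter_intact(cand, *self._evidence())
        assert isinstance(result, Rejection)
        assert result.reason_codes == frozenset({LOW_LTR_SIMILARITY})

    def test_solo_ltr_like_candidate_carries_all_failures(self):
        cand = _candidate(None, (100, 200), (1000, 1100))
        result = filter_intact(cand, None, None, None, [])
        assert result.reason_codes == frozenset({NO_TSD, NO_PBS, NO_PPT, NO_RT})


class TestDecoyRejection:
    def test_all_decoys_rejected_with_planted_reason(self, annotated_scenario):
        """No decoy may be accepted; TSD-less decoys that reach the filter
        must carry the NO_TSD reason code."""
        genome, truth, result = annotated_scenario
        for td in truth.decoys():
            assert all(
                not el.interval.overlaps(td.interval) for el in result.elements
            ), f"decoy {td.element_id} ({td.decoy_class}) accepted"
        no_tsd_rejects = 0
        for td in truth.decoys():
            if td.decoy_class != "no_tsd":
                continue
            for r in result.rejections:
                if r.candidate.element.overlaps(td.interval):
                    assert NO_TSD in r.reason_codes
                    no_tsd_rejects += 1
        assert no_tsd_rejects >= 1

    def test_majority_of_intact_elements_accepted(self, annotated_scenario):
        genome, truth, result = annotated_scenario
        accepted = sum(
            1 for t in truth.intact() if match_truth(result.elements, t) is not None
        )
        assert accepted >= 0.9 * len(truth.intact())
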