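import numpy as np
import pytest

from ltrscout import aleseq
from ltrscout.aleseq import (
    ElementReadStats,
    call_active,
    count_reads,
    coverage_track,
    fragments_from_alignments,
    junction_signature,
    normalize,
)
from ltrscout.core import Fragment, GenomicInterval, ReadAlignment
from ltrscout.io import AnnotatedElement
from ltrscout.ltr_detect import ParameterError


def _element(eid, start, end, seq_id="c1", pbs=None, ltr_len=50):
    return AnnotatedElement(
        element_id=eid,
        interval=GenomicInterval(seq_id, start, end, "+"),
        ltr_left=GenomicInterval(seq_id, start, start + ltr_len, "+"),
        ltr_right=GenomicInterval(seq_id, end - ltr_len, end, "+"),
        pbs_interval=pbs,
    )


def _frag(fid, start, end, seq_id="c1", unique=True):
    return Fragment(fid, GenomicInterval(seq_id, start, end), unique)


class TestCountReads:
    def test_fragment_inside_element_counts_once(self):
        counts = count_reads([_frag("f1", 120, 180)], [_element("A", 100, 200)])
        assert counts == {"A": 1}

    def test_ambiguous_fragment_counts_for_neither(self):
        els = [_element("A", 100, 200), _element("B", 210, 300)]
        counts = count_reads([_frag("f1", 190, 220)], els)
        assert counts == {"A": 0, "B": 0}

    def test_non_unique_fragment_ignored(self):
        counts = count_reads(
            [_frag("f1", 120, 180, unique=False)], [_element("A", 100, 200)]
        )
        assert counts == {"A": 0}

    def test_single_base_overlap_counts(self):
        counts = count_reads([_frag("f1", 199, 250)], [_element("A", 100, 200)])
        assert counts == {"A": 1}

    def test_reference_mismatch_errors(self):
        with pytest.raises(ValueError, match="c1"):
            count_reads([], [_element("A", 100, 200)], references=("cX",))

    def test_paired_mates_count_as_one_fragment(self):
        r1 = GenomicInterval("c1", 120, 150, "+")
        r2 = GenomicInterval("c1", 160, 190, "-")
        alns = [
            ReadAlignment("p1", r1, r2, True),
            ReadAlignment("p1", r2, r1, True),
        ]
        counts = count_reads(alns, [_element("A", 100, 200)])
        assert counts == {"A": 1}

    def test_total_counted_never_exceeds_fragments(self):
        rng = np.random.default_rng(0)
        frags = [
            _frag(f"f{i}", s, s + 60)
            for i, s in enumerate(rng.integers(0, 5000, 300))
        ]
        els = [_element("A", 500, 900), _element("B", 2000, 2600)]
        counts = count_reads(frags, els)
        assert sum(counts.values()) <= len(frags)


class TestNormalize:
    def test_reads_per_million(self):
        assert normalize({"A": 50}, 1_000_000) == {"A": 50.0}

    def test_zero_counts_stay_zero(self):
        assert normalize({"A": 0, "B": 0}, 10) == {"A": 0.0, "B": 0.0}

    def test_scale_invariance(self):
        base = normalize({"A": 3, "B": 7}, 1000)
        doubled = normalize({"A": 6, "B": 14}, 2000)
        assert base == doubled

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            normalize({"A": 1}, 0)


class TestJunctionSignature:
    def _el(self):
        # 5' LTR [100, 200), PBS [202, 214)
        return _element(
            "A", 100, 800, pbs=GenomicInterval("c1", 202, 214, "+"), ltr_len=100
        )

    def test_fragment_spanning_junction_counted(self):
        el = self._el()
        assert junction_signature([_frag("f1", 180, 214)], el) == 1

    def test_fragment_in_three_prime_ltr_not_counted(self):
        el = self._el()
        assert junction_signature([_frag("f1", 700, 790)], el) == 0

    def test_missing_pbs_errors(self):
        with pytest.raises(ValueError, match="PBS"):
            junction_signature([], _element("A", 100, 800))

    def test_batch_counts_match_single_element_calls(self):
        rng = np.random.default_rng(1)
        els = [
            _element("A", 100, 800, pbs=GenomicInterval("c1", 202, 214, "+"), ltr_len=100),
            _element("B", 2000, 2700, pbs=GenomicInterval("c1", 2102, 2114, "+"), ltr_len=100),
        ]
        frags = [
            _frag(f"f{i}", s, s + 40) for i, s in enumerate(rng.integers(0, 3000, 500))
        ]
        batch = aleseq.junction_signatures(frags, els)
        for el in els:
            assert batch[el.element_id] == junction_signature(frags, el)


class TestCallActive:
    def _stats(self, rpm, junction):
        return ElementReadStats("A", 100, rpm, junction)

    @pytest.mark.parametrize(
        "rpm,junction,expected",
        [
            (40_000.0, 500, "strong"),
            (3_500.0, 0, "moderate"),
            (4_500.0, 0, "moderate"),  # high RPM without junction evidence
            (2_000.0, 500, "none"),
            (100.0, 0, "none"),
        ],
    )
    def test_tier_rules(self, rpm, junction, expected):
        (out,) = call_active([self._stats(rpm, junction)], 4000.0, 3000.0, 50)
        assert out.call == expected

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            call_active([], 100.0, 200.0, 5)
        with pytest.raises(ParameterError):
            call_active([], -1.0, -2.0, 5)


class TestCoverageTrack:
    def test_single_read_covers_its_span(self):
        cov = coverage_track([_frag("f1", 5, 35)], "c1", 50)
        assert cov.sum() == 30
        assert cov[5] == 1 and cov[34] == 1 and cov[35] == 0

    def test_overlapping_mates_count_once_per_position(self):
        r1 = GenomicInterval("c1", 10, 40, "+")
        r2 = GenomicInterval("c1", 30, 60, "-")
        alns = [ReadAlignment("p", r1, r2, True), ReadAlignment("p", r2, r1, True)]
        cov = coverage_track(alns, "c1", 100)
        assert cov[35] == 1  # overlap region counted once
        assert cov.sum() == 50  # union span 10..60

    def test_empty_alignment_set_gives_zero_vector(self):
        assert coverage_track([], "c1", 20).sum() == 0


class TestFragments:
    def test_mate_union_and_uniqueness_propagation(self):
        r1 = GenomicInterval("c1", 10, 40, "+")
        r2 = GenomicInterval("c1", 80, 110, "-")
        alns = [
            ReadAlignment("p", r1, r2, True),
            ReadAlignment("p", r2, r1, False),
        ]
        (frag,) = fragments_from_alignments(alns)
        assert (frag.interval.start, frag.interval.end) == (10, 110)
        assert not frag.is_unique
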