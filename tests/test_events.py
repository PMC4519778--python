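"""Event decomposition, classification and event-annotation construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ateseq.annotation import AnnotationError, exonic_symmetric_difference
from ateseq.events import (
    build_event_annotation,
    classify_utr_length,
    find_events,
)
from conftest import make_transcript
from oracles import brute_force_events


def pair(ref_exons, alt_exons, strand="+", ref_cds=None, alt_cds=None):
    a = make_transcript(ref_exons, strand=strand, tid="g.t1", cds=ref_cds)
    b = make_transcript(alt_exons, strand=strand, tid="g.t2", cds=alt_cds)
    return a, b


class TestFindEvents:
    def test_cassette_exon_is_contained_splicing(self):
        a, b = pair([(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)])
        (ev,) = find_events(a, b)
        assert ev.positional_class == "contained"
        assert ev.event_type == "alternative_splicing"
        assert ev.alt_ref == [(300, 400)] and ev.alt_alt == []

    def test_alternative_first_exon_is_upstream_promoter(self):
        a, b = pair(
            [(100, 200), (500, 600)], [(10, 40), (100, 200), (500, 600)]
        )
        (ev,) = find_events(a, b)
        assert ev.positional_class == "upstream"
        assert ev.event_type == "alternative_promoter"
        assert ev.alt_ref == [] and ev.alt_alt == [(10, 40)]

    def test_identical_transcripts_yield_nothing(self):
        a, b = pair([(0, 50), (80, 120)], [(0, 50), (80, 120)])
        assert find_events(a, b) == []

    def test_internal_exon_extension_minus_strand_is_contained(self):
        a, b = pair(
            [(100, 200), (300, 400)], [(100, 260), (300, 400)], strand="-"
        )
        (ev,) = find_events(a, b)
        assert ev.positional_class == "contained"
        assert ev.event_type == "alternative_splicing"
        assert ev.divergent_intervals == [(200, 260)]

    def test_left_truncation_minus_strand_is_downstream_3prime(self):
        a, b = pair(
            [(100, 200), (300, 400)], [(150, 200), (300, 400)], strand="-"
        )
        (ev,) = find_events(a, b)
        assert ev.positional_class == "downstream"
        assert ev.event_type == "alternative_3prime"
        # the same pair on the + strand must become an upstream promoter event
        a2, b2 = pair([(100, 200), (300, 400)], [(150, 200), (300, 400)])
        (ev2,) = find_events(a2, b2)
        assert ev2.event_type == "alternative_promoter"

    def test_no_shared_base_single_contained_event_with_warning(self):
        a, b = pair([(0, 100)], [(200, 300)])
        with pytest.warns(UserWarning, match="no exonic base"):
            evs = find_events(a, b)
        assert len(evs) == 1
        assert evs[0].positional_class == "contained"
        assert evs[0].whole_transcript

    def test_different_genes_rejected(self):
        a = make_transcript([(0, 10)], tid="t1", gid="g1")
        b = make_transcript([(0, 20)], tid="t2", gid="g2")
        with pytest.raises(AnnotationError):
            find_events(a, b)

    def test_cds_change_restricted_to_event(self):
        # cassette exon fully coding (200 bp) plus a UTR-only 3' extension
        a, b = pair(
            [(0, 100), (200, 400), (500, 600)],
            [(0, 100), (500, 900)],
            ref_cds=[(50, 100), (200, 400), (500, 550)],
            alt_cds=[(50, 100), (500, 550)],
        )
        evs = {e.positional_class: e for e in find_events(a, b)}
        assert evs["contained"].cds_change_bp == 200
        assert evs["contained"].coding
        assert evs["downstream"].cds_change_bp == 0
        assert not evs["downstream"].coding

    def test_cds_change_of_exactly_100bp_is_not_coding(self):
        a, b = pair(
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (400, 500)],
            ref_cds=[(200, 300)],
        )
        (ev,) = find_events(a, b)
        assert ev.cds_change_bp == 100
        assert not ev.coding

    def test_no_cds_on_either_side_is_noncoding(self):
        a, b = pair([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)])
        (ev,) = find_events(a, b)
        assert ev.cds_change_bp == 0 and not ev.coding


@st.composite
def toy_chains(draw):
    k = draw(st.integers(1, 4))
    pts = draw(
        st.lists(st.integers(0, 11), min_size=2 * k, max_size=2 * k, unique=True)
        .map(sorted)
    )
    return tuple((pts[2 * i], pts[2 * i + 1]) for i in range(k))


class TestEventProperties:
    @given(a=toy_chains(), b=toy_chains(), strand=st.sampled_from("+-"))
    @settings(max_examples=300, deadline=None)
    def test_matches_per_base_brute_force(self, a, b, strand):
        import warnings

        ta = make_transcript(a, strand=strand, tid="t1")
        tb = make_transcript(b, strand=strand, tid="t2")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            evs = find_events(ta, tb)
        got = sorted(
            (e.positional_class, tuple(e.divergent_intervals)) for e in evs
        )
        assert got == sorted(brute_force_events(a, b, strand))

    @given(a=toy_chains(), b=toy_chains())
    @settings(max_examples=200, deadline=None)
    def test_strand_flip_swaps_promoter_and_3prime(self, a, b):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plus = find_events(
                make_transcript(a, tid="t1"), make_transcript(b, tid="t2")
            )
            minus = find_events(
                make_transcript(a, strand="-", tid="t1"),
                make_transcript(b, strand="-", tid="t2"),
            )
        swap = {
            "alternative_promoter": "alternative_3prime",
            "alternative_3prime": "alternative_promoter",
            "alternative_splicing": "alternative_splicing",
        }
        assert sorted(
            (tuple(e.divergent_intervals), swap[e.event_type]) for e in plus
        ) == sorted((tuple(e.divergent_intervals), e.event_type) for e in minus)

    @given(a=toy_chains(), b=toy_chains())
    @settings(max_examples=200, deadline=None)
    def test_events_partition_the_symmetric_difference(self, a, b):
        import warnings

        ta = make_transcript(a, tid="t1")
        tb = make_transcript(b, tid="t2")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            evs = find_events(ta, tb)
        _, total = exonic_symmetric_difference(ta, tb)
        assert sum(e.divergent_bp for e in evs) == total

    @given(a=toy_chains(), b=toy_chains())
    @settings(max_examples=200, deadline=None)
    def test_argument_swap_exchanges_ref_and_alt_roles(self, a, b):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fwd = find_events(
                make_transcript(a, tid="t1"), make_transcript(b, tid="t2")
            )
            rev = find_events(
                make_transcript(b, tid="t2"), make_transcript(a, tid="t1")
            )
        assert sorted(
            (e.positional_class, tuple(e.alt_ref), tuple(e.alt_alt)) for e in fwd
        ) == sorted(
            (e.positional_class, tuple(e.alt_alt), tuple(e.alt_ref)) for e in rev
        )


class TestBuildEventAnnotation:
    def test_cassette_event_with_one_flank(self):
        a, b = pair([(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)])
        (ev,) = find_events(a, b)
        ann = build_event_annotation(ev, a, b, flank_exons=1)
        assert ann.ref_transcript.exons == [(100, 200), (300, 400), (500, 600)]
        assert ann.alt_transcript.exons == [(100, 200), (500, 600)]
        assert ann.ref_transcript.transcript_id == f"{ev.event_id}.ref"
        assert ann.alt_transcript.transcript_id == f"{ev.event_id}.alt"

    def test_upstream_event_flanks_only_downstream_side(self):
        a, b = pair([(100, 200), (500, 600)], [(10, 40), (100, 200), (500, 600)])
        (ev,) = find_events(a, b)
        ann = build_event_annotation(ev, a, b, flank_exons=1)
        assert ann.alt_transcript.exons == [(10, 40), (100, 200)]
        assert ann.ref_transcript.exons == [(100, 200)]

    def test_zero_flank_with_empty_side_rejected(self):
        a, b = pair([(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)])
        (ev,) = find_events(a, b)
        with pytest.raises(AnnotationError, match="no exons"):
            build_event_annotation(ev, a, b, flank_exons=0)

    def test_negative_flank_rejected(self):
        a, b = pair([(0, 100)], [(0, 150)])
        (ev,) = find_events(a, b)
        with pytest.raises(ValueError):
            build_event_annotation(ev, a, b, flank_exons=-1)

    def test_partial_exon_3prime_extension_merges_flank(self):
        a, b = pair([(100, 200)], [(100, 300)])
        (ev,) = find_events(a, b)
        assert ev.event_type == "alternative_3prime"
        ann = build_event_annotation(ev, a, b, flank_exons=1)
        assert ann.ref_transcript.exons == [(100, 200)]
        assert ann.alt_transcript.exons == [(100, 300)]


class TestClassifyUtrLength:
    def _threeprime_event(self, ref_exons, alt_exons, **kw):
        a, b = pair(ref_exons, alt_exons, **kw)
        (ev,) = find_events(a, b)
        assert ev.event_type == "alternative_3prime"
        return ev

    def test_longer_reference_alternative(self):
        ev = self._threeprime_event([(0, 100), (200, 700)], [(0, 100), (200, 300)])
        assert classify_utr_length(ev) == "long_ref"

    def test_longer_alt_alternative(self):
        ev = self._threeprime_event([(0, 100), (200, 300)], [(0, 100), (200, 700)])
        assert classify_utr_length(ev) == "long_alt"

    def test_promoter_event_not_applicable(self):
        a, b = pair([(100, 200), (500, 600)], [(10, 40), (100, 200), (500, 600)])
        (ev,) = find_events(a, b)
        assert classify_utr_length(ev) == "not_applicable"

    def test_coding_3prime_event_not_applicable(self):
        # terminal change rewriting >100 bp of CDS is not a pure UTR event
        ev = self._threeprime_event(
            [(0, 100), (200, 700)],
            [(0, 100), (200, 300)],
            ref_cds=[(50, 100), (200, 450)],
            alt_cds=[(50, 100), (200, 250)],
        )
        assert ev.coding
        assert classify_utr_length(ev) == "not_applicable"
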