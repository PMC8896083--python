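"""Motif enumeration: worked domain examples, oracle equivalence, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camscan.motif_engine import (
    ALPHABETS,
    DEFAULT_CLASSES,
    STRICT,
    AnchorAlphabet,
    MotifClassSpec,
    MotifConfigError,
    count_by_class,
    enumerate_anchor_motifs,
    get_alphabet,
    get_class,
    scan_all_classes,
    scan_iq,
)
from conftest import regex_oracle_starts

AA = "ACDEFGHIKLMNPQRSTVWY"
TWO_ANCHOR = [c for c in DEFAULT_CLASSES if len(c.offsets) == 2]

random_seq = st.text(alphabet=AA, min_size=0, max_size=40)
any_class = st.sampled_from(DEFAULT_CLASSES)


class TestClassDefinitions:
    @pytest.mark.parametrize(
        "name,offsets,span",
        [
            ("1-10", (0, 9), 10),
            ("1-12", (0, 11), 12),
            ("1-14", (0, 13), 14),
            ("1-16", (0, 15), 16),
            ("1-5-10", (0, 4, 9), 10),
            ("1-5-8-14", (0, 4, 7, 13), 14),
        ],
    )
    def test_default_roster(self, name, offsets, span):
        spec = get_class(name)
        assert spec.offsets == offsets and spec.span == span

    def test_invalid_offsets_rejected(self):
        with pytest.raises(MotifConfigError):
            MotifClassSpec("bad", (1, 9))
        with pytest.raises(MotifConfigError):
            MotifClassSpec("bad", (0, 9, 9))

    def test_custom_alphabet_and_unknown_names(self):
        assert get_alphabet("custom:filvwm").residues == frozenset("FILVWM")
        with pytest.raises(MotifConfigError):
            get_alphabet("loose")
        with pytest.raises(MotifConfigError):
            get_class("1-8-14")


class TestWorkedDomainExamples:
    """Anchor tallies on reported CaMBD sequences, strict alphabet."""

    def test_abca7_cambd1_1_10_anchor_pairs(self):
        hits = enumerate_anchor_motifs("LQALLLKRFLLARRSRRGLF", get_class("1-10"))
        assert [h.anchor_positions for h in hits] == [(1, 10), (10, 19), (11, 20)]

    def test_abca7_cambd1_1_5_10(self):
        hits = enumerate_anchor_motifs("LQALLLKRFLLARRSRRGLF", get_class("1-5-10"))
        assert [h.anchor_positions for h in hits] == [(1, 5, 10)]

    def test_abca7_cambd2_two_1_10(self):
        hits = enumerate_anchor_motifs("QGLKTKKWVNEVRYGGFSLG", get_class("1-10"))
        assert len(hits) == 2

    def test_cr1_single_1_16_spans_whole_domain(self):
        hits = enumerate_anchor_motifs("VVTYRCNLGSRGRKVFEL", get_class("1-16"))
        assert [h.anchor_positions for h in hits] == [(1, 16)]

    def test_trem2_two_1_10(self):
        by_class = scan_all_classes("RVVSTHNLWLLSFLRRWNG", TWO_ANCHOR)
        assert len(by_class["1-10"]) == 2

    def test_no_anchor_residues_no_hits(self):
        for spec in DEFAULT_CLASSES:
            assert enumerate_anchor_motifs("K" * 12, spec) == []

    def test_hit_residues_are_anchors_and_offsets_exact(self):
        for spec in DEFAULT_CLASSES:
            for hit in enumerate_anchor_motifs("LQALLLKRFLLARRSRRGLFWIVF", spec):
                assert all(r in STRICT for r in hit.anchor_residues)
                deltas = tuple(p - hit.anchor_positions[0] for p in hit.anchor_positions)
                assert deltas == spec.offsets


class TestScanAllClasses:
    def test_all_classes_present_and_total_conserved(self):
        by_class = scan_all_classes("RVVSTHNLWLLSFLRRWNG")
        assert set(by_class) == {c.name for c in DEFAULT_CLASSES}
        counts = count_by_class(by_class)
        assert sum(counts.values()) == sum(len(v) for v in by_class.values())

    def test_empty_sequence_all_zero(self):
        counts = count_by_class(scan_all_classes(""))
        assert set(counts.values()) == {0}

    def test_duplicate_class_names_rejected(self):
        with pytest.raises(MotifConfigError):
            scan_all_classes("LLLL", [get_class("1-10"), MotifClassSpec("1-10", (0, 9))])

    def test_count_by_class_flat_hits_with_zero_fill(self):
        hits = enumerate_anchor_motifs("LQALLLKRFLLARRSRRGLF", get_class("1-10"))
        counts = count_by_class(hits, classes=["1-10", "1-16"])
        assert counts == {"1-10": 3, "1-16": 0}


class TestIQScanning:
    def test_nlrp3_region_is_iq_like_not_canonical(self):
        hits = scan_iq("WQKAERGDILLSSL")
        assert [(h.variant, h.start) for h in hits] == [("IQ-like", 1)]

    def test_constructed_canonical_iq(self):
        hits = scan_iq("IQAAARGAAAKAAF")
        assert [(h.variant, h.start) for h in hits] == [("IQ", 1)]
        assert hits[0].matched_text == "IQAAARGAAAKAAF"

    def test_no_glutamine_no_hits(self):
        assert scan_iq("AAAAAAAA") == []

    def test_matched_text_occurs_at_start(self):
        seq = "GGIQAAARGAAAKAAFGGWQKAERGGG"
        for hit in scan_iq(seq):
            assert seq[hit.start - 1 : hit.start - 1 + len(hit.matched_text)] == hit.matched_text


class TestEngineProperties:
    @settings(max_examples=300, deadline=None)
    @given(seq=random_seq, spec=any_class, alphabet=st.sampled_from(sorted(ALPHABETS)))
    def test_oracle_equivalence(self, seq, spec, alphabet):
        """Scanner agrees with an independent lookahead-regex brute force."""
        alpha = ALPHABETS[alphabet]
        starts = [h.span_start for h in enumerate_anchor_motifs(seq, spec, alpha)]
        assert starts == regex_oracle_starts(seq, spec, alpha)

    @settings(max_examples=200, deadline=None)
    @given(seq=random_seq, spec=any_class)
    def test_alphabet_monotonicity(self, seq, spec):
        """Hits under an alphabet never exceed hits under a superset alphabet."""
        small = STRICT
        big = AnchorAlphabet("big", STRICT.residues | frozenset("MAY"))
        assert len(enumerate_anchor_motifs(seq, spec, small)) <= len(
            enumerate_anchor_motifs(seq, spec, big)
        )

    @settings(max_examples=200, deadline=None)
    @given(seq=random_seq, spec=st.sampled_from(TWO_ANCHOR))
    def test_reversal_symmetry_two_anchor(self, seq, spec):
        """Reversing a sequence preserves two-anchor class counts."""
        assert len(enumerate_anchor_motifs(seq, spec)) == len(
            enumerate_anchor_motifs(seq[::-1], spec)
        )

    @settings(max_examples=200, deadline=None)
    @given(seq=random_seq)
    def test_sub_motif_implication(self, seq):
        """Every 1-5-10 hit has a 1-10 hit at the same outer anchors; same
        for 1-5-8-14 within 1-14."""
        for inner, outer in (("1-5-10", "1-10"), ("1-5-8-14", "1-14")):
            outer_pairs = {
                (h.span_start, h.span_end)
                for h in enumerate_anchor_motifs(seq, get_class(outer))
            }
            for hit in enumerate_anchor_motifs(seq, get_class(inner)):
                assert (hit.span_start, hit.span_end) in outer_pairs

    @settings(max_examples=100, deadline=None)
    @given(spec=any_class, pad=st.integers(0, 10))
    def test_planted_anchor_recovery(self, spec, pad):
        """Anchors exactly at the class offsets in non-anchor filler yield
        exactly one hit at the planted position."""
        window = ["G"] * spec.span
        for off in spec.offsets:
            window[off] = "W"
        seq = "K" * pad + "".join(window) + "K" * pad
        hits = enumerate_anchor_motifs(seq, spec)
        assert [h.span_start for h in hits] == [pad + 1]
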