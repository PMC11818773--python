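"""Grammar and consequence-classification tests for the HGVS module."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lamaspectrum.hgvs import (
    CdnaEvent,
    CdnaKind,
    Consequence,
    HgvsParseError,
    ProteinKind,
    classify_consequence,
    describe_variant,
    format_cdna,
    format_protein,
    net_length_change,
    parse_cdna,
    parse_protein,
)


class TestParseCdna:
    @pytest.mark.parametrize(
        "text,kind,start,offset,ref,alt",
        [
            ("c.5116C>T", CdnaKind.SUBSTITUTION, 5116, 0, "C", "T"),
            ("c.8245-2A>G", CdnaKind.SUBSTITUTION, 8245, -2, "A", "G"),
            ("C.4198C>T", CdnaKind.SUBSTITUTION, 4198, 0, "C", "T"),
            ("c.6992+1G>T", CdnaKind.SUBSTITUTION, 6992, 1, "G", "T"),
        ],
    )
    def test_substitutions(self, text, kind, start, offset, ref, alt):
        e = parse_cdna(text)
        assert e.kind is kind
        assert (e.start_anchor, e.start_offset) == (start, offset)
        assert (e.end_anchor, e.end_offset) == (start, offset)
        assert (e.ref_seq, e.alt_seq) == (ref, alt)

    def test_case_tolerant_prefix_same_event(self):
        assert parse_cdna("C.4198C>T") == parse_cdna("c.4198C>T")

    def test_range_deletion(self):
        e = parse_cdna("c.1893_1897del")
        assert e.kind is CdnaKind.DELETION
        assert (e.start_anchor, e.end_anchor) == (1893, 1897)
        assert net_length_change(e) == -5

    def test_intronic_range_deletion(self):
        e = parse_cdna("c.8244+3_8244+6del")
        assert e.is_intronic
        assert (e.start_offset, e.end_offset) == (3, 6)
        assert net_length_change(e) == -4

    @pytest.mark.parametrize(
        "text,span",
        [("del ex 57,58", (57, 58)), ("del ex 14", (14,)), ("ex 40 del", (40,))],
    )
    def test_exon_level_deletions(self, text, span):
        e = parse_cdna(text)
        assert e.kind is CdnaKind.EXON_LEVEL_DEL
        assert e.exon_span == span

    def test_delins_with_explicit_ref(self):
        e = parse_cdna("c.7701delTinsGTGTCCCTAGGTGTCCCTA")
        assert e.kind is CdnaKind.DELINS
        assert e.ref_seq == "T"
        assert len(e.alt_seq) == 19

    @pytest.mark.parametrize(
        "bad",
        [
            "c.5116X>T",  # invalid base
            "c.5116C>",  # missing alt
            "c.123foo",  # unknown keyword
            "g.5116C>T",  # wrong prefix
            "",
            "c.",
            "c.1897_1893del",  # inverted range
        ],
    )
    def test_rejects_malformed(self, bad):
        with pytest.raises(HgvsParseError):
            parse_cdna(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(HgvsParseError, match="X"):
            parse_cdna("c.5116X>T")


class TestParseProtein:
    def test_frameshift(self):
        p = parse_protein("p.(Asp2513IlefsTer34)")
        assert p.kind is ProteinKind.FRAMESHIFT
        assert (p.ref_aa, p.position, p.alt_aa, p.ter_offset) == ("Asp", 2513, "Ile", 34)

    def test_stop_gain(self):
        p = parse_protein("p.(Arg1706Ter)")
        assert p.kind is ProteinKind.STOP_GAIN

    def test_unknown(self):
        assert parse_protein("p.?").kind is ProteinKind.UNKNOWN

    def test_internal_space_tolerated(self):
        p = parse_protein("p. (Lys1556GlufsTer3)")
        assert p.kind is ProteinKind.FRAMESHIFT
        assert p == parse_protein("p.(Lys1556GlufsTer3)")

    def test_protein_delins(self):
        p = parse_protein("p.(Ser2567delinsArgCysProTer)")
        assert p.kind is ProteinKind.DELINS
        assert p.alt_aa.endswith("Ter")

    @pytest.mark.parametrize("bad", ["p.(Xyz55His)", "p.(Asn55Zzz)", "q.(Asn55His)", ""])
    def test_rejects_unknown_codes(self, bad):
        with pytest.raises(HgvsParseError):
            parse_protein(bad)


class TestNetLengthChange:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("c.6560delinsTGCCA", +4),
            ("c.5116C>T", 0),
            ("c.8699_8700insGTAAATTCT", +9),
            ("c.7536del", -1),
            ("c.4692_4695dup", +4),
            ("c.7701delTinsGTGTCCCTAGGTGTCCCTA", +18),
        ],
    )
    def test_examples(self, text, expected):
        assert net_length_change(parse_cdna(text)) == expected

    def test_exon_level_unsupported(self):
        with pytest.raises(HgvsParseError):
            net_length_change(parse_cdna("del ex 40"))


class TestClassification:
    @pytest.mark.parametrize(
        "cdna,protein,expected",
        [
            ("del ex 40", "p.?", Consequence.GROSS_DEL_DUP),
            ("c.8245-2A>G", "p.?", Consequence.SPLICE),
            ("c.7536del", "p.(Asp2513IlefsTer34)", Consequence.FRAMESHIFT),
            ("c.163A>C", "p.(Asn55His)", Consequence.MISSENSE),
            ("c.8699_8700insGTAAATTCT", "p.(Pro2901Ter)", Consequence.NONSENSE),
            ("c.7701delTinsGTGTCCCTAGGTGTCCCTA", "p.(Ser2567delinsArgCysProTer)",
             Consequence.FRAMESHIFT),
            ("c.5116C>T", "p.(Arg1706Ter)", Consequence.NONSENSE),
            ("c.8244+3_8244+6del", "p.?", Consequence.SPLICE),
        ],
    )
    def test_precedence_ladder(self, cdna, protein, expected):
        assert describe_variant(cdna, protein).consequence is expected

    def test_ambiguous_stop_gain_indels_flagged(self):
        v1 = describe_variant("c.8699_8700insGTAAATTCT", "p.(Pro2901Ter)")
        v2 = describe_variant(
            "c.7701delTinsGTGTCCCTAGGTGTCCCTA", "p.(Ser2567delinsArgCysProTer)"
        )
        v3 = describe_variant("c.5116C>T", "p.(Arg1706Ter)")
        assert v1.ambiguous_class and v2.ambiguous_class and not v3.ambiguous_class

    def test_splice_invariant_intronic_offset_with_unknown_protein(self, fixture_variants):
        for v in fixture_variants:
            if v.cdna.is_intronic and v.protein.kind is ProteinKind.UNKNOWN:
                assert v.consequence is Consequence.SPLICE


class TestRoundTrip:
    def test_fixture_round_trips(self, fixture_rows):
        """format(parse(x)) re-parses to an equal event for all 75 rows."""
        for r in fixture_rows.itertuples():
            e = parse_cdna(r.cdna)
            assert parse_cdna(format_cdna(e)) == e
            p = parse_protein(r.protein)
            assert parse_protein(format_protein(p)) == p

    @given(
        anchor=st.integers(1, 9999),
        offset=st.integers(-50, 50),
        length=st.integers(0, 8),
        kind=st.sampled_from([CdnaKind.DELETION, CdnaKind.DUPLICATION]),
    )
    def test_constructed_events_round_trip(self, anchor, offset, length, kind):
        end_anchor, end_offset = anchor, offset
        if length:
            if offset == 0:
                end_anchor = anchor + length
            else:
                end_offset = offset + length
        e = CdnaEvent(
            kind=kind,
            start_anchor=anchor,
            start_offset=offset,
            end_anchor=end_anchor,
            end_offset=end_offset,
        )
        assert parse_cdna(format_cdna(e)) == e
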