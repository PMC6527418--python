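"""Annotation-map model, TSV round-tripping, lookup and summary statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from lab2pheno.annotation_store import (
    AnnotationError,
    AnnotationMap,
    LookupMiss,
    LookupStatus,
    MappingEntry,
    OutcomeKey,
    loinc_check_digit_ok,
    map_statistics,
    read_annotation_tsv,
    sorted_entries,
    write_annotation_tsv,
)


def entry(loinc="6298-4", scale="Qn", code="H", hpo="HP:0002153", negated=False, **kw):
    outcome = (
        OutcomeKey.internal(code)
        if kw.pop("system", "FHIR") == "FHIR"
        else OutcomeKey.external(kw.pop("_system"), code)
    )
    return MappingEntry(loinc=loinc, scale=scale, outcome=outcome, hpo=hpo, negated=negated, **kw)


class TestValidation:
    @pytest.mark.parametrize("bad", ["6298", "6298-44", "abc-1", " 6298-4", "HP:0002153"])
    def test_malformed_loinc_rejected(self, bad):
        with pytest.raises(AnnotationError):
            entry(loinc=bad)

    @pytest.mark.parametrize("bad", ["HP:123", "HPO:0002153", "hp:0002153", "HP:00021530"])
    def test_malformed_hpo_rejected(self, bad):
        with pytest.raises(AnnotationError):
            entry(hpo=bad)

    def test_unknown_scale_rejected(self):
        with pytest.raises(AnnotationError):
            entry(scale="Doc")

    def test_negation_only_for_normal_or_absent_outcomes(self):
        entry(code="N", hpo="HP:0011042", negated=True)  # fine
        entry(scale="Ord", code="NEG", hpo="HP:0031812", negated=True)  # fine
        with pytest.raises(AnnotationError):
            entry(code="H", negated=True)

    def test_unknown_outcome_is_not_annotatable(self):
        with pytest.raises(AnnotationError):
            entry(code="U")

    def test_duplicate_key_rejected(self):
        amap = AnnotationMap([entry()])
        with pytest.raises(AnnotationError):
            amap.add(entry(hpo="HP:0002900"))

    def test_inconsistent_scale_rejected(self):
        amap = AnnotationMap([entry()])
        with pytest.raises(AnnotationError):
            amap.add(entry(scale="Ord", code="POS", hpo="HP:0031812"))

    @pytest.mark.parametrize(
        "code,ok",
        [
            ("6298-4", True), ("2345-7", True), ("2339-0", True),
            ("15074-8", True), ("32710-6", True), ("5778-6", True),
            ("6298-5", False), ("2345-0", False),
        ],
    )
    def test_check_digit(self, code, ok):
        # real codes carry valid mod-10 check digits; mutated ones do not
        assert loinc_check_digit_ok(code) is ok


class TestTsvIO:
    def test_fixture_map_reads_clean(self, amap):
        assert len(amap) > 0
        hit = amap.lookup("6298-4", OutcomeKey.internal("H"))
        assert isinstance(hit, MappingEntry)
        assert (hit.hpo, hit.negated) == ("HP:0002153", False)

    def test_round_trip_identity(self, amap, tmp_path):
        p = tmp_path / "roundtrip.tsv"
        write_annotation_tsv(amap, p)
        assert read_annotation_tsv(p) == amap

    def test_two_writes_byte_identical(self, amap, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_annotation_tsv(amap, p1)
        write_annotation_tsv(amap, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_map_round_trip(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_annotation_tsv(AnnotationMap(), p)
        assert len(read_annotation_tsv(p)) == 0

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "hdr.tsv"
        p.write_text("loincId\tloincScale\toutcomeSystem\toutcomeCode\thpoTermId\tisNegated\n")
        assert len(read_annotation_tsv(p)) == 0

    def test_comments_ignored(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "# generated by curation pipeline\n"
            "loincId\tloincScale\toutcomeSystem\toutcomeCode\thpoTermId\tisNegated\n"
            "# a comment row\n"
            "6298-4\tQn\tFHIR\tH\tHP:0002153\tfalse\n"
        )
        assert len(read_annotation_tsv(p)) == 1

    def test_duplicate_rows_error_names_line(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "loincId\tloincScale\toutcomeSystem\toutcomeCode\thpoTermId\tisNegated\n"
            "6298-4\tQn\tFHIR\tH\tHP:0002153\tfalse\n"
            "6298-4\tQn\tFHIR\tH\tHP:0002900\tfalse\n"
        )
        with pytest.raises(AnnotationError, match="line 3"):
            read_annotation_tsv(p)

    def test_malformed_id_error_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "loincId\tloincScale\toutcomeSystem\toutcomeCode\thpoTermId\tisNegated\n"
            "notaloinc\tQn\tFHIR\tH\tHP:0002153\tfalse\n"
        )
        with pytest.raises(AnnotationError, match="line 2"):
            read_annotation_tsv(p)

    def test_unknown_columns_preserved(self, tmp_path):
        p = tmp_path / "extra.tsv"
        p.write_text(
            "loincId\tloincScale\toutcomeSystem\toutcomeCode\thpoTermId\tisNegated\tversion\n"
            "6298-4\tQn\tFHIR\tH\tHP:0002153\tfalse\tv2\n"
        )
        amap = read_annotation_tsv(p)
        (e,) = list(amap)
        assert e.extra == {"version": "v2"}
        out = tmp_path / "out.tsv"
        write_annotation_tsv(amap, out)
        assert read_annotation_tsv(out) == amap

    def test_aliased_upstream_layout(self, tmp_path):
        p = tmp_path / "alias.tsv"
        p.write_text(
            "loincNumber\tloincScale\tsystem\tcode\thpoTermId\tisNegated\n"
            "6298-4\tQn\tFHIR\tH\tHP:0002153\tfalse\n"
        )
        amap = read_annotation_tsv(p)
        assert isinstance(amap.lookup("6298-4", OutcomeKey.internal("H")), MappingEntry)

    def test_strict_mode_rejects_unknown_layout(self, tmp_path):
        p = tmp_path / "weird.tsv"
        p.write_text(
            "loincId\tloincScale\toutcomeSystem\toutcomeCode\thpoTermId\tisNegated\tmystery\n"
            "6298-4\tQn\tFHIR\tH\tHP:0002153\tfalse\tx\n"
        )
        with pytest.raises(AnnotationError, match="mystery"):
            read_annotation_tsv(p, strict=True)


class TestLookup:
    def test_nitrite_positive_and_negative(self, amap):
        pos = amap.lookup("32710-6", OutcomeKey.internal("POS"))
        neg = amap.lookup("32710-6", OutcomeKey.internal("NEG"))
        assert (pos.hpo, pos.negated) == ("HP:0031812", False)
        assert (neg.hpo, neg.negated) == ("HP:0031812", True)

    def test_unmapped_loinc_vs_unmapped_outcome(self, amap):
        miss = amap.lookup("99999-9", OutcomeKey.internal("H"))
        assert isinstance(miss, LookupMiss)
        assert miss.reason is LookupStatus.UNMAPPED_LOINC
        miss = amap.lookup("32710-6", OutcomeKey.internal("H"))
        assert miss.reason is LookupStatus.UNMAPPED_OUTCOME

    def test_lookup_matches_linear_scan(self, amap):
        # oracle: a linear scan over all entries must agree with the index
        for e in amap:
            assert amap.lookup(e.loinc, e.outcome) is e
        probes = [(e.loinc, OutcomeKey.internal("POS")) for e in amap if e.scale == "Qn"]
        for loinc, outcome in probes:
            scan = [e for e in amap if e.key == (loinc, outcome)]
            hit = amap.lookup(loinc, outcome)
            assert (len(scan) == 1) == isinstance(hit, MappingEntry)


class TestStatistics:
    def test_empty_map_all_zero(self):
        s = map_statistics(AnnotationMap())
        assert s.n_entries == s.n_loincs == s.n_distinct_hpo == 0
        assert s.mean_loinc_per_hpo == 0.0

    def test_scale_fractions(self):
        entries = [
            entry(loinc=f"9000{i}-1", code="H", hpo=f"HP:000000{i}") for i in range(1, 5)
        ] + [entry(loinc="90005-1", scale="Ord", code="POS", hpo="HP:0000005")]
        s = map_statistics(AnnotationMap(entries))
        assert s.scale_percent["Qn"] == pytest.approx(80.0)
        assert s.scale_percent["Ord"] == pytest.approx(20.0)

    def test_shared_hpo_mean(self):
        entries = [
            entry(loinc="90001-1", scale="Ord", code="POS", hpo="HP:0031812"),
            entry(loinc="90002-1", scale="Ord", code="POS", hpo="HP:0031812"),
        ]
        s = map_statistics(AnnotationMap(entries))
        assert s.n_distinct_hpo == 1
        assert s.mean_loinc_per_hpo == pytest.approx(2.0)
        assert s.loinc_per_hpo == {2: 1}

    def test_matches_brute_force_recount(self, amap):
        s = map_statistics(amap)
        # independent recount straight off the entry list
        loincs = {e.loinc for e in amap}
        by_hpo = {}
        for e in amap:
            by_hpo.setdefault(e.hpo, set()).add(e.loinc)
        assert s.n_loincs == len(loincs)
        assert s.n_distinct_hpo == len(by_hpo)
        assert s.mean_loinc_per_hpo == pytest.approx(
            sum(len(v) for v in by_hpo.values()) / len(by_hpo)
        )
        assert sum(s.scale_percent.values()) == pytest.approx(100.0, abs=0.1)


# -- property: TSV round-trip identity over generated maps -------------------

_loincs = st.builds(lambda a, b: f"{a}-{b}", st.integers(1, 9_999_999), st.integers(0, 9))
_hpos = st.builds(lambda n: f"HP:{n:07d}", st.integers(1, 9_999_999))
_internal = st.sampled_from(["A", "L", "N", "H"])


@st.composite
def annotation_maps(draw):
    amap = AnnotationMap()
    n = draw(st.integers(0, 12))
    for _ in range(n):
        loinc = draw(_loincs)
        scale = amap.scale_of(loinc) or draw(st.sampled_from(["Qn", "Ord"]))
        code = draw(_internal if scale == "Qn" else st.sampled_from(["POS", "NEG", "N"]))
        if amap.lookup(loinc, OutcomeKey.internal(code)).__class__ is not LookupMiss:
            continue
        negated = code in ("N", "NEG") and draw(st.booleans())
        amap.add(
            MappingEntry(
                loinc=loinc, scale=scale, outcome=OutcomeKey.internal(code),
                hpo=draw(_hpos), negated=negated,
                curator=draw(st.none() | st.just("curator-a")),
            )
        )
    return amap


@settings(max_examples=50, derandomize=True, deadline=None)
@given(annotation_maps())
def test_round_trip_property(tmp_path_factory, generated):
    p = tmp_path_factory.mktemp("prop") / "m.tsv"
    write_annotation_tsv(generated, p)
    back = read_annotation_tsv(p)
    assert back == generated
    assert [e.key for e in sorted_entries(back)] == [e.key for e in sorted_entries(generated)]
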