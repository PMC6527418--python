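"""Outcome normalization, range comparison and observation conversion."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from lab2pheno.annotation_store import OutcomeKey
from lab2pheno.conversion import (
    ConversionFailure,
    FailureReason,
    PhenotypeCall,
    convert_collection,
    convert_observation,
    infer_outcome_from_range,
    normalize_interpretation,
    resolve_outcome,
    write_conversion_tsv,
)
from lab2pheno.fhir_io import CodedValue, LabObservation, Quantity, ReferenceRange

from conftest import make_obs

# the full secondary-to-primary interpretation code table
TABLE = {
    "A": ["A", "AA", "W"],
    "L": ["L", "<", "D", "LL", "LU"],
    "N": ["N", "B", "I"],
    "H": ["H", ">", "HH", "HU", "UH"],
    "NEG": ["NEG", "ND", "NR"],
    "POS": ["POS", "AC", "DET", "RR", "TOX", "WR"],
    "U": ["U", "HM", "IE", "IND", "MS", "NS", "null", "OBX", "QCF",
          "R", "S", "SDD", "SYN-R", "SYN-S", "VS"],
}


class TestNormalizeInterpretation:
    @pytest.mark.parametrize(
        "raw,primary",
        [(raw, primary) for primary, raws in TABLE.items() for raw in raws],
    )
    def test_listed_codes(self, raw, primary):
        assert normalize_interpretation(raw) == primary

    @pytest.mark.parametrize("raw", ["XYZ", "h i", "9", "pos neg", "??"])
    def test_unlisted_codes_normalize_to_unknown(self, raw):
        assert normalize_interpretation(raw) == "U"

    @pytest.mark.parametrize("raw", ["ll", " hh ", "Det", "neg", "n"])
    def test_case_and_whitespace_insensitive(self, raw):
        assert normalize_interpretation(raw) != "U"

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.text(min_size=1, max_size=8))
    def test_total_and_idempotent(self, raw):
        primary = normalize_interpretation(raw)
        assert primary in ("A", "L", "N", "H", "NEG", "POS", "U")
        assert normalize_interpretation(primary) == primary


class TestRangeInference:
    RANGE = ReferenceRange(Quantity(3.5, "mmol/L"), Quantity(5.0, "mmol/L"))

    @pytest.mark.parametrize(
        "value,expected",
        [(3.0, "L"), (6.1, "H"), (4.0, "N"), (3.5, "N"), (5.0, "N")],
    )
    def test_two_sided(self, value, expected):
        assert infer_outcome_from_range(Quantity(value, "mmol/L"), self.RANGE) == expected

    def test_one_sided_ranges(self):
        high_only = ReferenceRange(high=Quantity(5.0, "x"))
        assert infer_outcome_from_range(Quantity(6.0, "x"), high_only) == "H"
        assert infer_outcome_from_range(Quantity(1.0, "x"), high_only) == "N"
        low_only = ReferenceRange(low=Quantity(3.5, "x"))
        assert infer_outcome_from_range(Quantity(1.0, "x"), low_only) == "L"

    def test_no_bounds_is_insufficient(self):
        from lab2pheno.conversion import _InsufficientRange

        with pytest.raises(_InsufficientRange):
            infer_outcome_from_range(Quantity(1.0, "x"), ReferenceRange())
        with pytest.raises(_InsufficientRange):
            infer_outcome_from_range(Quantity(1.0, "x"), None)

    def test_unit_mismatch_is_insufficient(self):
        from lab2pheno.conversion import _InsufficientRange

        with pytest.raises(_InsufficientRange):
            infer_outcome_from_range(Quantity(6.1, "mg/dL"), self.RANGE)


class TestResolveOutcome:
    def test_interpretation_takes_precedence(self):
        obs = make_obs("6298-4", value=4.0, low=3.5, high=5.0, interpretation="HH")
        out = resolve_outcome(obs, "Qn")
        assert out == OutcomeKey.internal("H")

    def test_unknown_interpretation_fails_even_with_value(self):
        obs = make_obs("6298-4", value=6.1, low=3.5, high=5.0, interpretation="IND")
        assert resolve_outcome(obs, "Qn") == FailureReason.UNKNOWN_INTERPRETATION

    def test_coded_value_for_nominal(self):
        obs = LabObservation(
            "o1", "p1", "5778-6",
            value=CodedValue("http://snomed.info/sct", "371254008"),
        )
        out = resolve_outcome(obs, "Nom")
        assert out == OutcomeKey.external("http://snomed.info/sct", "371254008")

    def test_numeric_range_path(self):
        obs = make_obs("6298-4", value=6.1, low=3.5, high=5.0)
        assert resolve_outcome(obs, "Qn") == OutcomeKey.internal("H")

    def test_missing_everything_is_insufficient(self):
        obs = make_obs("6298-4")
        assert resolve_outcome(obs, "Qn") == FailureReason.INSUFFICIENT_DATA


class TestConvertObservation:
    @pytest.mark.parametrize(
        "value,hpo,negated",
        [(6.1, "HP:0002153", False), (3.0, "HP:0002900", False), (4.2, "HP:0011042", True)],
    )
    def test_potassium_three_outcomes(self, amap, value, hpo, negated):
        call = convert_observation(make_obs("6298-4", value=value, low=3.5, high=5.0, unit="mmol/L"), amap)
        assert isinstance(call, PhenotypeCall)
        assert (call.hpo, call.negated) == (hpo, negated)

    def test_glucose_high(self, amap):
        call = convert_observation(make_obs("15074-8", value=162.0, low=70.0, high=110.0), amap)
        assert (call.hpo, call.negated) == ("HP:0003074", False)

    def test_urine_color_coded_value(self, amap):
        obs = LabObservation(
            "o1", "p1", "5778-6",
            value=CodedValue("http://snomed.info/sct", "371254008"),
        )
        call = convert_observation(obs, amap)
        assert (call.hpo, call.negated) == ("HP:0040318", False)

    def test_unmapped_loinc(self, amap):
        fail = convert_observation(make_obs("99999-9", value=1.0, low=0.0, high=2.0), amap)
        assert isinstance(fail, ConversionFailure)
        assert fail.reason == FailureReason.UNMAPPED_LOINC

    def test_abnormal_fallback_for_l_and_h(self, amap):
        # 90011-7 is annotated only at the A (abnormal) level
        call = convert_observation(make_obs("90011-7", interpretation="HH"), amap)
        assert (call.hpo, call.negated) == ("HP:0003236", False)
        call = convert_observation(make_obs("90011-7", interpretation="L"), amap)
        assert call.hpo == "HP:0003236"

    def test_normal_never_falls_back_to_abnormal(self, amap):
        fail = convert_observation(make_obs("90011-7", interpretation="N"), amap)
        assert isinstance(fail, ConversionFailure)
        assert fail.reason == FailureReason.UNMAPPED_OUTCOME

    def test_interpretation_wins_over_conflicting_range(self, amap, caplog):
        # interpretation H but the value sits inside the range: code wins
        obs = make_obs("6298-4", value=4.0, low=3.5, high=5.0, unit="mmol/L",
                       interpretation="H")
        with caplog.at_level("WARNING", logger="lab2pheno.conversion"):
            call = convert_observation(obs, amap)
        assert call.hpo == "HP:0002153"
        assert any("disagrees" in r.message for r in caplog.records)

    def test_consistent_paths_agree(self, amap):
        via_code = convert_observation(make_obs("6298-4", interpretation="H"), amap)
        via_range = convert_observation(
            make_obs("6298-4", value=6.1, low=3.5, high=5.0, unit="mmol/L"), amap
        )
        assert (via_code.hpo, via_code.negated) == (via_range.hpo, via_range.negated)

    def test_negated_only_for_normal_outcomes(self, amap):
        # scan every convertible synthetic outcome: negation implies N/NEG
        for interpretation in ("H", "L", "N", "POS", "NEG"):
            for loinc in ("6298-4", "32710-6"):
                result = convert_observation(make_obs(loinc, interpretation=interpretation), amap)
                if isinstance(result, PhenotypeCall) and result.negated:
                    assert result.outcome.code in ("N", "NEG")


class TestConvertCollection:
    def build_mixed(self, amap, n=50, seed=7):
        rng = random.Random(seed)
        observations = []
        for i in range(n):
            kind = rng.random()
            if kind < 0.6:
                observations.append(
                    make_obs("6298-4", value=rng.uniform(2.0, 7.0), low=3.5, high=5.0,
                             unit="mmol/L", obs_id=f"o{i}")
                )
            elif kind < 0.8:
                observations.append(make_obs("99999-9", value=1.0, low=0.0, high=2.0, obs_id=f"o{i}"))
            else:
                observations.append(make_obs("6298-4", interpretation="IND", obs_id=f"o{i}"))
        return observations

    def test_partition_and_rate(self, amap):
        observations = self.build_mixed(amap)
        report = convert_collection(observations, amap)
        assert len(report.calls) + len(report.failures) == len(observations)
        # independent per-record recount
        expected_failures = sum(
            1 for o in observations
            if isinstance(convert_observation(o, amap), ConversionFailure)
        )
        assert len(report.failures) == expected_failures
        assert report.rate == pytest.approx(1 - expected_failures / len(observations))

    def test_counting_example(self, amap):
        observations = [
            make_obs("6298-4", value=6.1, low=3.5, high=5.0, unit="mmol/L", obs_id=f"g{i}")
            for i in range(8)
        ] + [
            make_obs("99999-9", value=1.0, low=0.0, high=2.0, obs_id=f"u{i}")
            for i in range(2)
        ]
        report = convert_collection(observations, amap)
        assert report.rate == pytest.approx(0.8)
        assert report.failure_counts == {"UNMAPPED_LOINC": 2}

    def test_empty_input(self, amap):
        report = convert_collection([], amap)
        assert report.rate == 0.0 and report.calls == [] and report.failures == []

    def test_permutation_equivariance(self, amap):
        observations = self.build_mixed(amap, n=30, seed=3)
        fwd = convert_collection(observations, amap)
        rev = convert_collection(list(reversed(observations)), amap)
        assert fwd.calls == list(reversed(rev.calls))
        assert fwd.failures == list(reversed(rev.failures))

    def test_tsv_export(self, amap, tmp_path):
        report = convert_collection(self.build_mixed(amap, n=10), amap)
        p = tmp_path / "conv.tsv"
        write_conversion_tsv(report, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("obs_id\t")
        assert len(lines) == 11
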