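"""Parsing of FHIR Observation resources into normalized lab records.

Only the narrow slice of an Observation that matters for phenotype conversion
is extracted: the LOINC coding, the observed value (quantity, coded concept or
text), the reference range(s), the interpretation code, the subject and the
effective time.  The target shape is the R3/STU3 Observation, with tolerance
for R4 aliases (``interpretation`` as a single CodeableConcept or a list).

Resources without a LOINC coding are rejected with a typed reason rather than
guessed at; bundles report such entries as skipped instead of failing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

__all__ = [
    "LOINC_SYSTEMS",
    "Quantity",
    "ReferenceRange",
    "NumericValue",
    "CodedValue",
    "TextValue",
    "MISSING",
    "LabObservation",
    "SkippedResource",
    "FhirParseError",
    "parse_observation",
    "parse_bundle",
    "read_bundle_file",
    "read_ndjson",
    "observation_to_fhir",
    "preferred_range",
]

#: coding.system values accepted as identifying LOINC ("LOINC" is a lenient
#: spelling used by some sandbox servers and fixtures).
LOINC_SYSTEMS = frozenset({"http://loinc.org", "LOINC"})

SNOMED_SYSTEM = "http://snomed.info/sct"


class FhirParseError(ValueError):
    """Raised for structurally unusable resources.

    ``reason`` is one of NOT_OBSERVATION, NO_LOINC, COMPONENT_ONLY, MALFORMED.
    """

    def __init__(self, reason: str, message: str, resource_id: str | None = None):
        super().__init__(message)
        self.reason = reason
        self.resource_id = resource_id


@dataclass(frozen=True)
class Quantity:
    value: float
    unit: str | None = None

    def __post_init__(self) -> None:
        if not (self.value == self.value and abs(self.value) != float("inf")):
            raise FhirParseError("MALFORMED", f"non-finite quantity {self.value!r}")


@dataclass(frozen=True)
class ReferenceRange:
    """Normal interval for a quantitative test; either bound may be absent.

    ``qualified`` marks ranges restricted by age/appliesTo — downstream uses
    the first unqualified range, falling back to the first of any kind.
    """

    low: Quantity | None = None
    high: Quantity | None = None
    qualified: bool = False

    def __post_init__(self) -> None:
        if (
            self.low is not None
            and self.high is not None
            and self.low.unit == self.high.unit
            and self.low.value > self.high.value
        ):
            raise FhirParseError(
                "MALFORMED",
                f"reference range low {self.low.value} > high {self.high.value}",
            )


@dataclass(frozen=True)
class NumericValue:
    quantity: Quantity


@dataclass(frozen=True)
class CodedValue:
    system: str | None
    code: str
    display: str | None = None


@dataclass(frozen=True)
class TextValue:
    text: str


class _Missing:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return "MISSING"


#: sentinel for Observations carrying no value element at all
MISSING = _Missing()

ObservationValue = NumericValue | CodedValue | TextValue | _Missing


@dataclass
class LabObservation:
    """Normalized extract of one FHIR Observation for a LOINC-coded test."""

    obs_id: str
    subject_id: str
    loinc: str
    value: ObservationValue = MISSING
    ranges: list[ReferenceRange] = field(default_factory=list)
    interpretation_raw: str | None = None
    effective_time: str | None = None  # ISO-8601; compared lexicographically


@dataclass(frozen=True)
class SkippedResource:
    resource_id: str | None
    resource_type: str | None
    reason: str


def _reference_id(ref: Any) -> str:
    if isinstance(ref, dict):
        ref = ref.get("reference") or ref.get("display") or ""
    if isinstance(ref, str) and "/" in ref:
        return ref.rsplit("/", 1)[-1]
    return str(ref or "")


def _first_loinc(code: dict | None) -> str | None:
    for coding in (code or {}).get("coding", []) or []:
        if coding.get("system") in LOINC_SYSTEMS and coding.get("code"):
            return str(coding["code"])
    return None


def _parse_quantity(q: dict | None) -> Quantity | None:
    if not q or "value" not in q:
        return None
    return Quantity(value=float(q["value"]), unit=q.get("unit") or q.get("code"))


def _parse_ranges(resource: dict) -> list[ReferenceRange]:
    out = []
    for rr in resource.get("referenceRange", []) or []:
        qualified = bool(rr.get("appliesTo") or rr.get("age") or rr.get("type"))
        out.append(
            ReferenceRange(
                low=_parse_quantity(rr.get("low")),
                high=_parse_quantity(rr.get("high")),
                qualified=qualified,
            )
        )
    return out


def _parse_interpretation(resource: dict) -> str | None:
    interp = resource.get("interpretation")
    if isinstance(interp, list):  # R4: list of CodeableConcept
        interp = interp[0] if interp else None
    if not isinstance(interp, dict):
        return None
    for coding in interp.get("coding", []) or []:
        if coding.get("code"):
            return str(coding["code"])
    return interp.get("text") or None


def _parse_value(resource: dict) -> ObservationValue:
    # precedence: valueQuantity > valueCodeableConcept > valueString > Missing
    if "valueQuantity" in resource:
        q = _parse_quantity(resource["valueQuantity"])
        if q is not None:
            return NumericValue(q)
    if "valueCodeableConcept" in resource:
        cc = resource["valueCodeableConcept"] or {}
        for coding in cc.get("coding", []) or []:
            if coding.get("code"):
                return CodedValue(
                    system=coding.get("system"),
                    code=str(coding["code"]),
                    display=coding.get("display"),
                )
        if cc.get("text"):
            return TextValue(cc["text"])
    if "valueString" in resource:
        return TextValue(str(resource["valueString"]))
    return MISSING


def parse_observation(resource: dict) -> LabObservation:
    """Parse one Observation resource (JSON object) into a LabObservation.

    Raises :class:`FhirParseError` with reason NOT_OBSERVATION, NO_LOINC or
    COMPONENT_ONLY (panel observations whose codings live in components are
    not guessed at).
    """
    if not isinstance(resource, dict) or resource.get("resourceType") != "Observation":
        raise FhirParseError(
            "NOT_OBSERVATION",
            f"expected an Observation, got {resource.get('resourceType')!r}"
            if isinstance(resource, dict)
            else "expected a JSON object",
            resource.get("id") if isinstance(resource, dict) else None,
        )
    obs_id = str(resource.get("id") or "")
    loinc = _first_loinc(resource.get("code"))
    if loinc is None:
        if resource.get("component"):
            raise FhirParseError(
                "COMPONENT_ONLY",
                "multi-component observation without a top-level LOINC coding",
                obs_id,
            )
        raise FhirParseError("NO_LOINC", "no LOINC coding in Observation.code", obs_id)
    effective = resource.get("effectiveDateTime")
    if effective is None and isinstance(resource.get("effectivePeriod"), dict):
        effective = resource["effectivePeriod"].get("start")
    return LabObservation(
        obs_id=obs_id,
        subject_id=_reference_id(resource.get("subject")),
        loinc=loinc,
        value=_parse_value(resource),
        ranges=_parse_ranges(resource),
        interpretation_raw=_parse_interpretation(resource),
        effective_time=str(effective) if effective is not None else None,
    )


def parse_bundle(bundle: dict) -> tuple[list[LabObservation], list[SkippedResource]]:
    """Parse a FHIR Bundle, preserving entry order.

    Non-Observation entries and LOINC-less Observations are reported as
    skipped (with the typed reason), never fatal.
    """
    if not isinstance(bundle, dict) or bundle.get("resourceType") != "Bundle":
        raise FhirParseError(
            "MALFORMED",
            "expected a Bundle resource",
            bundle.get("id") if isinstance(bundle, dict) else None,
        )
    observations: list[LabObservation] = []
    skipped: list[SkippedResource] = []
    for entry in bundle.get("entry", []) or []:
        resource = entry.get("resource") if isinstance(entry, dict) else None
        if not isinstance(resource, dict):
            skipped.append(SkippedResource(None, None, "MALFORMED"))
            continue
        rtype = resource.get("resourceType")
        if rtype != "Observation":
            skipped.append(
                SkippedResource(resource.get("id"), rtype, "NOT_OBSERVATION")
            )
            continue
        try:
            observations.append(parse_observation(resource))
        except FhirParseError as exc:
            skipped.append(SkippedResource(exc.resource_id, rtype, exc.reason))
    return observations, skipped


def read_bundle_file(path: str | Path) -> tuple[list[LabObservation], list[SkippedResource]]:
    """Load a JSON file holding a Bundle or a single Observation."""
    with Path(path).open(encoding="utf-8") as fh:
        doc = json.load(fh)
    if isinstance(doc, dict) and doc.get("resourceType") == "Observation":
        return [parse_observation(doc)], []
    return parse_bundle(doc)


def read_ndjson(path: str | Path) -> tuple[list[LabObservation], list[SkippedResource]]:
    """Read a newline-delimited JSON stream of FHIR resources."""
    observations: list[LabObservation] = []
    skipped: list[SkippedResource] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            resource = json.loads(line)
            rtype = resource.get("resourceType")
            if rtype != "Observation":
                skipped.append(SkippedResource(resource.get("id"), rtype, "NOT_OBSERVATION"))
                continue
            try:
                observations.append(parse_observation(resource))
            except FhirParseError as exc:
                skipped.append(SkippedResource(exc.resource_id, rtype, exc.reason))
    return observations, skipped


def observation_to_fhir(obs: LabObservation) -> dict:
    """Re-serialize a LabObservation as a minimal FHIR Observation.

    Inverse of :func:`parse_observation` over the extracted fields, so
    ``parse_observation(observation_to_fhir(x)) == x``.
    """
    resource: dict[str, Any] = {
        "resourceType": "Observation",
        "id": obs.obs_id,
        "status": "final",
        "subject": {"reference": f"Patient/{obs.subject_id}"},
        "code": {"coding": [{"system": "http://loinc.org", "code": obs.loinc}]},
    }
    if obs.effective_time is not None:
        resource["effectiveDateTime"] = obs.effective_time
    if isinstance(obs.value, NumericValue):
        q: dict[str, Any] = {"value": obs.value.quantity.value}
        if obs.value.quantity.unit is not None:
            q["unit"] = obs.value.quantity.unit
        resource["valueQuantity"] = q
    elif isinstance(obs.value, CodedValue):
        coding: dict[str, Any] = {"code": obs.value.code}
        if obs.value.system is not None:
            coding["system"] = obs.value.system
        if obs.value.display is not None:
            coding["display"] = obs.value.display
        resource["valueCodeableConcept"] = {"coding": [coding]}
    elif isinstance(obs.value, TextValue):
        resource["valueString"] = obs.value.text
    if obs.ranges:
        rr_list = []
        for rr in obs.ranges:
            item: dict[str, Any] = {}
            for name, bound in (("low", rr.low), ("high", rr.high)):
                if bound is not None:
                    b: dict[str, Any] = {"value": bound.value}
                    if bound.unit is not None:
                        b["unit"] = bound.unit
                    item[name] = b
            if rr.qualified:
                item["appliesTo"] = [{"text": "qualified"}]
            rr_list.append(item)
        resource["referenceRange"] = rr_list
    if obs.interpretation_raw is not None:
        resource["interpretation"] = {
            "coding": [
                {
                    "system": "http://hl7.org/fhir/v2/0078",
                    "code": obs.interpretation_raw,
                }
            ]
        }
    return resource


def preferred_range(ranges: Iterable[ReferenceRange]) -> ReferenceRange | None:
    """First unqualified reference range, else the first range, else None."""
    ranges = list(ranges)
    for rr in ranges:
        if not rr.qualified:
            return rr
    return ranges[0] if ranges else None
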