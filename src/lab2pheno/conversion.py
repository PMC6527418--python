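"""Conversion of laboratory observations into (possibly negated) HPO terms.

The algorithm inspects a normalized :class:`~lab2pheno.fhir_io.LabObservation`
and resolves the test *outcome*:

1. an interpretation code, when present, is normalized to one of seven
   primary codes (A, L, N, H, NEG, POS, U) — variant codes such as ``LL``
   (critically low) or ``DET`` (detected) collapse onto their primary;
2. otherwise, a coded value (nominal/ordinal tests) is used directly as an
   external outcome key;
3. otherwise, for quantitative tests, the numeric value is compared against
   the normal reference range to derive L, N or H.

The resolved outcome is then looked up in the annotation map to obtain the
HPO term and its negation flag.  Every way this can fail is a typed,
per-record reason — never an exception — so a collection converts to a
(calls, failures, rate) triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .annotation_store import (
    AnnotationMap,
    LookupMiss,
    LookupStatus,
    MappingEntry,
    OutcomeKey,
)
from .fhir_io import (
    CodedValue,
    LabObservation,
    NumericValue,
    Quantity,
    ReferenceRange,
    preferred_range,
)

__all__ = [
    "PRIMARY_CODES",
    "PhenotypeCall",
    "ConversionFailure",
    "FailureReason",
    "normalize_interpretation",
    "infer_outcome_from_range",
    "resolve_outcome",
    "convert_observation",
    "convert_collection",
    "ConversionReport",
    "write_conversion_tsv",
]

logger = logging.getLogger(__name__)

PRIMARY_CODES = ("A", "L", "N", "H", "NEG", "POS", "U")

# Secondary interpretation codes collapsing onto each primary code.  Matching
# is case-insensitive after trimming; "<"/">" are matched literally; the
# literal token "null" is itself a listed code.  Any code not listed
# normalizes to U (unknown).
_SECONDARY: dict[str, tuple[str, ...]] = {
    "A": ("A", "AA", "W"),
    "L": ("L", "<", "D", "LL", "LU"),
    "N": ("N", "B", "I"),
    "H": ("H", ">", "HH", "HU", "UH"),
    "NEG": ("NEG", "ND", "NR"),
    "POS": ("POS", "AC", "DET", "RR", "TOX", "WR"),
    "U": (
        "U", "HM", "IE", "IND", "MS", "NS", "NULL", "OBX", "QCF",
        "R", "S", "SDD", "SYN-R", "SYN-S", "VS",
    ),
}

_NORMALIZATION: dict[str, str] = {
    sec.upper(): primary for primary, secs in _SECONDARY.items() for sec in secs
}


def normalize_interpretation(raw: str) -> str:
    """Normalize any interpretation token to a primary code (total function).

    Unlisted tokens normalize to ``U``; the function is idempotent because
    every primary code maps to itself.
    """
    return _NORMALIZATION.get(raw.strip().upper(), "U")


class FailureReason:
    """Closed enumeration of per-record conversion failure reasons."""

    UNMAPPED_LOINC = "UNMAPPED_LOINC"
    UNMAPPED_OUTCOME = "UNMAPPED_OUTCOME"
    UNKNOWN_INTERPRETATION = "UNKNOWN_INTERPRETATION"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"
    RANGE_CONFLICT = "RANGE_CONFLICT"

    ALL = (
        UNMAPPED_LOINC,
        UNMAPPED_OUTCOME,
        UNKNOWN_INTERPRETATION,
        INSUFFICIENT_DATA,
        RANGE_CONFLICT,
    )


@dataclass(frozen=True)
class PhenotypeCall:
    """One converted result: an HPO term, possibly negated (a normal result
    is encoded as NOT <abnormality>), with provenance."""

    hpo: str
    negated: bool
    source_obs: str
    loinc: str
    subject_id: str = ""
    time: str | None = None
    outcome: OutcomeKey | None = None


@dataclass(frozen=True)
class ConversionFailure:
    source_obs: str
    reason: str
    loinc: str | None = None
    subject_id: str = ""
    detail: str | None = None

    def __post_init__(self) -> None:
        if self.reason not in FailureReason.ALL:
            raise ValueError(f"unknown failure reason {self.reason!r}")


class _InsufficientRange(Exception):
    """Internal signal: no usable reference range for a numeric comparison."""


def infer_outcome_from_range(value: Quantity, rng: ReferenceRange | None) -> str:
    """Classify a numeric value against a normal range: L, N or H.

    Bounds are inclusive of normal (value == low or == high -> N).  One-sided
    ranges compare only the present bound.  No unit conversion is attempted:
    a bound whose unit differs (string inequality after trimming) from the
    value's is unusable — silent unit coercion is a safety hazard.

    Raises ``_InsufficientRange`` when no usable bound exists; callers
    surface this as an INSUFFICIENT_DATA failure.
    """
    if rng is None:
        raise _InsufficientRange("no reference range")

    def usable(bound: Quantity | None) -> bool:
        if bound is None:
            return False
        a = (value.unit or "").strip()
        b = (bound.unit or "").strip()
        return a == b

    low_ok = usable(rng.low)
    high_ok = usable(rng.high)
    if not low_ok and not high_ok:
        raise _InsufficientRange("no usable bound (absent or unit mismatch)")
    if low_ok and value.value < rng.low.value:  # type: ignore[union-attr]
        return "L"
    if high_ok and value.value > rng.high.value:  # type: ignore[union-attr]
        return "H"
    return "N"


def resolve_outcome(
    obs: LabObservation, scale: str
) -> OutcomeKey | str:
    """Resolve an observation to an outcome key, or a failure-reason string.

    Precedence: (1) interpretation code when present (an explicit unknown,
    U, fails the record — the lab itself could not interpret it); (2) coded
    value as an external key for Nom (and Ord) tests; (3) numeric value vs
    reference range for Qn tests.
    """
    if obs.interpretation_raw is not None and obs.interpretation_raw.strip():
        primary = normalize_interpretation(obs.interpretation_raw)
        if primary == "U":
            return FailureReason.UNKNOWN_INTERPRETATION
        return OutcomeKey.internal(primary)
    if scale in ("Nom", "Ord") and isinstance(obs.value, CodedValue):
        return OutcomeKey.external(obs.value.system or "", obs.value.code)
    if scale == "Qn" and isinstance(obs.value, NumericValue):
        try:
            return OutcomeKey.internal(
                infer_outcome_from_range(obs.value.quantity, preferred_range(obs.ranges))
            )
        except _InsufficientRange:
            return FailureReason.INSUFFICIENT_DATA
    return FailureReason.INSUFFICIENT_DATA


def _check_range_agreement(obs: LabObservation, primary: str) -> None:
    """When a Qn record carries both an interpretation code and a numeric
    value + range, recompute from the range and warn on disagreement.  The
    interpretation code wins (codes are authoritative when present)."""
    if not isinstance(obs.value, NumericValue):
        return
    try:
        recomputed = infer_outcome_from_range(
            obs.value.quantity, preferred_range(obs.ranges)
        )
    except _InsufficientRange:
        return
    comparable = {"L", "N", "H"}
    if primary in comparable and recomputed != primary:
        logger.warning(
            "observation %s: interpretation %s disagrees with range-derived %s "
            "(interpretation wins)",
            obs.obs_id, primary, recomputed,
        )


def convert_observation(
    obs: LabObservation, amap: AnnotationMap
) -> PhenotypeCall | ConversionFailure:
    """Convert one observation via the annotation map.

    A resolved L or H outcome with no scale-specific annotation falls back to
    the test's ``A`` (abnormal) annotation when one exists; N never falls
    back to A.
    """
    scale = amap.scale_of(obs.loinc)
    if scale is None:
        return ConversionFailure(
            obs.obs_id, FailureReason.UNMAPPED_LOINC, obs.loinc, obs.subject_id
        )
    outcome = resolve_outcome(obs, scale)
    if isinstance(outcome, str):
        return ConversionFailure(obs.obs_id, outcome, obs.loinc, obs.subject_id)
    if obs.interpretation_raw and outcome.is_internal:
        _check_range_agreement(obs, outcome.code)
    hit = amap.lookup(obs.loinc, outcome)
    if isinstance(hit, LookupMiss) and outcome.is_internal and outcome.code in ("L", "H"):
        fallback = amap.lookup(obs.loinc, OutcomeKey.internal("A"))
        if isinstance(fallback, MappingEntry):
            hit = fallback
    if isinstance(hit, LookupMiss):
        reason = (
            FailureReason.UNMAPPED_LOINC
            if hit.reason is LookupStatus.UNMAPPED_LOINC
            else FailureReason.UNMAPPED_OUTCOME
        )
        return ConversionFailure(
            obs.obs_id, reason, obs.loinc, obs.subject_id,
            detail=f"outcome {outcome.code}",
        )
    return PhenotypeCall(
        hpo=hit.hpo,
        negated=hit.negated,
        source_obs=obs.obs_id,
        loinc=obs.loinc,
        subject_id=obs.subject_id,
        time=obs.effective_time,
        outcome=outcome,
    )


@dataclass
class ConversionReport:
    calls: list[PhenotypeCall]
    failures: list[ConversionFailure]

    @property
    def rate(self) -> float:
        """Fraction of observations converted (0 for empty input)."""
        total = len(self.calls) + len(self.failures)
        return len(self.calls) / total if total else 0.0

    @property
    def failure_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.failures:
            counts[f.reason] = counts.get(f.reason, 0) + 1
        return dict(sorted(counts.items()))


def convert_collection(
    observations: Iterable[LabObservation], amap: AnnotationMap
) -> ConversionReport:
    """Convert each observation independently; order is preserved and
    |calls| + |failures| == |observations|."""
    calls: list[PhenotypeCall] = []
    failures: list[ConversionFailure] = []
    for obs in observations:
        result = convert_observation(obs, amap)
        if isinstance(result, PhenotypeCall):
            calls.append(result)
        else:
            failures.append(result)
    return ConversionReport(calls, failures)


def write_conversion_tsv(
    report: ConversionReport, path: str | Path, observations: Sequence[LabObservation] | None = None
) -> None:
    """Export per-observation results: one row per call or failure."""
    rows: list[tuple] = []
    for c in report.calls:
        rows.append(
            (
                c.source_obs, c.subject_id, c.loinc,
                c.outcome.code if c.outcome else "",
                c.hpo, "true" if c.negated else "false",
                c.time or "", "CONVERTED",
            )
        )
    for f in report.failures:
        rows.append((f.source_obs, f.subject_id, f.loinc or "", "", "", "", "", f.reason))
    rows.sort(key=lambda r: (r[1], r[0]))
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("obs_id\tsubject_id\tloinc\toutcome\thpo\tnegated\ttime\tstatus\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
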