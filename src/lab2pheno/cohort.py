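"""Per-patient phenotype profiles, cohort thresholds and exposure flags.

From a stream of phenotype calls, each patient's calls are grouped by
(term, negated) with observation counts and first/last times; non-negated
abnormality counts are then propagated up the ontology.  Presence of an
abnormality is three-valued:

* PRESENT      — at least ``min_obs_for_present`` (default 3) observations
  support the term after propagation; an isolated abnormal measurement may be
  an artifact, so a single observation is not enough;
* ABSENT       — the term was never assigned to the patient at all (count 0,
  propagation included);
* INDETERMINATE — assigned, but below the presence threshold.

Negated calls (normal results, NOT <term>) are retained as asserted but are
never propagated and never support PRESENT.

Cohort-level rules: patients with medical encounters on fewer than
``min_encounter_days`` distinct days (default 10) are excluded (they receive
few tests, so their phenotype profiles are unreliably sparse); a patient with
strictly more than ``prednisone_rx_threshold`` (default 3) prednisone
prescriptions is a frequent user; an acute-asthma flag comes from diagnosis
codes matched prefix-wise against a configurable code set.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .conversion import PhenotypeCall
from .ontology import DEFAULT_STOP_SET, Ontology, propagate_observations

__all__ = [
    "Presence",
    "AnalysisConfig",
    "PatientRecord",
    "AssertedTerm",
    "PatientProfile",
    "CohortSummary",
    "build_profiles",
    "apply_exclusions",
    "flag_exposures",
    "profile_summary",
    "load_cohort_csvs",
    "DEFAULT_ASTHMA_CODES",
]

#: default acute-asthma diagnosis prefixes (ICD-10 asthma block and the
#: ICD-9 asthma family); site-specific code lists are configuration, not code.
DEFAULT_ASTHMA_CODES = frozenset({"J45", "493"})


class Presence(enum.Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis thresholds, with the defaults used throughout.

    ``ci_z`` is 1.98 (the multiplier applied to standard errors when forming
    confidence intervals); ``uniformity_threshold`` drops terms for which 95%
    of the analyzable cohort agrees; ``min_term_patients`` is the minimum
    number of PRESENT patients for a term to enter the association screen.
    ``threshold_before_propagation`` switches the presence threshold to
    asserted (pre-propagation) counts, for sensitivity analysis.
    """

    min_obs_for_present: int = 3
    min_encounter_days: int = 10
    prednisone_rx_threshold: int = 3  # strict greater-than
    uniformity_threshold: float = 0.95
    ci_z: float = 1.98
    asthma_code_set: frozenset[str] = DEFAULT_ASTHMA_CODES
    min_term_patients: int = 100
    threshold_before_propagation: bool = False
    stop_set: frozenset[str] = DEFAULT_STOP_SET

    def __post_init__(self) -> None:
        if self.min_obs_for_present < 1 or self.min_encounter_days < 1:
            raise ValueError("thresholds must be positive")
        if self.prednisone_rx_threshold < 1 or self.min_term_patients < 1:
            raise ValueError("thresholds must be positive")
        if not (0.5 < self.uniformity_threshold <= 1.0):
            raise ValueError("uniformity_threshold must lie in (0.5, 1]")


@dataclass
class PatientRecord:
    """Demographics plus the extract-derived fields the analysis needs."""

    patient_id: str
    sex: str | None = None
    birth_date: str | None = None
    encounter_dates: set[str] = field(default_factory=set)
    prednisone_rx_count: int = 0
    dx_codes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.prednisone_rx_count < 0:
            raise ValueError("prednisone_rx_count must be non-negative")

    def has_acute_asthma_dx(self, cfg: AnalysisConfig) -> bool:
        return flag_exposures(self, cfg)[1]


@dataclass
class AssertedTerm:
    """One (term, negated) group for a patient."""

    count: int
    first_time: str | None
    last_time: str | None
    negated: bool
    loincs: set[str] = field(default_factory=set)
    obs_ids: set[str] = field(default_factory=set)


@dataclass
class PatientProfile:
    patient_id: str
    asserted: dict[tuple[str, bool], AssertedTerm]
    propagated: dict[str, int]  # non-negated abnormality counts, post-propagation
    _presence_counts: dict[str, int]  # counts the presence threshold applies to
    min_obs_for_present: int

    def presence(self, term: str) -> Presence:
        n = self.propagated.get(term, 0)
        if n == 0:
            return Presence.ABSENT
        if self._presence_counts.get(term, 0) >= self.min_obs_for_present:
            return Presence.PRESENT
        return Presence.INDETERMINATE

    @property
    def unique_terms(self) -> int:
        """Distinct asserted (term, negated) annotations, normals included."""
        return len(self.asserted)

    @property
    def unique_abnormalities(self) -> int:
        return sum(1 for (_, neg) in self.asserted if not neg)

    @property
    def unique_propagated_terms(self) -> int:
        """Distinct abnormality terms after propagation plus asserted normals."""
        negated = sum(1 for (_, neg) in self.asserted if neg)
        return len(self.propagated) + negated


def build_profiles(
    calls: Iterable[PhenotypeCall],
    ont: Ontology | None,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> dict[str, PatientProfile]:
    """Group calls per patient, propagate abnormalities, assign presence.

    With no ontology, profiles carry asserted counts only (propagated equals
    asserted for non-negated terms).
    """
    grouped: dict[str, dict[tuple[str, bool], AssertedTerm]] = {}
    for call in calls:
        pat = grouped.setdefault(call.subject_id, {})
        key = (call.hpo, call.negated)
        at = pat.get(key)
        if at is None:
            at = AssertedTerm(0, None, None, call.negated)
            pat[key] = at
        at.count += 1
        at.loincs.add(call.loinc)
        at.obs_ids.add(call.source_obs)
        if call.time is not None:
            if at.first_time is None or call.time < at.first_time:
                at.first_time = call.time
            if at.last_time is None or call.time > at.last_time:
                at.last_time = call.time

    profiles: dict[str, PatientProfile] = {}
    for patient_id, asserted in grouped.items():
        abnormal = {
            term: at.obs_ids for (term, neg), at in asserted.items() if not neg
        }
        if ont is not None:
            result = propagate_observations(abnormal, ont, cfg.stop_set)
            propagated = result.counts
        else:
            propagated = {t: len(ids) for t, ids in abnormal.items()}
        if cfg.threshold_before_propagation:
            # presence from terms that individually meet the threshold,
            # propagated among themselves only
            strong = {
                t: ids
                for t, ids in abnormal.items()
                if len(ids) >= cfg.min_obs_for_present
            }
            if ont is not None:
                presence_counts = propagate_observations(strong, ont, cfg.stop_set).counts
            else:
                presence_counts = {t: len(ids) for t, ids in strong.items()}
        else:
            presence_counts = propagated
        profiles[patient_id] = PatientProfile(
            patient_id=patient_id,
            asserted=asserted,
            propagated=propagated,
            _presence_counts=presence_counts,
            min_obs_for_present=cfg.min_obs_for_present,
        )
    return profiles


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    reason: str
    detail: str


def apply_exclusions(
    patients: Mapping[str, PatientRecord], cfg: AnalysisConfig = AnalysisConfig()
) -> tuple[set[str], list[ExclusionRecord]]:
    """Retain patients with >= ``min_encounter_days`` distinct encounter dates."""
    retained: set[str] = set()
    log: list[ExclusionRecord] = []
    for pid, rec in patients.items():
        n_days = len(rec.encounter_dates)
        if n_days >= cfg.min_encounter_days:
            retained.add(pid)
        else:
            log.append(
                ExclusionRecord(
                    pid,
                    "FEW_ENCOUNTER_DAYS",
                    f"{n_days} distinct days < {cfg.min_encounter_days}",
                )
            )
    return retained, log


def _strip_dots(code: str) -> str:
    return code.replace(".", "").upper()


def flag_exposures(
    record: PatientRecord, cfg: AnalysisConfig = AnalysisConfig()
) -> tuple[bool, bool]:
    """(frequent_prednisone, acute_asthma) for one patient.

    Frequent use is a strict inequality (>3 prescriptions -> frequent; exactly
    3 is not).  Diagnosis codes match prefix-wise after dot-stripping, so
    "J45" covers "J45.901".
    """
    frequent = record.prednisone_rx_count > cfg.prednisone_rx_threshold
    prefixes = tuple(_strip_dots(c) for c in cfg.asthma_code_set)
    asthma = any(
        _strip_dots(code).startswith(prefixes) for code in record.dx_codes
    )
    return frequent, asthma


@dataclass
class CohortSummary:
    n_patients: int
    mean_unique_terms: float | None
    mean_unique_abnormalities: float | None
    mean_propagated_terms: float | None
    histogram: dict[str, int]  # unique-term bins -> patient counts


def profile_summary(
    profiles: Mapping[str, PatientProfile],
    bins: tuple[int, ...] = (1, 11, 21, 41, 61, 81, 101),
) -> CohortSummary:
    """Cohort means and a unique-terms-per-patient histogram.

    Means are undefined (None) for an empty cohort.  ``bins`` gives left
    edges of half-open bins, with a final open-ended bin.
    """
    n = len(profiles)
    if n == 0:
        return CohortSummary(0, None, None, None, {})
    uniq = [p.unique_terms for p in profiles.values()]
    abn = [p.unique_abnormalities for p in profiles.values()]
    prop = [p.unique_propagated_terms for p in profiles.values()]
    labels = []
    for i, left in enumerate(bins):
        if i + 1 < len(bins):
            labels.append((left, bins[i + 1] - 1, f"{left}-{bins[i + 1] - 1}"))
        else:
            labels.append((left, None, f">={left}"))
    hist = {lab: 0 for _, _, lab in labels}
    for u in uniq:
        for left, right, lab in labels:
            if u >= left and (right is None or u <= right):
                hist[lab] += 1
                break
    return CohortSummary(
        n_patients=n,
        mean_unique_terms=sum(uniq) / n,
        mean_unique_abnormalities=sum(abn) / n,
        mean_propagated_terms=sum(prop) / n,
        histogram=hist,
    )


def load_cohort_csvs(
    directory: str | Path, prednisone_pattern: str = "prednisone"
) -> dict[str, PatientRecord]:
    """Load patients/encounters/medications/diagnoses CSVs into records.

    Expected files (UTF-8, header rows, ISO dates): ``patients.csv``
    (patient_id, sex, birth_date), ``encounters.csv`` (patient_id, date),
    ``medications.csv`` (patient_id, date, drug_name), ``diagnoses.csv``
    (patient_id, date, icd_version, code).  Prescription counting matches
    ``prednisone_pattern`` case-insensitively against the drug name.
    """
    directory = Path(directory)
    records: dict[str, PatientRecord] = {}

    def rec(pid: str) -> PatientRecord:
        if pid not in records:
            records[pid] = PatientRecord(patient_id=pid)
        return records[pid]

    patients_csv = directory / "patients.csv"
    if patients_csv.exists():
        with patients_csv.open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                r = rec(row["patient_id"])
                r.sex = row.get("sex") or None
                r.birth_date = row.get("birth_date") or None
    with (directory / "encounters.csv").open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rec(row["patient_id"]).encounter_dates.add(row["date"])
    meds_csv = directory / "medications.csv"
    if meds_csv.exists():
        with meds_csv.open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                if prednisone_pattern.lower() in (row.get("drug_name") or "").lower():
                    rec(row["patient_id"]).prednisone_rx_count += 1
    dx_csv = directory / "diagnoses.csv"
    if dx_csv.exists():
        with dx_csv.open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                rec(row["patient_id"]).dx_codes.add(row["code"])
    return records
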