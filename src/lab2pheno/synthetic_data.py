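"""Synthetic fixtures and cohorts with known ground truth.

No patient-level dataset ships with this package, so every stage is exercised
against generated data whose generative truth is known exactly:

* a mini HPO-style ontology (~35 terms) carrying the is_a chains the other
  modules reference (potassium, glucose, urine, eosinophil and vitamin
  branches, including a diamond);
* a fixture annotation map covering quantitative, ordinal and nominal tests;
* full cohorts: per-patient FHIR Observations (NDJSON), encounter /
  medication / diagnosis CSV extracts, and a ground-truth JSON with the
  planted exposure effects.

The cohort generator emulates an asthma/respiratory EHR extract: about one
third of patients carry an acute asthma diagnosis; 14.2% of those (8.5% of
the rest) are frequent prednisone users; per-term presence follows a
logistic model with configurable baseline prevalence and planted log-odds
effects; 11.4% of emitted tests carry LOINC codes without annotations, so
the default conversion rate lands near 88.6%.  Intended-present patients
receive at least ``min_obs_for_present`` abnormal results; intended-absent
patients receive only normal results, so presence recovery is exact up to
sampling noise.

Abnormal numeric values are drawn uniformly from a band just outside the
reference range and normals from within it — crude, but only the L/N/H
partition matters downstream.  All randomness flows from one seed; equal
seeds give byte-identical outputs.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .cohort import AssertedTerm, PatientProfile
from .association import Exposures

__all__ = [
    "PanelTest",
    "PhenotypeEffect",
    "GenerativeSpec",
    "GroundTruth",
    "GeneratedCohort",
    "DEFAULT_PANEL",
    "DEFAULT_EFFECTS",
    "make_fixture_ontology",
    "make_fixture_annotations",
    "make_fixture_bundle",
    "generate_cohort",
    "simulate_presence_cohort",
]

SNOMED = "http://snomed.info/sct"

_BASE_DATE = date(2004, 1, 1)
_N_DAYS = (date(2016, 12, 31) - _BASE_DATE).days + 1  # extract window


@dataclass(frozen=True)
class PanelTest:
    """One quantitative test in the synthetic panel.

    ``direction`` is the side of the reference range on which the mapped
    abnormality lies ("high" or "low").  Synthetic codes use the reserved
    90000+ numeric space; a few real glucose/potassium codes are reused so
    the worked examples flow through the same panel.
    """

    loinc: str
    hpo: str
    direction: str  # "high" | "low"
    low: float
    high: float
    unit: str
    name: str = ""


@dataclass(frozen=True)
class PhenotypeEffect:
    baseline_prevalence: float
    log_or_prednisone: float = 0.0
    log_or_asthma: float = 0.0


#: default panel: 2 tests for terms where the study design needs aggregation
#: across distinctly coded tests, 1 elsewhere.
DEFAULT_PANEL: tuple[PanelTest, ...] = (
    PanelTest("90001-9", "HP:0001880", "high", 0.0, 0.5, "10*3/uL", "Eosinophils [#/vol] blood (analyzer)"),
    PanelTest("90002-7", "HP:0001880", "high", 0.0, 0.5, "10*3/uL", "Eosinophils [#/vol] blood (manual)"),
    PanelTest("90003-5", "HP:0020059", "high", 3.8, 5.8, "10*6/uL", "Erythrocytes [#/vol] blood (analyzer)"),
    PanelTest("90004-3", "HP:0020059", "high", 3.8, 5.8, "10*6/uL", "Erythrocytes [#/vol] blood (manual)"),
    PanelTest("6298-4", "HP:0002900", "low", 3.5, 5.0, "mmol/L", "Potassium [Moles/vol] in blood"),
    PanelTest("15074-8", "HP:0003074", "high", 70.0, 110.0, "mg/dL", "Glucose [Mass/vol] in blood"),
    PanelTest("2339-0", "HP:0003074", "high", 70.0, 110.0, "mg/dL", "Glucose [Mass/vol] in blood (strip)"),
    PanelTest("2345-7", "HP:0003074", "high", 70.0, 110.0, "mg/dL", "Glucose [Mass/vol] in serum/plasma"),
    PanelTest("90005-0", "HP:0003073", "low", 3.5, 5.0, "g/dL", "Albumin [Mass/vol] in serum"),
    PanelTest("90006-8", "HP:0003362", "high", 5.0, 40.0, "mg/dL", "VLDL cholesterol [Mass/vol] in serum"),
    PanelTest("90007-6", "HP:0012311", "high", 0.2, 0.8, "10*3/uL", "Monocytes [#/vol] in blood"),
    PanelTest("90008-4", "HP:0040087", "high", 2.0, 20.0, "ng/mL", "Folate [Mass/vol] in serum"),
    PanelTest("90009-2", "HP:0012053", "low", 30.0, 100.0, "ng/mL", "Calcifediol [Mass/vol] in serum"),
)

#: default planted effects: baseline prevalence and per-exposure log odds
#: ratios of the magnitudes seen in asthma-cohort screens (eosinophilia
#: strongly tied to steroid use, vitamin-branch terms to asthma, glucose
#: null), plus deliberate nulls.
DEFAULT_EFFECTS: dict[str, PhenotypeEffect] = {
    "HP:0001880": PhenotypeEffect(0.12, math.log(3.74), math.log(1.17)),
    "HP:0020059": PhenotypeEffect(0.10, math.log(2.48), math.log(1.50)),
    "HP:0002900": PhenotypeEffect(0.08, math.log(2.00), 0.0),
    "HP:0003074": PhenotypeEffect(0.20, 0.0, 0.0),
    "HP:0003073": PhenotypeEffect(0.06, math.log(1.50), 0.0),
    "HP:0003362": PhenotypeEffect(0.05, 0.0, math.log(1.49)),
    "HP:0012311": PhenotypeEffect(0.10, math.log(1.80), 0.0),
    "HP:0040087": PhenotypeEffect(0.02, 0.0, math.log(1.72)),
    "HP:0012053": PhenotypeEffect(0.03, 0.0, math.log(1.72)),
}


@dataclass
class GenerativeSpec:
    """Study conditions for a synthetic cohort; the seed fixes all draws."""

    n_patients: int = 2000
    seed: int = 0
    loinc_panel: tuple[PanelTest, ...] = DEFAULT_PANEL
    phenotype_effects: Mapping[str, PhenotypeEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    asthma_prevalence: float = 1.0 / 3.0
    prednisone_given_asthma: float = 0.142
    prednisone_given_no_asthma: float = 0.085
    encounter_days_mean: float = 24.0
    low_utilizer_fraction: float = 0.03
    low_utilizer_days_mean: float = 5.0
    unmapped_loinc_fraction: float = 0.114
    interpretation_only_fraction: float = 0.30
    variant_code_fraction: float = 0.15
    normal_obs_mean: float = 1.5
    abnormal_extra_obs_mean: float = 1.0
    min_obs_for_present: int = 3
    nitrite_test_fraction: float = 0.30
    nitrituria_prevalence: float = 0.10

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "asthma_prevalence", "prednisone_given_asthma",
            "prednisone_given_no_asthma", "unmapped_loinc_fraction",
            "interpretation_only_fraction", "variant_code_fraction",
            "low_utilizer_fraction", "nitrite_test_fraction",
            "nitrituria_prevalence",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for term in self.phenotype_effects:
            eff = self.phenotype_effects[term]
            if not (0.0 < eff.baseline_prevalence < 1.0):
                raise ValueError(f"baseline prevalence for {term} must be in (0,1)")
        panel_terms = {t.hpo for t in self.loinc_panel}
        missing = set(self.phenotype_effects) - panel_terms
        if missing:
            raise ValueError(f"effect terms without a panel test: {sorted(missing)}")


@dataclass
class GroundTruth:
    seed: int
    effects: dict[str, PhenotypeEffect]
    patients: dict[str, dict]  # pid -> {exposures, intended_present}

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "effects": {t: asdict(e) for t, e in sorted(self.effects.items())},
            "patients": self.patients,
        }
        return json.dumps(doc, sort_keys=True, indent=1)


@dataclass
class GeneratedCohort:
    out_dir: Path
    observations_path: Path
    csv_paths: dict[str, Path]
    ground_truth: GroundTruth
    n_observations: int


# ---------------------------------------------------------------------------
# fixture ontology
# ---------------------------------------------------------------------------

#: (term id, label, parent ids) — a synthetic mini-ontology.  Chains that the
#: analysis relies on (eosinophil, vitamin, potassium, glucose, urine) follow
#: the published HPO structure; other placements are plausible simplifications.
FIXTURE_TERMS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("HP:0000001", "All", ()),
    ("HP:0000118", "Phenotypic abnormality", ("HP:0000001",)),
    ("HP:0001939", "Abnormality of metabolism/homeostasis", ("HP:0000118",)),
    ("HP:0032245", "Abnormal metabolism", ("HP:0001939",)),
    ("HP:0100508", "Abnormality of vitamin metabolism", ("HP:0032245",)),
    ("HP:0040087", "Increased blood folate concentration", ("HP:0100508",)),
    ("HP:0200502", "Vitamin B12 deficiency", ("HP:0100508",)),
    ("HP:0012053", "Decreased serum calcifediol", ("HP:0100508",)),
    ("HP:0012052", "Decreased serum calcitriol", ("HP:0100508",)),
    ("HP:0003111", "Abnormal blood ion concentration", ("HP:0001939",)),
    ("HP:0011042", "Abnormal blood potassium concentration", ("HP:0003111",)),
    ("HP:0002153", "Hyperkalemia", ("HP:0011042",)),
    ("HP:0002900", "Hypokalemia", ("HP:0011042",)),
    ("HP:0011015", "Abnormal blood glucose concentration", ("HP:0001939",)),
    ("HP:0003074", "Hyperglycemia", ("HP:0011015",)),
    ("HP:0001943", "Hypoglycemia", ("HP:0011015",)),
    ("HP:0003073", "Hypoalbuminemia", ("HP:0001939",)),
    ("HP:0003236", "Elevated circulating creatine kinase concentration", ("HP:0001939",)),
    ("HP:0003362", "Increased VLDL cholesterol concentration", ("HP:0001939",)),
    ("HP:0000119", "Abnormality of the genitourinary system", ("HP:0000118",)),
    ("HP:0011277", "Abnormality of the urinary system physiology", ("HP:0000119",)),
    ("HP:0031812", "Nitrituria", ("HP:0011277",)),
    ("HP:0012086", "Abnormal urinary color", ("HP:0011277",)),
    ("HP:0040318", "Red urine", ("HP:0012086",)),
    ("HP:0040319", "Dark urine", ("HP:0012086",)),
    ("HP:0001871", "Abnormality of blood and blood-forming tissues", ("HP:0000118",)),
    ("HP:0001879", "Abnormal eosinophil morphology", ("HP:0001871",)),
    ("HP:0020064", "Abnormal eosinophil count", ("HP:0001879",)),
    ("HP:0001880", "Eosinophilia", ("HP:0020064",)),
    # deliberate diamond: two is_a paths from HP:0020059 to HP:0001871
    ("HP:0020058", "Abnormal red blood cell count", ("HP:0001871",)),
    ("HP:0020059", "Increased red blood cell count", ("HP:0020058", "HP:0001871")),
    ("HP:0001974", "Leukocytosis", ("HP:0001871",)),
    ("HP:0011897", "Neutrophilia", ("HP:0001974",)),
    ("HP:0012311", "Monocytosis", ("HP:0001974",)),
    ("HP:0900000", "Abnormality of synthetic panel analytes", ("HP:0000118",)),
)

FIXTURE_ALT_IDS: dict[str, str] = {"HP:0099880": "HP:0001880"}
FIXTURE_OBSOLETE: dict[str, str | None] = {"HP:0099999": "HP:0001880"}


def make_fixture_ontology(
    out_dir: str | Path,
    extra_terms: Sequence[tuple[str, str]] = (),
) -> tuple[Path, Path]:
    """Write the mini-ontology as OBO and obographs JSON; deterministic bytes.

    ``extra_terms`` (id, label) are attached under the synthetic-panel parent
    HP:0900000, letting callers scale the term universe (e.g. many null
    replicate terms) without touching the curated chains.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    terms = list(FIXTURE_TERMS) + [
        (tid, label, ("HP:0900000",)) for tid, label in extra_terms
    ]

    obo_lines = ["format-version: 1.2", "ontology: lab2pheno-mini", ""]
    alt_by_primary: dict[str, list[str]] = {}
    for alt, primary in FIXTURE_ALT_IDS.items():
        alt_by_primary.setdefault(primary, []).append(alt)
    for tid, label, parents in terms:
        obo_lines += ["[Term]", f"id: {tid}", f"name: {label}"]
        for alt in sorted(alt_by_primary.get(tid, [])):
            obo_lines.append(f"alt_id: {alt}")
        for p in parents:
            obo_lines.append(f"is_a: {p}")
        obo_lines.append("")
    for tid, replacement in sorted(FIXTURE_OBSOLETE.items()):
        obo_lines += ["[Term]", f"id: {tid}", f"name: obsolete term {tid}",
                      "is_obsolete: true"]
        if replacement:
            obo_lines.append(f"replaced_by: {replacement}")
        obo_lines.append("")
    obo_path = out_dir / "mini_hpo.obo"
    obo_path.write_text("\n".join(obo_lines), encoding="utf-8")

    def uri(tid: str) -> str:
        return "http://purl.obolibrary.org/obo/" + tid.replace(":", "_")

    nodes, edges = [], []
    for tid, label, parents in terms:
        meta: dict = {}
        if tid in alt_by_primary:
            meta["basicPropertyValues"] = [
                {
                    "pred": "http://www.geneontology.org/formats/oboInOwl#hasAlternativeId",
                    "val": uri(alt),
                }
                for alt in sorted(alt_by_primary[tid])
            ]
        node = {"id": uri(tid), "lbl": label, "type": "CLASS"}
        if meta:
            node["meta"] = meta
        nodes.append(node)
        for p in parents:
            edges.append({"sub": uri(tid), "pred": "is_a", "obj": uri(p)})
    for tid, replacement in sorted(FIXTURE_OBSOLETE.items()):
        meta = {"deprecated": True}
        if replacement:
            meta["basicPropertyValues"] = [
                {
                    "pred": "http://purl.obolibrary.org/obo/IAO_0100001",  # term_replaced_by
                    "val": uri(replacement),
                }
            ]
        nodes.append(
            {"id": uri(tid), "lbl": f"obsolete term {tid}", "type": "CLASS", "meta": meta}
        )
    json_path = out_dir / "mini_hpo.json"
    json_path.write_text(
        json.dumps({"graphs": [{"nodes": nodes, "edges": edges}]}, sort_keys=True, indent=1),
        encoding="utf-8",
    )
    return obo_path, json_path


# ---------------------------------------------------------------------------
# fixture annotation map
# ---------------------------------------------------------------------------

#: curated example rows beyond the quantitative panel:
#: potassium (three-outcome Qn), nitrite (two-outcome Ord), urine colour
#: (Nom with SNOMED-coded outcomes), glucose (three distinctly coded tests
#: sharing one interpretation), and an abnormal-only annotation exercising
#: the A-fallback.
_CURATED_ROWS: tuple[tuple[str, str, str, str, str, bool], ...] = (
    ("6298-4", "Qn", "FHIR", "L", "HP:0002900", False),
    ("6298-4", "Qn", "FHIR", "N", "HP:0011042", True),
    ("6298-4", "Qn", "FHIR", "H", "HP:0002153", False),
    ("32710-6", "Ord", "FHIR", "POS", "HP:0031812", False),
    ("32710-6", "Ord", "FHIR", "NEG", "HP:0031812", True),
    ("5778-6", "Nom", SNOMED, "371254008", "HP:0040318", False),  # red urine
    ("5778-6", "Nom", SNOMED, "405737000", "HP:0040319", False),  # dark urine
    ("15074-8", "Qn", "FHIR", "H", "HP:0003074", False),
    ("15074-8", "Qn", "FHIR", "L", "HP:0001943", False),
    ("15074-8", "Qn", "FHIR", "N", "HP:0011015", True),
    ("2339-0", "Qn", "FHIR", "H", "HP:0003074", False),
    ("2339-0", "Qn", "FHIR", "L", "HP:0001943", False),
    ("2339-0", "Qn", "FHIR", "N", "HP:0011015", True),
    ("2345-7", "Qn", "FHIR", "H", "HP:0003074", False),
    ("2345-7", "Qn", "FHIR", "L", "HP:0001943", False),
    ("2345-7", "Qn", "FHIR", "N", "HP:0011015", True),
    ("90011-7", "Qn", "FHIR", "A", "HP:0003236", False),
)


def make_fixture_annotations(
    path: str | Path, panel: Sequence[PanelTest] = DEFAULT_PANEL
) -> Path:
    """Write the fixture annotation TSV (curated rows + panel-derived rows)."""
    from .annotation_store import (
        AnnotationMap,
        MappingEntry,
        OutcomeKey,
        write_annotation_tsv,
    )

    amap = AnnotationMap()
    seen: set[tuple[str, str, str]] = set()

    def add(loinc: str, scale: str, system: str, code: str, hpo: str, negated: bool) -> None:
        key = (loinc, system, code)
        if key in seen:
            return
        seen.add(key)
        outcome = (
            OutcomeKey.internal(code) if system == "FHIR"
            else OutcomeKey.external(system, code)
        )
        amap.add(MappingEntry(loinc=loinc, scale=scale, outcome=outcome, hpo=hpo,
                              negated=negated, curator="synthetic"))

    for row in _CURATED_ROWS:
        add(*row)
    for test in panel:
        abnormal_code = "H" if test.direction == "high" else "L"
        add(test.loinc, "Qn", "FHIR", abnormal_code, test.hpo, False)
        add(test.loinc, "Qn", "FHIR", "N", test.hpo, True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    write_annotation_tsv(amap, path)
    return path


# ---------------------------------------------------------------------------
# worked-example bundle
# ---------------------------------------------------------------------------

def make_fixture_bundle() -> dict:
    """Bundle of four high-glucose Observations for one patient (two of
    LOINC 15074-8, one each of 2339-0 and 2345-7) plus a Patient entry, the
    aggregation worked example: all four map to Hyperglycemia (HP:0003074)."""

    def glucose(obs_id: str, loinc: str, value: float, when: str) -> dict:
        return {
            "resourceType": "Observation",
            "id": obs_id,
            "status": "final",
            "subject": {"reference": "Patient/example-1"},
            "code": {"coding": [{"system": "http://loinc.org", "code": loinc}]},
            "effectiveDateTime": when,
            "valueQuantity": {"value": value, "unit": "mg/dL"},
            "referenceRange": [
                {"low": {"value": 70.0, "unit": "mg/dL"},
                 "high": {"value": 110.0, "unit": "mg/dL"}}
            ],
        }

    entries = [
        {"resource": {"resourceType": "Patient", "id": "example-1"}},
        {"resource": glucose("glu-1", "15074-8", 180.0, "2008-03-12")},
        {"resource": glucose("glu-2", "15074-8", 145.0, "2009-07-01")},
        {"resource": glucose("glu-3", "2339-0", 162.0, "2010-11-23")},
        {"resource": glucose("glu-4", "2345-7", 151.0, "2012-02-05")},
    ]
    return {"resourceType": "Bundle", "type": "searchset", "entry": entries}


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_VARIANTS = {
    "H": ("HH", ">", "HU", "UH"),
    "L": ("LL", "<", "LU", "D"),
    "N": ("B", "I"),
}

#: reserved LOINC-shaped codes guaranteed absent from the annotation map
_UNMAPPED_POOL = tuple(f"9{900 + i}-{i % 10}" for i in range(20))


def _iso(day_offset: int) -> str:
    return (_BASE_DATE + timedelta(days=int(day_offset))).isoformat()


def _value_for(rng: np.random.Generator, test: PanelTest, outcome: str) -> float:
    span = test.high - test.low
    if outcome == "H":
        return test.high + (0.05 + 0.45 * rng.random()) * span
    if outcome == "L":
        return test.low - (0.05 + 0.45 * rng.random()) * span
    return test.low + rng.random() * span


def _emit_observation(
    rng: np.random.Generator,
    gspec: GenerativeSpec,
    obs_id: str,
    pid: str,
    test: PanelTest,
    outcome: str,  # "H" | "L" | "N"
    when: str,
) -> dict:
    resource: dict = {
        "resourceType": "Observation",
        "id": obs_id,
        "status": "final",
        "subject": {"reference": f"Patient/{pid}"},
        "code": {"coding": [{"system": "http://loinc.org", "code": test.loinc}]},
        "effectiveDateTime": when,
    }
    if rng.random() < gspec.interpretation_only_fraction:
        code = outcome
        if rng.random() < gspec.variant_code_fraction:
            code = str(rng.choice(_VARIANTS[outcome]))
        resource["interpretation"] = {
            "coding": [{"system": "http://hl7.org/fhir/v2/0078", "code": code}]
        }
    else:
        resource["valueQuantity"] = {
            "value": round(float(_value_for(rng, test, outcome)), 4),
            "unit": test.unit,
        }
        resource["referenceRange"] = [
            {"low": {"value": test.low, "unit": test.unit},
             "high": {"value": test.high, "unit": test.unit}}
        ]
    return resource


def generate_cohort(gspec: GenerativeSpec, out_dir: str | Path) -> GeneratedCohort:
    """Generate a full synthetic cohort under ``out_dir``.

    Writes ``observations.ndjson`` (FHIR Observations, one per line),
    ``patients.csv``, ``encounters.csv``, ``medications.csv``,
    ``diagnoses.csv``, ``ground_truth.json`` and ``generative_spec.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(gspec.seed)

    tests_by_term: dict[str, list[PanelTest]] = {}
    for test in gspec.loinc_panel:
        tests_by_term.setdefault(test.hpo, []).append(test)

    unmapped_ratio = (
        gspec.unmapped_loinc_fraction / (1.0 - gspec.unmapped_loinc_fraction)
        if gspec.unmapped_loinc_fraction < 1.0
        else 0.0
    )

    obs_counter = 0
    truth_patients: dict[str, dict] = {}
    patient_rows, encounter_rows, med_rows, dx_rows = [], [], [], []
    obs_lines: list[str] = []

    for i in range(gspec.n_patients):
        pid = f"p{i:05d}"
        sex = "F" if rng.random() < 0.589 else "M"
        birth_year = 1930 + int(rng.integers(0, 60))
        patient_rows.append((pid, sex, f"{birth_year}-07-01"))

        asthma = bool(rng.random() < gspec.asthma_prevalence)
        p_freq = (
            gspec.prednisone_given_asthma if asthma else gspec.prednisone_given_no_asthma
        )
        frequent = bool(rng.random() < p_freq)
        rx_count = (
            4 + int(rng.poisson(2.0)) if frequent else int(rng.integers(0, 4))
        )

        mean_days = (
            gspec.low_utilizer_days_mean
            if rng.random() < gspec.low_utilizer_fraction
            else gspec.encounter_days_mean
        )
        n_days = max(1, int(rng.poisson(mean_days)))
        day_offsets = np.sort(
            rng.choice(_N_DAYS, size=min(n_days, _N_DAYS), replace=False)
        )
        enc_dates = [_iso(d) for d in day_offsets]
        encounter_rows += [(pid, d) for d in enc_dates]

        for _ in range(rx_count):
            med_rows.append(
                (pid, enc_dates[int(rng.integers(0, len(enc_dates)))],
                 "prednisone 10 mg oral tablet")
            )
        if asthma:
            dx_rows.append(
                (pid, enc_dates[int(rng.integers(0, len(enc_dates)))], "10", "J45.901")
            )
        dx_rows.append(
            (pid, enc_dates[int(rng.integers(0, len(enc_dates)))], "10", "J06.9")
        )

        intended: dict[str, bool] = {}
        patient_obs: list[dict] = []
        for term in sorted(gspec.phenotype_effects):
            eff = gspec.phenotype_effects[term]
            eta = (
                logit(eff.baseline_prevalence)
                + eff.log_or_prednisone * frequent
                + eff.log_or_asthma * asthma
            )
            present = bool(rng.random() < expit(eta))
            intended[term] = present
            tests = tests_by_term[term]
            if present:
                n_obs = gspec.min_obs_for_present + int(
                    rng.poisson(gspec.abnormal_extra_obs_mean)
                )
                outcome_code = "H" if tests[0].direction == "high" else "L"
            else:
                n_obs = int(rng.poisson(gspec.normal_obs_mean))
                outcome_code = "N"
            for k in range(n_obs):
                obs_counter += 1
                test = tests[k % len(tests)]
                when = enc_dates[int(rng.integers(0, len(enc_dates)))]
                patient_obs.append(
                    _emit_observation(
                        rng, gspec, f"o{obs_counter:07d}", pid, test, outcome_code, when
                    )
                )

        if gspec.nitrite_test_fraction and rng.random() < gspec.nitrite_test_fraction:
            obs_counter += 1
            pos = rng.random() < gspec.nitrituria_prevalence
            patient_obs.append(
                {
                    "resourceType": "Observation",
                    "id": f"o{obs_counter:07d}",
                    "status": "final",
                    "subject": {"reference": f"Patient/{pid}"},
                    "code": {"coding": [{"system": "http://loinc.org", "code": "32710-6"}]},
                    "effectiveDateTime": enc_dates[int(rng.integers(0, len(enc_dates)))],
                    "interpretation": {
                        "coding": [
                            {"system": "http://hl7.org/fhir/v2/0078",
                             "code": "POS" if pos else "NEG"}
                        ]
                    },
                }
            )

        # pad with annotation-less tests so the expected unmapped share is met
        n_mapped = len(patient_obs)
        for _ in range(n_mapped):
            if rng.random() < unmapped_ratio:
                obs_counter += 1
                code = str(rng.choice(_UNMAPPED_POOL))
                when = enc_dates[int(rng.integers(0, len(enc_dates)))]
                patient_obs.append(
                    {
                        "resourceType": "Observation",
                        "id": f"o{obs_counter:07d}",
                        "status": "final",
                        "subject": {"reference": f"Patient/{pid}"},
                        "code": {"coding": [{"system": "http://loinc.org", "code": code}]},
                        "effectiveDateTime": when,
                        "valueQuantity": {"value": round(float(rng.random() * 10), 4), "unit": "1"},
                        "referenceRange": [
                            {"low": {"value": 0.0, "unit": "1"},
                             "high": {"value": 10.0, "unit": "1"}}
                        ],
                    }
                )

        obs_lines += [
            json.dumps(r, sort_keys=True, separators=(",", ":")) for r in patient_obs
        ]
        truth_patients[pid] = {
            "frequent_prednisone": frequent,
            "acute_asthma": asthma,
            "prednisone_rx_count": rx_count,
            "intended_present": intended,
        }

    observations_path = out_dir / "observations.ndjson"
    observations_path.write_text("\n".join(obs_lines) + "\n", encoding="utf-8")

    csv_paths: dict[str, Path] = {}
    for name, header, rows in (
        ("patients", ("patient_id", "sex", "birth_date"), patient_rows),
        ("encounters", ("patient_id", "date"), encounter_rows),
        ("medications", ("patient_id", "date", "drug_name"), med_rows),
        ("diagnoses", ("patient_id", "date", "icd_version", "code"), dx_rows),
    ):
        p = out_dir / f"{name}.csv"
        with p.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(header)
            w.writerows(rows)
        csv_paths[name] = p

    truth = GroundTruth(
        seed=gspec.seed,
        effects=dict(gspec.phenotype_effects),
        patients=truth_patients,
    )
    (out_dir / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
    spec_doc = asdict(gspec)
    spec_doc["loinc_panel"] = [asdict(t) for t in gspec.loinc_panel]
    spec_doc["phenotype_effects"] = {
        t: asdict(e) for t, e in sorted(gspec.phenotype_effects.items())
    }
    (out_dir / "generative_spec.json").write_text(
        json.dumps(spec_doc, sort_keys=True, indent=1), encoding="utf-8"
    )
    return GeneratedCohort(
        out_dir=out_dir,
        observations_path=observations_path,
        csv_paths=csv_paths,
        ground_truth=truth,
        n_observations=obs_counter,
    )


# ---------------------------------------------------------------------------
# profile-level simulator (fast harness for the association stage)
# ---------------------------------------------------------------------------

def simulate_presence_cohort(
    n_patients: int,
    effects: Mapping[str, PhenotypeEffect],
    seed: int,
    asthma_prevalence: float = 1.0 / 3.0,
    prednisone_prevalence: float = 0.10,
    min_obs_for_present: int = 3,
) -> tuple[dict[str, PatientProfile], dict[str, Exposures]]:
    """Draw presence/absence directly at the profile level.

    Bypasses FHIR emission and conversion: each present term gets exactly
    ``min_obs_for_present`` supporting counts.  Exposures are drawn
    independently here.  Intended for association-stage calibration
    (e.g. many null replicate terms) where the upstream stages would only
    add runtime, not information.
    """
    rng = np.random.default_rng(seed)
    terms = sorted(effects)
    profiles: dict[str, PatientProfile] = {}
    exposures: dict[str, Exposures] = {}
    for i in range(n_patients):
        pid = f"s{i:06d}"
        asthma = bool(rng.random() < asthma_prevalence)
        frequent = bool(rng.random() < prednisone_prevalence)
        exposures[pid] = Exposures(frequent_prednisone=frequent, acute_asthma=asthma)
        counts: dict[str, int] = {}
        for term in terms:
            eff = effects[term]
            eta = (
                logit(eff.baseline_prevalence)
                + eff.log_or_prednisone * frequent
                + eff.log_or_asthma * asthma
            )
            if rng.random() < expit(eta):
                counts[term] = min_obs_for_present
        profiles[pid] = PatientProfile(
            patient_id=pid,
            asserted={
                (t, False): AssertedTerm(c, None, None, False) for t, c in counts.items()
            },
            propagated=dict(counts),
            _presence_counts=dict(counts),
            min_obs_for_present=min_obs_for_present,
        )
    return profiles, exposures
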