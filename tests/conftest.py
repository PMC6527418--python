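"""Shared fixtures: generated mini-ontology, fixture annotation map, helpers."""

from __future__ import annotations

import pytest

from lab2pheno.annotation_store import read_annotation_tsv
from lab2pheno.fhir_io import (
    MISSING,
    LabObservation,
    NumericValue,
    Quantity,
    ReferenceRange,
)
from lab2pheno.ontology import load_ontology
from lab2pheno.synthetic_data import (
    make_fixture_annotations,
    make_fixture_bundle,
    make_fixture_ontology,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    make_fixture_ontology(d)
    make_fixture_annotations(d / "annotations.tsv")
    return d


@pytest.fixture(scope="session")
def ont(fixture_dir):
    return load_ontology(fixture_dir / "mini_hpo.obo")


@pytest.fixture(scope="session")
def ont_json(fixture_dir):
    return load_ontology(fixture_dir / "mini_hpo.json")


@pytest.fixture(scope="session")
def amap(fixture_dir):
    return read_annotation_tsv(fixture_dir / "annotations.tsv")


@pytest.fixture(scope="session")
def glucose_bundle():
    return make_fixture_bundle()


def make_obs(
    loinc: str,
    value: float | None = None,
    low: float | None = None,
    high: float | None = None,
    unit: str = "mg/dL",
    interpretation: str | None = None,
    obs_id: str = "obs-1",
    subject: str = "pat-1",
    time: str | None = None,
) -> LabObservation:
    """Terse quantitative-observation builder for unit tests."""
    ranges = []
    if low is not None or high is not None:
        ranges.append(
            ReferenceRange(
                low=Quantity(low, unit) if low is not None else None,
                high=Quantity(high, unit) if high is not None else None,
            )
        )
    return LabObservation(
        obs_id=obs_id,
        subject_id=subject,
        loinc=loinc,
        value=NumericValue(Quantity(value, unit)) if value is not None else MISSING,
        ranges=ranges,
        interpretation_raw=interpretation,
        effective_time=time,
    )
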