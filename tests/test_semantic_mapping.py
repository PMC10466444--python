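from __future__ import annotations

import logging

import pytest

from fhiromop.etl_engine import run_job
from fhiromop.omop_store import TrackingKey
from fhiromop.semantic_mapping import (
    MiniVocabulary,
    map_resource,
    resolve_medication,
    route_by_domain,
)
from fhiromop.synthetic_data import GeneratorConfig, generate_baseline

from conftest import condition, encounter, make_envelope, patient


def medication(logical_id="m1", code="N02BE01"):
    return make_envelope(
        "Medication",
        logical_id,
        code={
            "coding": [
                {"system": "http://fhir.de/CodeSystem/bfarm/atc", "code": code}
            ]
        },
    )


def administration(logical_id="ma1", medication_id="m1"):
    return make_envelope(
        "MedicationAdministration",
        logical_id,
        subject={"reference": "Patient/p1"},
        context={"reference": "Encounter/e1"},
        medicationReference={"reference": f"Medication/{medication_id}"},
        effectiveDateTime="2023-01-04T12:00:00Z",
    )


# -- route_by_domain -------------------------------------------------------

def test_route_known_condition_code(vocab):
    table, concept_id = route_by_domain("E11.9", "ICD10GM", vocab)
    assert table == "condition_occurrence"
    assert concept_id == 2000000101


def test_route_unknown_code_falls_back_to_observation(vocab):
    assert route_by_domain("XX.X", "ICD10GM", vocab) == ("observation", 0)


def test_route_is_pure(vocab):
    assert route_by_domain("718-7", "LOINC", vocab) == route_by_domain(
        "718-7", "LOINC", vocab
    )


# -- map_resource structure ------------------------------------------------

def test_alive_patient_rows(db, vocab):
    run_job(db, [patient()], mode="bulk", vocab=vocab)
    counts = db.count_per_table()
    assert (counts["person"], counts["observation_period"], counts["death"]) == (
        1,
        1,
        0,
    )


def test_deceased_patient_gets_death_row(db, vocab):
    deceased = patient(deceasedDateTime="2023-01-20T00:00:00Z")
    run_job(db, [deceased], mode="bulk", vocab=vocab)
    assert db.count_per_table()["death"] == 1


def test_condition_cross_domain_routing(db, vocab):
    # Z98.8 carries domain Procedure in the fixture vocabulary
    run_job(
        db,
        [patient(), encounter(), condition(code="Z98.8")],
        mode="bulk",
        vocab=vocab,
    )
    counts = db.count_per_table()
    assert counts["procedure_occurrence"] == 1
    assert counts["condition_occurrence"] == 0


def test_staged_condition_emits_reciprocal_fact_pair(db, vocab):
    run_job(
        db,
        [patient(), encounter(), condition(stage="II")],
        mode="bulk",
        vocab=vocab,
    )
    facts = db.fetch_all("fact_relationship")
    assert len(facts) == 2
    a, b = facts
    assert (a["fact_id_1"], a["fact_id_2"]) == (b["fact_id_2"], b["fact_id_1"])
    assert (a["domain_concept_id_1"], a["domain_concept_id_2"]) == (
        b["domain_concept_id_2"],
        b["domain_concept_id_1"],
    )


def test_unmapped_code_routes_to_observation_not_dropped(db, vocab):
    run_job(
        db,
        [patient(), encounter(), condition(code="UNKNOWN")],
        mode="bulk",
        vocab=vocab,
    )
    rows = db.fetch_all("observation")
    assert len(rows) == 1
    assert rows[0]["observation_concept_id"] == 0


def test_dangling_patient_reference_errors(db, vocab):
    with pytest.raises(ValueError, match="Patient/p1"):
        run_job(db, [condition()], mode="bulk", vocab=vocab)


def test_map_resource_rejects_deleted(db, vocab):
    with pytest.raises(ValueError):
        map_resource(condition(deleted=True), vocab, db)


def test_encounter_produces_visit_care_site_and_details(db, vocab):
    enc = encounter(
        location=[
            {
                "location": {"display": "Ward A"},
                "period": {
                    "start": "2023-01-03T08:00:00Z",
                    "end": "2023-01-04T08:00:00Z",
                },
            },
            {"location": {"display": "ICU"}},
        ]
    )
    run_job(db, [patient(), enc], mode="bulk", vocab=vocab)
    counts = db.count_per_table()
    assert counts["visit_occurrence"] == 1
    assert counts["visit_detail"] == 2
    assert counts["care_site"] == 1
    visit = db.fetch_all("visit_occurrence")[0]
    care_site = db.fetch_all("care_site")[0]
    assert visit["care_site_id"] == care_site["care_site_id"]
    assert visit["visit_concept_id"] == 9201  # IMP


def test_observation_routes_measurement_vs_observation(db, vocab):
    measurement = make_envelope(
        "Observation",
        "o1",
        subject={"reference": "Patient/p1"},
        code={"coding": [{"system": "http://loinc.org", "code": "718-7"}]},
        effectiveDateTime="2023-01-04T09:00:00Z",
        valueQuantity={"value": 13.4, "unit": "g/dL"},
    )
    survey = make_envelope(
        "Observation",
        "o2",
        subject={"reference": "Patient/p1"},
        code={"coding": [{"system": "http://loinc.org", "code": "72166-2"}]},
        effectiveDateTime="2023-01-04T09:00:00Z",
    )
    run_job(db, [patient(), measurement, survey], mode="bulk", vocab=vocab)
    counts = db.count_per_table()
    assert counts["measurement"] == 1
    assert counts["observation"] == 1
    assert db.fetch_all("measurement")[0]["value_as_number"] == 13.4


# -- medication resolution -------------------------------------------------

def test_administration_resolves_drug_code(db, vocab):
    run_job(
        db,
        [patient(), encounter(), medication(), administration()],
        mode="bulk",
        vocab=vocab,
    )
    (row,) = db.fetch_all("drug_exposure")
    assert row["drug_source_value"] == "ATC|N02BE01"
    assert row["drug_concept_id"] == 2000000401
    # Medication itself produced no standardized rows
    assert db.count_per_table()["drug_exposure"] == 1


def test_missing_medication_yields_unmapped_row_and_warning(db, vocab, caplog):
    with caplog.at_level(logging.WARNING):
        run_job(
            db,
            [patient(), encounter(), administration(medication_id="ghost")],
            mode="bulk",
            vocab=vocab,
        )
    (row,) = db.fetch_all("drug_exposure")
    assert row["drug_concept_id"] == 0
    assert any("Medication/ghost" in record.message for record in caplog.records)


def test_two_usages_of_one_medication_resolve_identically(db, vocab):
    run_job(
        db,
        [
            patient(),
            encounter(),
            medication(),
            administration("ma1"),
            administration("ma2"),
        ],
        mode="bulk",
        vocab=vocab,
    )
    rows = db.fetch_all("drug_exposure")
    assert len(rows) == 2
    assert rows[0]["drug_source_value"] == rows[1]["drug_source_value"]


def test_resolve_medication_direct(db, vocab):
    db.set_medication_code("med-m1", "ATC|N02BE01")
    assert resolve_medication("Medication/m1", db) == "ATC|N02BE01"
    assert resolve_medication("Medication/missing", db) is None


# -- structural properties over generated data -----------------------------

def test_fact_relationship_count_always_even(db, vocab):
    baseline = generate_baseline(
        GeneratorConfig(n_patients=20, seed=11, stage_code_fraction=0.7), vocab
    )
    run_job(db, baseline, mode="bulk", vocab=vocab)
    assert db.count_per_table()["fact_relationship"] % 2 == 0


def test_person_count_equals_observation_period_count(db, vocab):
    baseline = generate_baseline(GeneratorConfig(n_patients=25, seed=5), vocab)
    run_job(db, baseline, mode="bulk", vocab=vocab)
    counts = db.count_per_table()
    assert counts["person"] == counts["observation_period"]


def test_vocabulary_seeded_into_source_to_concept_map(db, vocab):
    run_job(db, [], mode="bulk", vocab=vocab)
    assert db.count_per_table()["source_to_concept_map"] == len(vocab.concepts)
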