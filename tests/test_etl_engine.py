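from __future__ import annotations

from datetime import timedelta

import pytest

from fhiromop.etl_engine import compute_tracking_key, run_job
from fhiromop.omop_store import IdSpaceExhausted, TrackingKey, initialize_schema
from fhiromop.evalkit import canonical_tables

from conftest import condition, encounter, make_envelope, patient, ts

WINDOW = (ts(1), ts(31))


def incr(db, envelopes, vocab, window=WINDOW):
    return run_job(db, envelopes, mode="incremental", window=window, vocab=vocab)


# -- compute_tracking_key --------------------------------------------------

def test_tracking_key_medication_prefix():
    key = compute_tracking_key(make_envelope("Medication", "m1"))
    assert key.fhir_logical_id == "med-m1"
    assert key.fhir_identifier == ""


def test_tracking_key_statement_with_identifier():
    envelope = make_envelope("MedicationStatement", "s2", identifier="sys|A9")
    key = compute_tracking_key(envelope)
    assert (key.fhir_logical_id, key.fhir_identifier) == ("mes-s2", "mes-sys|A9")


def test_tracking_key_unsupported_type():
    with pytest.raises(ValueError, match="Device"):
        compute_tracking_key(make_envelope("Device", "d1"))


# -- process_envelope semantics --------------------------------------------

def test_new_condition_is_inserted(db, vocab):
    run_job(db, [patient(), encounter()], mode="bulk", vocab=vocab)
    report = incr(db, [condition()], vocab)
    assert report.rows_deleted == 0
    assert report.rows_inserted >= 1
    assert db.count_per_table()["condition_occurrence"] == 1


def test_updated_condition_gets_new_ids(db, vocab):
    run_job(db, [patient(), encounter(), condition(stage="II")], mode="bulk", vocab=vocab)
    old_ids = dict(db.lookup_tracking(TrackingKey("con-c1")))
    old_condition_id = db.fetch_all("condition_occurrence")[0][
        "condition_occurrence_id"
    ]
    updated = condition(stage="III", last_updated=ts(10))
    report = incr(db, [updated], vocab)
    assert report.rows_deleted == 4  # main + stage + 2 fact rows
    new_condition_id = db.fetch_all("condition_occurrence")[0][
        "condition_occurrence_id"
    ]
    assert new_condition_id > old_condition_id
    assert db.count_per_table()["condition_occurrence"] == 1


def test_deleted_condition_removed_nothing_reinserted(db, vocab):
    run_job(db, [patient(), encounter(), condition(stage="II")], mode="bulk", vocab=vocab)
    deletion = condition(deleted=True, last_updated=ts(11))
    report = incr(db, [deletion], vocab)
    assert report.deleted_resources == 1
    assert db.lookup_tracking(TrackingKey("con-c1")) == []
    counts = db.count_per_table()
    assert counts["condition_occurrence"] == 0
    assert counts["fact_relationship"] == 0


# -- upsert_in_place -------------------------------------------------------

def test_patient_update_preserves_person_id(db, vocab):
    run_job(db, [patient()], mode="bulk", vocab=vocab)
    before = db.fetch_all("person")[0]
    updated = patient(gender="female", last_updated=ts(12))
    incr(db, [updated], vocab)
    after = db.fetch_all("person")[0]
    assert after["person_id"] == before["person_id"]
    assert after["gender_concept_id"] == 8532
    assert db.count_per_table()["person"] == 1


def test_encounter_update_keeps_visit_id_and_fk_resolves(db, vocab):
    run_job(db, [patient(), encounter(), condition()], mode="bulk", vocab=vocab)
    visit_before = db.fetch_all("visit_occurrence")[0]
    updated = encounter(
        last_updated=ts(13),
        period={"start": "2023-01-03T08:00:00Z", "end": "2023-01-09T16:00:00Z"},
    )
    incr(db, [updated], vocab)
    visit_after = db.fetch_all("visit_occurrence")[0]
    assert visit_after["visit_occurrence_id"] == visit_before["visit_occurrence_id"]
    assert visit_after["visit_end_date"] == "2023-01-09"
    condition_row = db.fetch_all("condition_occurrence")[0]
    assert condition_row["visit_occurrence_id"] == visit_after["visit_occurrence_id"]


def test_upsert_of_new_patient_is_plain_insert(db, vocab):
    report = incr(db, [patient("p9")], vocab)
    assert report.rows_updated == 0
    assert db.count_per_table()["person"] == 1


def test_deleted_patient_cascades(db, vocab):
    run_job(db, [patient(), encounter(), condition(stage="II")], mode="bulk", vocab=vocab)
    incr(db, [patient(deleted=True, last_updated=ts(14))], vocab)
    counts = db.count_per_table()
    assert counts["person"] == 0
    assert counts["visit_occurrence"] == 0
    assert counts["condition_occurrence"] == 0
    assert counts["observation_period"] == 0
    # shared reference data survives
    assert counts["care_site"] == 1


def test_deleted_encounter_cascades_but_keeps_patient(db, vocab):
    run_job(db, [patient(), encounter(), condition()], mode="bulk", vocab=vocab)
    incr(db, [encounter(deleted=True, last_updated=ts(14))], vocab)
    counts = db.count_per_table()
    assert counts["person"] == 1
    assert counts["visit_occurrence"] == 0
    assert counts["condition_occurrence"] == 0
    assert counts["care_site"] == 1


# -- run modes -------------------------------------------------------------

def test_bulk_is_deterministic(db, vocab):
    envelopes = [patient(), encounter(), condition(stage="II")]
    first = run_job(db, envelopes, mode="bulk", vocab=vocab)
    second = run_job(db, envelopes, mode="bulk", vocab=vocab)
    assert first.per_table_counts == second.per_table_counts


def test_bulk_empty_source(db, vocab):
    report = run_job(db, [], mode="bulk", vocab=vocab)
    standardized = dict(report.per_table_counts)
    assert standardized.pop("source_to_concept_map") == len(vocab.concepts)
    assert all(count == 0 for count in standardized.values())


def test_bulk_one_of_each_type_hand_computed(db, vocab):
    envelopes = [
        patient(),
        encounter(),
        make_envelope(
            "Medication",
            "m1",
            code={
                "coding": [
                    {"system": "http://fhir.de/CodeSystem/bfarm/atc", "code": "N02BE01"}
                ]
            },
        ),
        condition(stage="II"),
        make_envelope(
            "Observation",
            "o1",
            subject={"reference": "Patient/p1"},
            encounter={"reference": "Encounter/e1"},
            code={"coding": [{"system": "http://loinc.org", "code": "718-7"}]},
            effectiveDateTime="2023-01-04T09:00:00Z",
            valueQuantity={"value": 1.0},
        ),
        make_envelope(
            "Procedure",
            "pr1",
            subject={"reference": "Patient/p1"},
            encounter={"reference": "Encounter/e1"},
            code={"coding": [{"system": "http://fhir.de/CodeSystem/bfarm/ops", "code": "5-470"}]},
            performedDateTime="2023-01-04T11:00:00Z",
        ),
        make_envelope(
            "MedicationAdministration",
            "ma1",
            subject={"reference": "Patient/p1"},
            context={"reference": "Encounter/e1"},
            medicationReference={"reference": "Medication/m1"},
            effectiveDateTime="2023-01-04T12:00:00Z",
        ),
        make_envelope(
            "MedicationStatement",
            "ms1",
            subject={"reference": "Patient/p1"},
            context={"reference": "Encounter/e1"},
            medicationReference={"reference": "Medication/m1"},
            effectiveDateTime="2023-01-04T13:00:00Z",
        ),
    ]
    report = run_job(db, envelopes, mode="bulk", vocab=vocab)
    expected = {
        "person": 1,
        "observation_period": 1,
        "visit_occurrence": 1,
        "visit_detail": 0,
        "condition_occurrence": 1,
        "observation": 1,  # stage row
        "measurement": 1,  # LOINC 718-7 routes to Measurement
        "procedure_occurrence": 1,
        "drug_exposure": 2,  # administration + statement
        "death": 0,
        "care_site": 1,
        "fact_relationship": 2,
        "source_to_concept_map": len(vocab.concepts),
    }
    assert report.per_table_counts == expected


def test_incremental_empty_window_changes_nothing(db, vocab):
    run_job(db, [patient(), encounter(), condition()], mode="bulk", vocab=vocab)
    before = db.count_per_table()
    report = incr(db, [], vocab, window=(ts(20), ts(21)))
    assert report.collapsed == 0
    assert db.count_per_table() == before


def test_incremental_full_history_on_empty_equals_bulk(vocab):
    envelopes = [patient(), encounter(), condition(stage="II")]
    db_bulk = initialize_schema(":memory:", "columns")
    run_job(db_bulk, envelopes, mode="bulk", vocab=vocab)
    db_incr = initialize_schema(":memory:", "columns")
    incr(db_incr, envelopes, vocab)
    assert db_bulk.count_per_table() == db_incr.count_per_table()
    assert canonical_tables(db_bulk) == canonical_tables(db_incr)
    db_bulk.close()
    db_incr.close()


def test_incremental_rerun_is_idempotent(db, vocab):
    run_job(db, [patient(), encounter()], mode="bulk", vocab=vocab)
    delta = [condition(stage="II", last_updated=ts(15))]
    incr(db, delta, vocab)
    counts_once = db.count_per_table()
    content_once = canonical_tables(db)
    incr(db, delta, vocab)
    assert db.count_per_table() == counts_once
    assert canonical_tables(db) == content_once


def test_incremental_never_touches_outside_window(db, vocab):
    run_job(db, [patient(), encounter(), condition()], mode="bulk", vocab=vocab)
    stale_delete = condition(deleted=True, last_updated=ts(2, 9))
    report = incr(db, [stale_delete], vocab, window=(ts(20), ts(21)))
    assert report.filtered == 0
    assert db.count_per_table()["condition_occurrence"] == 1


# -- transactionality ------------------------------------------------------

def test_failed_job_restores_pre_job_state(db, vocab):
    run_job(db, [patient(), encounter(), condition()], mode="bulk", vocab=vocab)
    before_counts = db.count_per_table()
    before_content = canonical_tables(db)
    bad_batch = [
        condition("c2", last_updated=ts(16)),
        condition("c3", subject="ghost", last_updated=ts(16)),  # dangling ref
    ]
    with pytest.raises(ValueError, match="Patient/ghost"):
        incr(db, bad_batch, vocab)
    assert db.count_per_table() == before_counts
    assert canonical_tables(db) == before_content


def test_failed_bulk_restores_previous_load(db, vocab):
    run_job(db, [patient(), encounter(), condition()], mode="bulk", vocab=vocab)
    before = db.count_per_table()
    with pytest.raises(ValueError):
        run_job(db, [condition("c9", subject="ghost")], mode="bulk", vocab=vocab)
    assert db.count_per_table() == before


# -- id exhaustion and documented workaround -------------------------------

def test_id_exhaustion_then_bulk_workaround(vocab):
    db = initialize_schema(":memory:", "columns", max_id=2)
    baseline = [patient(), encounter(), condition("c1"), condition("c2")]
    run_job(db, baseline, mode="bulk", vocab=vocab)  # ids 1..2 per table
    assert db.count_per_table()["condition_occurrence"] == 2
    update = condition("c1", code="I10.0", last_updated=ts(17))
    with pytest.raises(IdSpaceExhausted, match="condition_occurrence"):
        incr(db, [update], vocab)
    # failed incremental left the target intact ...
    assert db.count_per_table()["condition_occurrence"] == 2
    # ... and the documented workaround (bulk reload) succeeds
    merged = baseline + [update]
    report = run_job(db, merged, mode="bulk", vocab=vocab)
    assert report.per_table_counts["condition_occurrence"] == 2
    rows = {row["condition_source_value"] for row in db.fetch_all("condition_occurrence")}
    assert "ICD10GM|I10.0" in rows
    db.close()
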