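"""Deterministic FHIR-resource → OMOP-row transformation.

A compact, fully specified mapping for the eight supported resource types.
It deliberately preserves the structural features the incremental logic has
to cope with: cross-domain routing (a Condition code may land in
``procedure_occurrence``), multi-table outputs (Patient → person +
observation_period [+ death]), reciprocal ``fact_relationship`` pairs for
staged conditions, and reference-dependent rows (drug exposures resolved
through a separately tracked Medication resource).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

from .omop_store import OmopDatabase, TrackingKey
from .prefixes import CARE_SITE_PREFIX
from .source_model import FhirEnvelope

logger = logging.getLogger(__name__)

__all__ = [
    "MiniVocabulary",
    "MappingOutput",
    "CareSiteSpec",
    "FactLink",
    "map_resource",
    "route_by_domain",
    "resolve_medication",
    "DOMAIN_TABLE",
    "DOMAIN_CONCEPT_ID",
    "SYSTEM_TO_VOCABULARY",
]

#: OMOP domain → standardized target table
DOMAIN_TABLE = {
    "Condition": "condition_occurrence",
    "Measurement": "measurement",
    "Observation": "observation",
    "Procedure": "procedure_occurrence",
    "Drug": "drug_exposure",
}

#: domain concept ids used in fact_relationship rows
DOMAIN_CONCEPT_ID = {
    "condition_occurrence": 19,
    "measurement": 21,
    "observation": 27,
    "procedure_occurrence": 10,
    "drug_exposure": 13,
}

#: FHIR coding.system → fixture vocabulary id
SYSTEM_TO_VOCABULARY = {
    "http://fhir.de/CodeSystem/bfarm/icd-10-gm": "ICD10GM",
    "http://loinc.org": "LOINC",
    "http://fhir.de/CodeSystem/bfarm/ops": "OPS",
    "http://fhir.de/CodeSystem/bfarm/atc": "ATC",
    "https://example.org/tumor-stage": "STAGE",
}

VOCABULARY_TO_SYSTEM = {v: k for k, v in SYSTEM_TO_VOCABULARY.items()}

GENDER_CONCEPT = {"male": 8507, "female": 8532}
VISIT_CLASS_CONCEPT = {"IMP": 9201, "AMB": 9202, "EMER": 9203}

# type_concept used for all rows ("EHR" provenance) and the observation period
EHR_TYPE_CONCEPT = 32817
PERIOD_TYPE_CONCEPT = 44814724
# reciprocal relationship concept pair for condition-stage links
REL_HAS_STAGE = 44818762
REL_STAGE_OF = 44818860


class MiniVocabulary:
    """Miniature concept lookup replacing full OMOP vocabularies.

    Holds ``(source_vocabulary, source_code) → (concept_id, domain)`` and can
    emit the equivalent ``source_to_concept_map`` seed rows.
    """

    def __init__(self, concepts: list[tuple[int, str, str, str]]):
        self.concepts = concepts
        self._index: dict[tuple[str, str], tuple[int, str]] = {}
        for concept_id, code, vocabulary, domain in concepts:
            if domain not in DOMAIN_TABLE:
                raise ValueError(f"unknown domain {domain!r} for code {code!r}")
            entry = (vocabulary, code)
            if entry in self._index:
                raise ValueError(f"duplicate code {code!r} in {vocabulary!r}")
            self._index[entry] = (concept_id, domain)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MiniVocabulary":
        with open(path, encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle)
            concepts = [
                (
                    int(row["concept_id"]),
                    row["source_code"],
                    row["source_vocabulary"],
                    row["domain"],
                )
                for row in reader
            ]
        return cls(concepts)

    @classmethod
    def default(cls) -> "MiniVocabulary":
        """The vocabulary fixture shipped with the package."""
        ref = resources.files("fhiromop").joinpath("data/vocabulary.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def lookup(self, code: str, vocabulary: str) -> tuple[int, str] | None:
        return self._index.get((vocabulary, code))

    def source_to_concept_map_rows(self) -> list[dict[str, Any]]:
        return [
            {
                "source_code": code,
                "source_concept_id": 0,
                "source_vocabulary_id": vocabulary,
                "source_code_description": f"{vocabulary} {code}",
                "target_concept_id": concept_id,
                "target_vocabulary_id": "None",
                "valid_start_date": "1970-01-01",
                "valid_end_date": "2099-12-31",
                "invalid_reason": None,
            }
            for concept_id, code, vocabulary, domain in self.concepts
        ]

    def drug_codes(self) -> list[str]:
        """``VOCAB|code`` strings of all Drug-domain concepts."""
        return [
            f"{vocabulary}|{code}"
            for _, code, vocabulary, domain in self.concepts
            if domain == "Drug"
        ]


@dataclass(frozen=True)
class FactLink:
    """A reciprocal fact_relationship pair between two mapped rows.

    Indices refer to positions in ``MappingOutput.rows_by_table[table]``.
    """

    table_1: str
    index_1: int
    table_2: str
    index_2: int


@dataclass(frozen=True)
class CareSiteSpec:
    """A care_site row an Encounter depends on, with its own tracking key."""

    key: TrackingKey
    row: dict[str, Any]


@dataclass
class MappingOutput:
    """Rows produced for one envelope, before surrogate-id assignment."""

    rows_by_table: dict[str, list[dict[str, Any]]] = field(default_factory=dict)
    fact_links: list[FactLink] = field(default_factory=list)
    care_site: CareSiteSpec | None = None
    medication_code: str | None = None
    requires_upsert: bool = False

    def add(self, table: str, row: dict[str, Any]) -> int:
        rows = self.rows_by_table.setdefault(table, [])
        rows.append(row)
        return len(rows) - 1


def route_by_domain(
    source_code: str, source_vocabulary: str, vocab: MiniVocabulary
) -> tuple[str, int]:
    """Target table and concept for a coded value; unknown → (observation, 0)."""
    hit = vocab.lookup(source_code, source_vocabulary)
    if hit is None:
        return ("observation", 0)
    concept_id, domain = hit
    return (DOMAIN_TABLE[domain], concept_id)


def resolve_medication(reference: str, db: OmopDatabase) -> str | None:
    """Resolve ``Medication/<id>`` to its cached ``VOCAB|code`` drug code.

    Returns None (with a warning) when the Medication was never loaded; the
    caller then writes an unmapped drug_exposure row instead of dropping it.
    """
    medication_id = reference.rsplit("/", 1)[-1]
    code = db.get_medication_code(f"med-{medication_id}")
    if code is None:
        logger.warning("unresolvable medication reference %s", reference)
    return code


# -- helpers ---------------------------------------------------------------


def _first_coding(payload: dict[str, Any], element: str = "code") -> tuple[str, str]:
    """(vocabulary, code) of the first coding of ``payload[element]``."""
    codings = payload.get(element, {}).get("coding") or []
    if not codings:
        return ("", "")
    system = codings[0].get("system", "")
    code = codings[0].get("code", "")
    return (SYSTEM_TO_VOCABULARY.get(system, system), code)


def _reference_id(payload: dict[str, Any], element: str) -> str | None:
    ref = payload.get(element, {}).get("reference")
    if not ref:
        return None
    return ref.rsplit("/", 1)[-1]


def _require_person(db: OmopDatabase, payload: dict, envelope: FhirEnvelope) -> int:
    patient_id = _reference_id(payload, "subject")
    if patient_id is None:
        raise ValueError(
            f"{envelope.resource_type}/{envelope.logical_id} has no subject"
        )
    person_id = db.find_row_id("person", TrackingKey(f"pat-{patient_id}"))
    if person_id is None:
        raise ValueError(
            f"dangling reference Patient/{patient_id} in "
            f"{envelope.resource_type}/{envelope.logical_id}"
        )
    return person_id


def _optional_visit(
    db: OmopDatabase, payload: dict, envelope: FhirEnvelope, element: str
) -> int | None:
    encounter_id = _reference_id(payload, element)
    if encounter_id is None:
        return None
    visit_id = db.find_row_id("visit_occurrence", TrackingKey(f"enc-{encounter_id}"))
    if visit_id is None:
        raise ValueError(
            f"dangling reference Encounter/{encounter_id} in "
            f"{envelope.resource_type}/{envelope.logical_id}"
        )
    return visit_id


def _date_of(value: str | None, fallback: str = "1970-01-01") -> str:
    if not value:
        return fallback
    return value[:10]


def _domain_row(
    table: str,
    *,
    person_id: int,
    visit_occurrence_id: int | None,
    date: str,
    concept_id: int,
    source_value: str,
    value_as_string: str | None = None,
    value_as_number: float | None = None,
) -> dict[str, Any]:
    """Build a row for whichever table domain routing selected."""
    if table == "condition_occurrence":
        return {
            "person_id": person_id,
            "condition_concept_id": concept_id,
            "condition_start_date": date,
            "condition_start_datetime": f"{date}T00:00:00",
            "condition_type_concept_id": EHR_TYPE_CONCEPT,
            "visit_occurrence_id": visit_occurrence_id,
            "condition_source_value": source_value,
            "condition_source_concept_id": 0,
        }
    if table == "measurement":
        return {
            "person_id": person_id,
            "measurement_concept_id": concept_id,
            "measurement_date": date,
            "measurement_datetime": f"{date}T00:00:00",
            "measurement_type_concept_id": EHR_TYPE_CONCEPT,
            "value_as_number": value_as_number,
            "visit_occurrence_id": visit_occurrence_id,
            "measurement_source_value": source_value,
            "measurement_source_concept_id": 0,
            "value_source_value": value_as_string,
        }
    if table == "observation":
        return {
            "person_id": person_id,
            "observation_concept_id": concept_id,
            "observation_date": date,
            "observation_datetime": f"{date}T00:00:00",
            "observation_type_concept_id": EHR_TYPE_CONCEPT,
            "value_as_number": value_as_number,
            "value_as_string": value_as_string,
            "visit_occurrence_id": visit_occurrence_id,
            "observation_source_value": source_value,
            "observation_source_concept_id": 0,
        }
    if table == "procedure_occurrence":
        return {
            "person_id": person_id,
            "procedure_concept_id": concept_id,
            "procedure_date": date,
            "procedure_datetime": f"{date}T00:00:00",
            "procedure_type_concept_id": EHR_TYPE_CONCEPT,
            "visit_occurrence_id": visit_occurrence_id,
            "procedure_source_value": source_value,
            "procedure_source_concept_id": 0,
        }
    if table == "drug_exposure":
        return {
            "person_id": person_id,
            "drug_concept_id": concept_id,
            "drug_exposure_start_date": date,
            "drug_exposure_start_datetime": f"{date}T00:00:00",
            "drug_exposure_end_date": date,
            "drug_exposure_end_datetime": f"{date}T00:00:00",
            "drug_type_concept_id": EHR_TYPE_CONCEPT,
            "visit_occurrence_id": visit_occurrence_id,
            "drug_source_value": source_value,
            "drug_source_concept_id": 0,
        }
    raise ValueError(f"no row builder for table {table!r}")


# -- per-type mappers ------------------------------------------------------


def _map_patient(envelope: FhirEnvelope, out: MappingOutput) -> None:
    payload = envelope.payload
    birth = payload.get("birthDate") or "1970-01-01"
    parts = (birth.split("-") + ["1", "1"])[:3]
    gender = payload.get("gender", "")
    out.add(
        "person",
        {
            "gender_concept_id": GENDER_CONCEPT.get(gender, 0),
            "year_of_birth": int(parts[0]),
            "month_of_birth": int(parts[1]),
            "day_of_birth": int(parts[2]),
            "birth_datetime": f"{birth}T00:00:00",
            "race_concept_id": 0,
            "ethnicity_concept_id": 0,
            "person_source_value": envelope.logical_id,
            "gender_source_value": gender,
            "gender_source_concept_id": 0,
        },
    )
    deceased = payload.get("deceasedDateTime")
    if deceased or payload.get("deceasedBoolean"):
        out.add(
            "death",
            {
                "death_date": _date_of(deceased),
                "death_datetime": deceased,
                "death_type_concept_id": EHR_TYPE_CONCEPT,
                "cause_concept_id": 0,
            },
        )


def _map_encounter(
    envelope: FhirEnvelope, db: OmopDatabase, out: MappingOutput
) -> None:
    payload = envelope.payload
    person_id = _require_person(db, payload, envelope)
    period = payload.get("period", {})
    start = _date_of(period.get("start"))
    end = _date_of(period.get("end"), start)
    visit_class = payload.get("class", {}).get("code", "")
    provider = payload.get("serviceProvider", {}).get("identifier")
    if provider:
        source_value = f"{provider.get('system', '')}|{provider.get('value', '')}"
        out.care_site = CareSiteSpec(
            key=TrackingKey(f"{CARE_SITE_PREFIX}-{source_value}"),
            row={
                "care_site_name": provider.get("value", ""),
                "place_of_service_concept_id": 0,
                "care_site_source_value": source_value,
            },
        )
    visit_index = out.add(
        "visit_occurrence",
        {
            "person_id": person_id,
            "visit_concept_id": VISIT_CLASS_CONCEPT.get(visit_class, 0),
            "visit_start_date": start,
            "visit_start_datetime": period.get("start"),
            "visit_end_date": end,
            "visit_end_datetime": period.get("end"),
            "visit_type_concept_id": EHR_TYPE_CONCEPT,
            "care_site_id": None,  # patched after care_site resolution
            "visit_source_value": visit_class,
            "visit_source_concept_id": 0,
        },
    )
    assert visit_index == 0
    for entry in payload.get("location") or []:
        sub_period = entry.get("period", {})
        sub_start = _date_of(sub_period.get("start"), start)
        sub_end = _date_of(sub_period.get("end"), end)
        out.add(
            "visit_detail",
            {
                "person_id": person_id,
                "visit_detail_concept_id": VISIT_CLASS_CONCEPT.get(visit_class, 0),
                "visit_detail_start_date": sub_start,
                "visit_detail_start_datetime": sub_period.get("start"),
                "visit_detail_end_date": sub_end,
                "visit_detail_end_datetime": sub_period.get("end"),
                "visit_detail_type_concept_id": EHR_TYPE_CONCEPT,
                "care_site_id": None,
                "visit_detail_source_value": entry.get("location", {}).get(
                    "display", ""
                ),
                "visit_detail_source_concept_id": 0,
                "visit_occurrence_id": None,  # patched to the new visit id
            },
        )


def _map_condition(
    envelope: FhirEnvelope, vocab: MiniVocabulary, db: OmopDatabase, out: MappingOutput
) -> None:
    payload = envelope.payload
    person_id = _require_person(db, payload, envelope)
    visit_id = _optional_visit(db, payload, envelope, "encounter")
    vocabulary, code = _first_coding(payload)
    table, concept_id = route_by_domain(code, vocabulary, vocab)
    date = _date_of(payload.get("onsetDateTime") or payload.get("recordedDate"))
    main_index = out.add(
        table,
        _domain_row(
            table,
            person_id=person_id,
            visit_occurrence_id=visit_id,
            date=date,
            concept_id=concept_id,
            source_value=f"{vocabulary}|{code}",
        ),
    )
    stages = payload.get("stage") or []
    if stages:
        stage_vocab, stage_code = _first_coding(stages[0], "summary")
        stage_table, stage_concept = route_by_domain(stage_code, stage_vocab, vocab)
        stage_index = out.add(
            stage_table,
            _domain_row(
                stage_table,
                person_id=person_id,
                visit_occurrence_id=visit_id,
                date=date,
                concept_id=stage_concept,
                source_value=f"{stage_vocab}|{stage_code}",
                value_as_string=stage_code,
            ),
        )
        out.fact_links.append(FactLink(table, main_index, stage_table, stage_index))


def _map_fhir_observation(
    envelope: FhirEnvelope, vocab: MiniVocabulary, db: OmopDatabase, out: MappingOutput
) -> None:
    payload = envelope.payload
    person_id = _require_person(db, payload, envelope)
    visit_id = _optional_visit(db, payload, envelope, "encounter")
    vocabulary, code = _first_coding(payload)
    table, concept_id = route_by_domain(code, vocabulary, vocab)
    quantity = payload.get("valueQuantity", {})
    out.add(
        table,
        _domain_row(
            table,
            person_id=person_id,
            visit_occurrence_id=visit_id,
            date=_date_of(payload.get("effectiveDateTime")),
            concept_id=concept_id,
            source_value=f"{vocabulary}|{code}",
            value_as_number=quantity.get("value"),
            value_as_string=payload.get("valueString"),
        ),
    )


def _map_procedure(
    envelope: FhirEnvelope, vocab: MiniVocabulary, db: OmopDatabase, out: MappingOutput
) -> None:
    payload = envelope.payload
    person_id = _require_person(db, payload, envelope)
    visit_id = _optional_visit(db, payload, envelope, "encounter")
    vocabulary, code = _first_coding(payload)
    hit = vocab.lookup(code, vocabulary)
    concept_id = hit[0] if hit is not None else 0
    out.add(
        "procedure_occurrence",
        _domain_row(
            "procedure_occurrence",
            person_id=person_id,
            visit_occurrence_id=visit_id,
            date=_date_of(payload.get("performedDateTime")),
            concept_id=concept_id,
            source_value=f"{vocabulary}|{code}",
        ),
    )


def _map_medication_usage(
    envelope: FhirEnvelope, vocab: MiniVocabulary, db: OmopDatabase, out: MappingOutput
) -> None:
    payload = envelope.payload
    person_id = _require_person(db, payload, envelope)
    visit_id = _optional_visit(db, payload, envelope, "context")
    reference = payload.get("medicationReference", {}).get("reference", "")
    drug_code = resolve_medication(reference, db) if reference else None
    if drug_code is None:
        concept_id, source_value = 0, reference or ""
    else:
        vocabulary, _, code = drug_code.partition("|")
        hit = vocab.lookup(code, vocabulary)
        concept_id = hit[0] if hit is not None and hit[1] == "Drug" else 0
        source_value = drug_code
    row = _domain_row(
        "drug_exposure",
        person_id=person_id,
        visit_occurrence_id=visit_id,
        date=_date_of(payload.get("effectiveDateTime")),
        concept_id=concept_id,
        source_value=source_value,
    )
    out.add("drug_exposure", row)


def _map_medication(envelope: FhirEnvelope, out: MappingOutput) -> None:
    vocabulary, code = _first_coding(envelope.payload)
    out.medication_code = f"{vocabulary}|{code}"


def map_resource(
    envelope: FhirEnvelope, vocab: MiniVocabulary, db: OmopDatabase
) -> MappingOutput:
    """Transform one non-deleted envelope into OMOP rows.

    The database handle is consulted only to resolve references (person and
    visit ids, cached medication codes); given those, the output is a pure
    function of (envelope, vocab).
    """
    if envelope.deleted:
        raise ValueError("map_resource must not be called on deleted envelopes")
    out = MappingOutput(
        requires_upsert=envelope.resource_type in ("Patient", "Encounter")
    )
    resource_type = envelope.resource_type
    if resource_type == "Patient":
        _map_patient(envelope, out)
    elif resource_type == "Encounter":
        _map_encounter(envelope, db, out)
    elif resource_type == "Condition":
        _map_condition(envelope, vocab, db, out)
    elif resource_type == "Observation":
        _map_fhir_observation(envelope, vocab, db, out)
    elif resource_type == "Procedure":
        _map_procedure(envelope, vocab, db, out)
    elif resource_type in ("MedicationAdministration", "MedicationStatement"):
        _map_medication_usage(envelope, vocab, db, out)
    elif resource_type == "Medication":
        _map_medication(envelope, out)
    else:
        raise ValueError(f"unsupported resource type {resource_type!r}")
    return out
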