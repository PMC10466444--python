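from __future__ import annotations

from datetime import datetime, timezone

import pytest

from fhiromop.omop_store import OmopDatabase, initialize_schema
from fhiromop.semantic_mapping import MiniVocabulary
from fhiromop.source_model import FhirEnvelope


def ts(day: int, hour: int = 0, minute: int = 0, second: int = 0) -> datetime:
    """Shorthand UTC timestamp inside January 2023."""
    return datetime(2023, 1, day, hour, minute, second, tzinfo=timezone.utc)


def make_envelope(
    resource_type: str,
    logical_id: str,
    *,
    last_updated: datetime | None = None,
    deleted: bool = False,
    identifier: str = "",
    **payload_fields,
) -> FhirEnvelope:
    """Handmade envelope; payload fields are merged into a minimal resource."""
    when = last_updated or ts(2, 8)
    payload = (
        {}
        if deleted
        else {
            "resourceType": resource_type,
            "id": logical_id,
            "meta": {"lastUpdated": when.isoformat().replace("+00:00", "Z")},
            **payload_fields,
        }
    )
    return FhirEnvelope(
        logical_id=logical_id,
        resource_type=resource_type,
        identifier=identifier,
        payload=payload,
        last_updated=when,
        deleted=deleted,
    )


def patient(logical_id: str = "p1", **extra) -> FhirEnvelope:
    extra.setdefault("gender", "male")
    extra.setdefault("birthDate", "1970-05-02")
    return make_envelope("Patient", logical_id, **extra)


def encounter(
    logical_id: str = "e1", subject: str = "p1", **extra
) -> FhirEnvelope:
    extra.setdefault("subject", {"reference": f"Patient/{subject}"})
    extra.setdefault("class", {"code": "IMP"})
    extra.setdefault(
        "period", {"start": "2023-01-03T08:00:00Z", "end": "2023-01-05T16:00:00Z"}
    )
    extra.setdefault(
        "serviceProvider",
        {"identifier": {"system": "https://hospital.example/org", "value": "ORG-1"}},
    )
    return make_envelope("Encounter", logical_id, **extra)


def condition(
    logical_id: str = "c1",
    subject: str = "p1",
    encounter_id: str | None = "e1",
    code: str = "E11.9",
    stage: str | None = None,
    **extra,
) -> FhirEnvelope:
    extra.setdefault("subject", {"reference": f"Patient/{subject}"})
    if encounter_id:
        extra.setdefault("encounter", {"reference": f"Encounter/{encounter_id}"})
    extra.setdefault(
        "code",
        {
            "coding": [
                {
                    "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
                    "code": code,
                }
            ]
        },
    )
    extra.setdefault("onsetDateTime", "2023-01-04T00:00:00Z")
    if stage:
        extra.setdefault(
            "stage",
            [
                {
                    "summary": {
                        "coding": [
                            {
                                "system": "https://example.org/tumor-stage",
                                "code": stage,
                            }
                        ]
                    }
                }
            ],
        )
    return make_envelope("Condition", logical_id, **extra)


@pytest.fixture(scope="session")
def vocab() -> MiniVocabulary:
    return MiniVocabulary.default()


@pytest.fixture
def db() -> OmopDatabase:
    database = initialize_schema(":memory:", "columns")
    yield database
    database.close()


@pytest.fixture(params=["columns", "mapping_tables"])
def db_any_strategy(request) -> OmopDatabase:
    database = initialize_schema(":memory:", request.param)
    yield database
    database.close()
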