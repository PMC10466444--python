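"""Synthetic FHIR R4 datasets with daily create/update/delete churn.

``generate_baseline`` emits a referentially complete set of Patient,
Encounter, Condition, Observation, Procedure, Medication and medication-use
resources; ``simulate_day`` derives one day of CUD deltas from it.  Deletes
cascade at the source level (deleting an Encounter also emits deletes for
the resources referencing it) so that a full reload of baseline+delta and an
incremental application of the delta describe the same final state.
"""

from __future__ import annotations

import csv
import json
import math
import random
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Any, Iterable, Sequence

from .semantic_mapping import MiniVocabulary, VOCABULARY_TO_SYSTEM
from .source_model import (
    DELETED_TAG_CODE,
    FhirEnvelope,
    collapse_versions,
    parse_timestamp,
)

__all__ = [
    "GeneratorConfig",
    "CudProfile",
    "generate_baseline",
    "simulate_day",
    "write_fixture",
]

_ORG_POOL = [f"ORG-{i}" for i in range(1, 6)]
_ORG_SYSTEM = "https://hospital.example/org"
_PID_SYSTEM = "https://hospital.example/pid"
_WARDS = ["Ward A", "Ward B", "ICU", "Day clinic"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the baseline generator; identical seed+config → identical data."""

    n_patients: int = 100
    encounters_per_patient: float = 2.0
    conditions_per_encounter: float = 2.0
    observations_per_encounter: float = 2.0
    procedures_per_encounter: float = 1.0
    medstatements_per_encounter: float = 1.0
    medadministrations_per_encounter: float = 0.5
    deceased_fraction: float = 0.05
    stage_code_fraction: float = 0.2
    n_medications: int = 8
    seed: int = 0
    base_date: date = date(2023, 1, 1)
    span_days: int = 90


@dataclass(frozen=True)
class CudProfile:
    """Requested create/update/delete counts per resource type for one day.

    The default rates are stand-ins (the original frequency distribution is
    not published): per 10,000 live resources of a type — 100 creates,
    50 updates, 10 deletes, with a floor of one create per present type.
    """

    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def default_for(
        cls, baseline: Sequence[FhirEnvelope], seed: int = 0
    ) -> "CudProfile":
        live: dict[str, int] = {}
        for envelope in collapse_versions(baseline):
            if not envelope.deleted:
                live[envelope.resource_type] = live.get(envelope.resource_type, 0) + 1
        counts = {}
        for resource_type, n in live.items():
            created = max(1, round(n * 0.01))
            updated = round(n * 0.005)
            deleted = round(n * 0.001)
            counts[resource_type] = (created, updated, deleted)
        # medication churn is excluded by default: re-deriving dependent drug
        # exposures when only the referenced Medication changes is out of scope
        counts.pop("Medication", None)
        return cls(counts=counts, seed=seed)


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    threshold = math.exp(-lam)
    k, product = 0, rng.random()
    while product > threshold:
        k += 1
        product *= rng.random()
    return k


def _ts(rng: random.Random, start: datetime, span_seconds: float) -> datetime:
    return start + timedelta(seconds=rng.random() * span_seconds)


def _iso(ts: datetime) -> str:
    return ts.astimezone(timezone.utc).isoformat().replace("+00:00", "Z")


def _coding(vocabulary: str, code: str) -> dict[str, Any]:
    return {
        "coding": [{"system": VOCABULARY_TO_SYSTEM[vocabulary], "code": code}]
    }


def _envelope(payload: dict[str, Any], identifier: str = "") -> FhirEnvelope:
    return FhirEnvelope(
        logical_id=payload["id"],
        resource_type=payload["resourceType"],
        identifier=identifier,
        payload=payload,
        last_updated=parse_timestamp(payload["meta"]["lastUpdated"]),
        deleted=False,
    )


def _deleted_envelope(
    resource_type: str, logical_id: str, ts: datetime
) -> FhirEnvelope:
    return FhirEnvelope(
        logical_id=logical_id,
        resource_type=resource_type,
        identifier="",
        payload={},
        last_updated=ts,
        deleted=True,
    )


class _CodePools:
    def __init__(self, vocab: MiniVocabulary):
        self.by_vocab: dict[str, list[str]] = {}
        for _, code, vocabulary, domain in vocab.concepts:
            self.by_vocab.setdefault(vocabulary, []).append(code)
        self.stage = self.by_vocab.get("STAGE", [])
        self.drugs = vocab.drug_codes()


def generate_baseline(
    config: GeneratorConfig, vocab: MiniVocabulary | None = None
) -> list[FhirEnvelope]:
    """Generate a referentially complete baseline dataset."""
    vocab = vocab or MiniVocabulary.default()
    pools = _CodePools(vocab)
    rng = random.Random(config.seed)
    span_seconds = config.span_days * 86400.0
    start = datetime.combine(config.base_date, time(0), tzinfo=timezone.utc)
    envelopes: list[FhirEnvelope] = []

    for i in range(min(config.n_medications, len(pools.drugs))):
        vocabulary, _, code = pools.drugs[i].partition("|")
        payload = {
            "resourceType": "Medication",
            "id": f"m{i + 1}",
            "meta": {"lastUpdated": _iso(_ts(rng, start, span_seconds))},
            "code": _coding(vocabulary, code),
        }
        envelopes.append(_envelope(payload))
    medication_ids = [e.logical_id for e in envelopes]

    encounter_counter = 0
    event_counter = 0
    for i in range(config.n_patients):
        patient_id = f"p{i + 1}"
        birth_year = rng.randint(1930, 2010)
        birth = date(birth_year, rng.randint(1, 12), rng.randint(1, 28))
        deceased = rng.random() < config.deceased_fraction
        identifier_value = f"PID-{i + 1:06d}"
        payload: dict[str, Any] = {
            "resourceType": "Patient",
            "id": patient_id,
            "meta": {"lastUpdated": _iso(_ts(rng, start, span_seconds))},
            "identifier": [{"system": _PID_SYSTEM, "value": identifier_value}],
            "gender": rng.choice(["male", "female"]),
            "birthDate": birth.isoformat(),
        }
        if deceased:
            death_day = config.base_date + timedelta(
                days=rng.randint(0, config.span_days - 1)
            )
            payload["deceasedDateTime"] = f"{death_day.isoformat()}T00:00:00Z"
        envelopes.append(_envelope(payload, f"{_PID_SYSTEM}|{identifier_value}"))

        for _ in range(_poisson(rng, config.encounters_per_patient)):
            encounter_counter += 1
            encounter_id = f"e{encounter_counter}"
            visit_start = config.base_date + timedelta(
                days=rng.randint(0, max(config.span_days - 1, 0))
            )
            visit_end = visit_start + timedelta(days=rng.randint(0, 10))
            org = rng.choice(_ORG_POOL)
            encounter_payload: dict[str, Any] = {
                "resourceType": "Encounter",
                "id": encounter_id,
                "meta": {"lastUpdated": _iso(_ts(rng, start, span_seconds))},
                "identifier": [
                    {
                        "system": "https://hospital.example/visit",
                        "value": f"VIS-{encounter_counter:06d}",
                    }
                ],
                "subject": {"reference": f"Patient/{patient_id}"},
                "class": {"code": rng.choice(["IMP", "AMB", "EMER"])},
                "period": {
                    "start": f"{visit_start.isoformat()}T08:00:00Z",
                    "end": f"{visit_end.isoformat()}T16:00:00Z",
                },
                "serviceProvider": {
                    "identifier": {"system": _ORG_SYSTEM, "value": org}
                },
            }
            locations = []
            for _ in range(rng.randint(0, 2)):
                locations.append(
                    {
                        "location": {"display": rng.choice(_WARDS)},
                        "period": {
                            "start": f"{visit_start.isoformat()}T08:00:00Z",
                            "end": f"{visit_end.isoformat()}T16:00:00Z",
                        },
                    }
                )
            if locations:
                encounter_payload["location"] = locations
            envelopes.append(
                _envelope(
                    encounter_payload,
                    f"https://hospital.example/visit|VIS-{encounter_counter:06d}",
                )
            )

            event_day = visit_start.isoformat()
            for _ in range(_poisson(rng, config.conditions_per_encounter)):
                event_counter += 1
                condition_payload: dict[str, Any] = {
                    "resourceType": "Condition",
                    "id": f"c{event_counter}",
                    "meta": {"lastUpdated": _iso(_ts(rng, start, span_seconds))},
                    "subject": {"reference": f"Patient/{patient_id}"},
                    "encounter": {"reference": f"Encounter/{encounter_id}"},
                    "code": _coding("ICD10GM", rng.choice(pools.by_vocab["ICD10GM"])),
                    "onsetDateTime": f"{event_day}T00:00:00Z",
                }
                if rng.random() < config.stage_code_fraction and pools.stage:
                    condition_payload["stage"] = [
                        {"summary": _coding("STAGE", rng.choice(pools.stage))}
                    ]
                envelopes.append(_envelope(condition_payload))
            for _ in range(_poisson(rng, config.observations_per_encounter)):
                event_counter += 1
                envelopes.append(
                    _envelope(
                        {
                            "resourceType": "Observation",
                            "id": f"o{event_counter}",
                            "meta": {
                                "lastUpdated": _iso(_ts(rng, start, span_seconds))
                            },
                            "subject": {"reference": f"Patient/{patient_id}"},
                            "encounter": {"reference": f"Encounter/{encounter_id}"},
                            "code": _coding(
                                "LOINC", rng.choice(pools.by_vocab["LOINC"])
                            ),
                            "effectiveDateTime": f"{event_day}T09:30:00Z",
                            "valueQuantity": {
                                "value": round(rng.uniform(0.5, 200.0), 1),
                                "unit": "arb",
                            },
                        }
                    )
                )
            for _ in range(_poisson(rng, config.procedures_per_encounter)):
                event_counter += 1
                envelopes.append(
                    _envelope(
                        {
                            "resourceType": "Procedure",
                            "id": f"pr{event_counter}",
                            "meta": {
                                "lastUpdated": _iso(_ts(rng, start, span_seconds))
                            },
                            "subject": {"reference": f"Patient/{patient_id}"},
                            "encounter": {"reference": f"Encounter/{encounter_id}"},
                            "code": _coding("OPS", rng.choice(pools.by_vocab["OPS"])),
                            "performedDateTime": f"{event_day}T11:00:00Z",
                        }
                    )
                )
            for resource_type, mean in (
                ("MedicationStatement", config.medstatements_per_encounter),
                (
                    "MedicationAdministration",
                    config.medadministrations_per_encounter,
                ),
            ):
                if not medication_ids:
                    continue
                for _ in range(_poisson(rng, mean)):
                    event_counter += 1
                    short = "ms" if resource_type == "MedicationStatement" else "ma"
                    envelopes.append(
                        _envelope(
                            {
                                "resourceType": resource_type,
                                "id": f"{short}{event_counter}",
                                "meta": {
                                    "lastUpdated": _iso(
                                        _ts(rng, start, span_seconds)
                                    )
                                },
                                "subject": {"reference": f"Patient/{patient_id}"},
                                "context": {
                                    "reference": f"Encounter/{encounter_id}"
                                },
                                "medicationReference": {
                                    "reference": (
                                        f"Medication/{rng.choice(medication_ids)}"
                                    )
                                },
                                "effectiveDateTime": f"{event_day}T12:00:00Z",
                            }
                        )
                    )
    return envelopes


# -- delta simulation ------------------------------------------------------


def _index_live(baseline: Sequence[FhirEnvelope]) -> dict[str, dict[str, FhirEnvelope]]:
    live: dict[str, dict[str, FhirEnvelope]] = {}
    for envelope in collapse_versions(baseline):
        if not envelope.deleted:
            live.setdefault(envelope.resource_type, {})[envelope.logical_id] = envelope
    return live


def _reference_id(payload: dict[str, Any], element: str) -> str | None:
    ref = payload.get(element, {}).get("reference")
    return ref.rsplit("/", 1)[-1] if ref else None


def _dependents_of(
    live: dict[str, dict[str, FhirEnvelope]],
    resource_type: str,
    logical_id: str,
) -> list[tuple[str, str]]:
    """Resources that reference (type, id) and must be deleted with it."""
    found: list[tuple[str, str]] = []
    if resource_type == "Patient":
        for other_type, members in live.items():
            for envelope in members.values():
                if _reference_id(envelope.payload, "subject") == logical_id:
                    found.append((other_type, envelope.logical_id))
    elif resource_type == "Encounter":
        for other_type, members in live.items():
            for envelope in members.values():
                element = (
                    "context"
                    if other_type
                    in ("MedicationStatement", "MedicationAdministration")
                    else "encounter"
                )
                if _reference_id(envelope.payload, element) == logical_id:
                    found.append((other_type, envelope.logical_id))
    elif resource_type == "Medication":
        for other_type in ("MedicationStatement", "MedicationAdministration"):
            for envelope in live.get(other_type, {}).values():
                ref = _reference_id(envelope.payload, "medicationReference")
                if ref == logical_id:
                    found.append((other_type, envelope.logical_id))
    return found


def _mutate_payload(
    envelope: FhirEnvelope, rng: random.Random, pools: _CodePools
) -> dict[str, Any]:
    """Return an updated copy of the payload with one observable change."""
    payload = json.loads(json.dumps(envelope.payload))
    resource_type = envelope.resource_type
    if resource_type == "Patient":
        payload["gender"] = "female" if payload.get("gender") == "male" else "male"
    elif resource_type == "Encounter":
        end = payload.get("period", {}).get("end", "2023-01-01T00:00:00Z")
        end_day = date.fromisoformat(end[:10]) + timedelta(days=1)
        payload.setdefault("period", {})["end"] = f"{end_day.isoformat()}T16:00:00Z"
    elif resource_type == "Condition":
        current = payload["code"]["coding"][0]["code"]
        choices = [c for c in pools.by_vocab["ICD10GM"] if c != current]
        payload["code"] = _coding("ICD10GM", rng.choice(choices))
    elif resource_type == "Observation":
        payload.setdefault("valueQuantity", {})["value"] = round(
            rng.uniform(0.5, 200.0), 1
        )
    elif resource_type == "Procedure":
        current = payload["code"]["coding"][0]["code"]
        choices = [c for c in pools.by_vocab["OPS"] if c != current]
        payload["code"] = _coding("OPS", rng.choice(choices))
    elif resource_type in ("MedicationStatement", "MedicationAdministration"):
        effective = payload.get("effectiveDateTime", "2023-01-01T12:00:00Z")
        day = date.fromisoformat(effective[:10]) + timedelta(days=1)
        payload["effectiveDateTime"] = f"{day.isoformat()}T12:00:00Z"
    elif resource_type == "Medication":
        vocabulary, _, code = rng.choice(pools.drugs).partition("|")
        payload["code"] = _coding(vocabulary, code)
    return payload


def simulate_day(
    baseline: Sequence[FhirEnvelope],
    profile: CudProfile,
    day: date,
    vocab: MiniVocabulary | None = None,
) -> list[FhirEnvelope]:
    """Simulate one day of CUD churn against ``baseline``.

    All delta timestamps lie within ``day`` and strictly after every
    baseline timestamp.  Deletes cascade to referencing resources.
    """
    vocab = vocab or MiniVocabulary.default()
    pools = _CodePools(vocab)
    rng = random.Random(profile.seed)
    day_start = datetime.combine(day, time(0), tzinfo=timezone.utc)
    if baseline and max(e.last_updated for e in baseline) >= day_start:
        raise ValueError("delta day must lie strictly after every baseline timestamp")
    live = _index_live(baseline)

    # --- select deletions first (with source-level cascades) --------------
    deleted: list[tuple[str, str]] = []
    deleted_set: set[tuple[str, str]] = set()

    def mark_deleted(resource_type: str, logical_id: str) -> None:
        ident = (resource_type, logical_id)
        if ident in deleted_set:
            return
        deleted_set.add(ident)
        deleted.append(ident)
        for dep_type, dep_id in _dependents_of(live, resource_type, logical_id):
            mark_deleted(dep_type, dep_id)

    for resource_type, (_, _, n_deleted) in sorted(profile.counts.items()):
        if n_deleted == 0:
            continue
        candidates = [
            lid
            for lid in sorted(live.get(resource_type, {}))
            if (resource_type, lid) not in deleted_set
        ]
        if n_deleted > len(candidates):
            raise ValueError(
                f"requested {n_deleted} deletions of {resource_type} but only "
                f"{len(candidates)} live resources remain"
            )
        for logical_id in rng.sample(candidates, n_deleted):
            mark_deleted(resource_type, logical_id)

    # --- select updates (never a resource deleted today) ------------------
    updates: list[FhirEnvelope] = []
    for resource_type, (_, n_updated, _) in sorted(profile.counts.items()):
        if n_updated == 0:
            continue
        candidates = [
            lid
            for lid in sorted(live.get(resource_type, {}))
            if (resource_type, lid) not in deleted_set
        ]
        for logical_id in rng.sample(candidates, min(n_updated, len(candidates))):
            updates.append(live[resource_type][logical_id])

    # --- creations --------------------------------------------------------
    def surviving(resource_type: str) -> list[str]:
        return [
            lid
            for lid in sorted(live.get(resource_type, {}))
            if (resource_type, lid) not in deleted_set
        ]

    encounter_subject = {
        lid: _reference_id(envelope.payload, "subject")
        for lid, envelope in live.get("Encounter", {}).items()
    }
    new_payloads: list[dict[str, Any]] = []
    patients = surviving("Patient")
    encounters = [
        lid
        for lid in surviving("Encounter")
        if ("Patient", encounter_subject[lid]) not in deleted_set
    ]
    medications = surviving("Medication")
    counter = 0

    def fresh_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"d{prefix}{counter}"

    for resource_type, (n_created, _, _) in sorted(profile.counts.items()):
        for _ in range(n_created):
            if resource_type == "Patient":
                new_id = fresh_id("p")
                payload = {
                    "resourceType": "Patient",
                    "id": new_id,
                    "identifier": [
                        {"system": _PID_SYSTEM, "value": f"PID-D{counter:06d}"}
                    ],
                    "gender": rng.choice(["male", "female"]),
                    "birthDate": date(
                        rng.randint(1930, 2010), rng.randint(1, 12), rng.randint(1, 28)
                    ).isoformat(),
                }
                patients.append(new_id)
            elif resource_type == "Encounter":
                if not patients:
                    continue
                new_id = fresh_id("e")
                org = rng.choice(_ORG_POOL)
                payload = {
                    "resourceType": "Encounter",
                    "id": new_id,
                    "subject": {"reference": f"Patient/{rng.choice(patients)}"},
                    "class": {"code": rng.choice(["IMP", "AMB"])},
                    "period": {
                        "start": f"{day.isoformat()}T08:00:00Z",
                        "end": f"{day.isoformat()}T16:00:00Z",
                    },
                    "serviceProvider": {
                        "identifier": {"system": _ORG_SYSTEM, "value": org}
                    },
                }
                encounters.append(new_id)
                encounter_subject[new_id] = _reference_id(payload, "subject")
            elif resource_type == "Medication":
                vocabulary, _, code = rng.choice(pools.drugs).partition("|")
                new_id = fresh_id("m")
                payload = {
                    "resourceType": "Medication",
                    "id": new_id,
                    "code": _coding(vocabulary, code),
                }
                medications.append(new_id)
            else:
                if not encounters:
                    continue
                encounter_id = rng.choice(encounters)
                patient_id = encounter_subject[encounter_id]
                common = {
                    "subject": {"reference": f"Patient/{patient_id}"},
                }
                if resource_type == "Condition":
                    payload = {
                        "resourceType": "Condition",
                        "id": fresh_id("c"),
                        **common,
                        "encounter": {"reference": f"Encounter/{encounter_id}"},
                        "code": _coding(
                            "ICD10GM", rng.choice(pools.by_vocab["ICD10GM"])
                        ),
                        "onsetDateTime": f"{day.isoformat()}T00:00:00Z",
                    }
                    if rng.random() < 0.2 and pools.stage:
                        payload["stage"] = [
                            {"summary": _coding("STAGE", rng.choice(pools.stage))}
                        ]
                elif resource_type == "Observation":
                    payload = {
                        "resourceType": "Observation",
                        "id": fresh_id("o"),
                        **common,
                        "encounter": {"reference": f"Encounter/{encounter_id}"},
                        "code": _coding("LOINC", rng.choice(pools.by_vocab["LOINC"])),
                        "effectiveDateTime": f"{day.isoformat()}T09:30:00Z",
                        "valueQuantity": {
                            "value": round(rng.uniform(0.5, 200.0), 1),
                            "unit": "arb",
                        },
                    }
                elif resource_type == "Procedure":
                    payload = {
                        "resourceType": "Procedure",
                        "id": fresh_id("pr"),
                        **common,
                        "encounter": {"reference": f"Encounter/{encounter_id}"},
                        "code": _coding("OPS", rng.choice(pools.by_vocab["OPS"])),
                        "performedDateTime": f"{day.isoformat()}T11:00:00Z",
                    }
                elif resource_type in (
                    "MedicationStatement",
                    "MedicationAdministration",
                ):
                    if not medications:
                        continue
                    short = "ms" if resource_type == "MedicationStatement" else "ma"
                    payload = {
                        "resourceType": resource_type,
                        "id": fresh_id(short),
                        **common,
                        "context": {"reference": f"Encounter/{encounter_id}"},
                        "medicationReference": {
                            "reference": f"Medication/{rng.choice(medications)}"
                        },
                        "effectiveDateTime": f"{day.isoformat()}T12:00:00Z",
                    }
                else:
                    raise ValueError(f"unsupported resource type {resource_type!r}")
            new_payloads.append(payload)

    # --- assign strictly increasing timestamps within the day -------------
    total_ops = len(new_payloads) + len(updates) + len(deleted)
    spacing = 86400.0 / (total_ops + 1)
    delta: list[FhirEnvelope] = []
    slot = 0

    def next_ts() -> datetime:
        nonlocal slot
        slot += 1
        return day_start + timedelta(seconds=slot * spacing)

    for payload in new_payloads:
        payload["meta"] = {"lastUpdated": _iso(next_ts())}
        identifier = ""
        entries = payload.get("identifier")
        if entries:
            identifier = f"{entries[0]['system']}|{entries[0]['value']}"
        delta.append(_envelope(payload, identifier))
    for envelope in updates:
        payload = _mutate_payload(envelope, rng, pools)
        payload["meta"] = dict(payload.get("meta", {}))
        payload["meta"]["lastUpdated"] = _iso(next_ts())
        delta.append(_envelope(payload, envelope.identifier))
    for resource_type, logical_id in deleted:
        delta.append(_deleted_envelope(resource_type, logical_id, next_ts()))
    return delta


# -- fixture serialization -------------------------------------------------


def write_fixture(
    dataset: Iterable[FhirEnvelope], dialect: str, path: str | Path
) -> Path:
    """Write a dataset in one of the two source dialects.

    Round-trips through the matching reader to an equal envelope collection.
    """
    path = Path(path)
    if dialect == "ndjson":
        with open(path, "w", encoding="utf-8") as handle:
            for envelope in dataset:
                if envelope.deleted:
                    payload = {
                        "resourceType": envelope.resource_type,
                        "id": envelope.logical_id,
                        "meta": {
                            "lastUpdated": _iso(envelope.last_updated),
                            "tag": [{"code": DELETED_TAG_CODE}],
                        },
                    }
                else:
                    payload = envelope.payload
                handle.write(json.dumps(payload, separators=(",", ":")) + "\n")
    elif dialect == "gateway_table":
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(
                ["fhir_id", "type", "data", "last_updated_at", "is_deleted"]
            )
            for envelope in dataset:
                writer.writerow(
                    [
                        envelope.logical_id,
                        envelope.resource_type,
                        ""
                        if envelope.deleted
                        else json.dumps(envelope.payload, separators=(",", ":")),
                        _iso(envelope.last_updated),
                        "true" if envelope.deleted else "false",
                    ]
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path
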