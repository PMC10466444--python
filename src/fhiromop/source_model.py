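"""Uniform representation of source FHIR resources and timestamp-based CDC.

Two source dialects are supported: NDJSON files of FHIR R4 resources (one
per line, deletions marked with a ``meta.tag`` code ``DELETED``) and a
gateway-style CSV table with columns
``fhir_id,type,data,last_updated_at,is_deleted``.  Both carry a last-updated
timestamp, which drives the change-data-capture window of incremental runs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Sequence

from .prefixes import RESOURCE_TYPES

__all__ = [
    "FhirEnvelope",
    "LoadConfig",
    "read_ndjson",
    "read_gateway_table",
    "filter_window",
    "collapse_versions",
    "parse_timestamp",
    "GATEWAY_COLUMNS",
    "DELETED_TAG_CODE",
]

#: required header of the gateway-table CSV dialect
GATEWAY_COLUMNS = ("fhir_id", "type", "data", "last_updated_at", "is_deleted")

#: meta.tag code marking a deleted resource in the NDJSON dialect
DELETED_TAG_CODE = "DELETED"


def parse_timestamp(value: str) -> datetime:
    """Parse an ISO-8601 timestamp and normalize it to UTC.

    Naive timestamps are interpreted as UTC.
    """
    ts = datetime.fromisoformat(value)
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True)
class FhirEnvelope:
    """One source FHIR resource in a dialect-independent form.

    ``identifier`` is the ``system|value`` of the first business identifier,
    or ``""`` when the resource has none.  ``payload`` holds the full parsed
    resource; deleted envelopes carry an empty payload.
    """

    logical_id: str
    resource_type: str
    identifier: str
    payload: dict[str, Any]
    last_updated: datetime
    deleted: bool = False

    def __post_init__(self) -> None:
        if not self.logical_id:
            raise ValueError("logical_id must be non-empty")
        if self.last_updated.tzinfo is None:
            object.__setattr__(
                self, "last_updated", self.last_updated.replace(tzinfo=timezone.utc)
            )
        else:
            object.__setattr__(
                self, "last_updated", self.last_updated.astimezone(timezone.utc)
            )


@dataclass
class LoadConfig:
    """Run configuration mirroring the ETL configuration file.

    ``bulkload_enabled=True`` requests a full reload; ``False`` an
    incremental load restricted to the closed window
    ``[data_begindate, data_enddate]``.
    """

    bulkload_enabled: bool
    data_begindate: datetime | None = None
    data_enddate: datetime | None = None
    tracking_strategy: str = "columns"
    source_kind: str = "ndjson"
    source_path: str = ""
    target_path: str = ""

    def __post_init__(self) -> None:
        if self.tracking_strategy not in ("columns", "mapping_tables"):
            raise ValueError(f"unknown tracking_strategy {self.tracking_strategy!r}")
        if self.source_kind not in ("ndjson", "gateway_table"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if not self.bulkload_enabled:
            if self.data_begindate is None or self.data_enddate is None:
                raise ValueError(
                    "incremental load requires data_begindate and data_enddate"
                )
            if self.data_begindate > self.data_enddate:
                raise ValueError("data_begindate must not exceed data_enddate")

    @classmethod
    def from_properties(cls, path: str | Path) -> "LoadConfig":
        """Read a ``key=value`` configuration file.

        Recognized keys: APP_BULKLOAD_ENABLED, DATA_BEGINDATE, DATA_ENDDATE,
        TRACKING_STRATEGY, SOURCE_KIND, SOURCE_PATH, TARGET_PATH.
        """
        values: dict[str, str] = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            if sep != "=":
                raise ValueError(f"malformed configuration line: {raw!r}")
            values[key.strip()] = value.strip()
        if "APP_BULKLOAD_ENABLED" not in values:
            raise ValueError("configuration is missing APP_BULKLOAD_ENABLED")
        bulk = values["APP_BULKLOAD_ENABLED"].lower() == "true"
        begin = values.get("DATA_BEGINDATE")
        end = values.get("DATA_ENDDATE")
        return cls(
            bulkload_enabled=bulk,
            data_begindate=parse_timestamp(begin) if begin else None,
            data_enddate=parse_timestamp(end) if end else None,
            tracking_strategy=values.get("TRACKING_STRATEGY", "columns"),
            source_kind=values.get("SOURCE_KIND", "ndjson"),
            source_path=values.get("SOURCE_PATH", ""),
            target_path=values.get("TARGET_PATH", ""),
        )


def _extract_identifier(payload: dict[str, Any]) -> str:
    entries = payload.get("identifier")
    if not entries:
        return ""
    first = entries[0]
    system = first.get("system", "")
    value = first.get("value", "")
    if not value and not system:
        return ""
    return f"{system}|{value}"


def _is_deleted_resource(payload: dict[str, Any]) -> bool:
    tags = payload.get("meta", {}).get("tag") or []
    return any(tag.get("code") == DELETED_TAG_CODE for tag in tags)


def read_ndjson(path: str | Path) -> list[FhirEnvelope]:
    """Read FHIR resources from an NDJSON file, one resource per line.

    Raises :class:`ValueError` naming the offending line for malformed JSON
    or resources missing ``id`` or ``meta.lastUpdated``.
    """
    envelopes: list[FhirEnvelope] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                payload = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            resource_type = payload.get("resourceType")
            if not resource_type:
                raise ValueError(f"line {lineno}: resource missing 'resourceType'")
            logical_id = payload.get("id")
            if not logical_id:
                raise ValueError(
                    f"line {lineno}: {resource_type} resource missing 'id'"
                )
            last_updated = payload.get("meta", {}).get("lastUpdated")
            if not last_updated:
                raise ValueError(
                    f"line {lineno}: {resource_type}/{logical_id} missing "
                    "'meta.lastUpdated'"
                )
            deleted = _is_deleted_resource(payload)
            envelopes.append(
                FhirEnvelope(
                    logical_id=logical_id,
                    resource_type=resource_type,
                    identifier="" if deleted else _extract_identifier(payload),
                    payload={} if deleted else payload,
                    last_updated=parse_timestamp(last_updated),
                    deleted=deleted,
                )
            )
    return envelopes


def read_gateway_table(path: str | Path) -> list[FhirEnvelope]:
    """Read FHIR resources from a gateway-style CSV table.

    The header must contain ``fhir_id,type,data,last_updated_at,is_deleted``;
    a missing column raises :class:`ValueError` naming it.
    """
    envelopes: list[FhirEnvelope] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        for column in GATEWAY_COLUMNS:
            if column not in header:
                raise ValueError(f"missing column {column}")
        for rowno, row in enumerate(reader, start=2):
            deleted = row["is_deleted"].strip().lower() == "true"
            data = row["data"].strip()
            if deleted or not data:
                payload: dict[str, Any] = {}
            else:
                try:
                    payload = json.loads(data)
                except json.JSONDecodeError as exc:
                    raise ValueError(
                        f"row {rowno}: malformed resource JSON ({exc.msg})"
                    ) from exc
            if not row["fhir_id"]:
                raise ValueError(f"row {rowno}: empty fhir_id")
            if not row["last_updated_at"]:
                raise ValueError(f"row {rowno}: empty last_updated_at")
            envelopes.append(
                FhirEnvelope(
                    logical_id=row["fhir_id"],
                    resource_type=row["type"],
                    identifier="" if deleted else _extract_identifier(payload),
                    payload=payload,
                    last_updated=parse_timestamp(row["last_updated_at"]),
                    deleted=deleted,
                )
            )
    return envelopes


def filter_window(
    envelopes: Iterable[FhirEnvelope], config: LoadConfig
) -> list[FhirEnvelope]:
    """Keep envelopes whose timestamp lies in the closed CDC window.

    Both endpoints are inclusive; source order is preserved.
    """
    if config.bulkload_enabled:
        raise ValueError("filter_window applies to incremental loads only")
    begin, end = config.data_begindate, config.data_enddate
    return [e for e in envelopes if begin <= e.last_updated <= end]


def collapse_versions(envelopes: Sequence[FhirEnvelope]) -> list[FhirEnvelope]:
    """Collapse multiple versions of one resource to its final state.

    Per ``(resource_type, logical_id)`` only the envelope with the greatest
    ``last_updated`` survives; timestamp ties are broken by source order with
    the later element winning.  Output preserves first-occurrence order.
    """
    latest: dict[tuple[str, str], FhirEnvelope] = {}
    for envelope in envelopes:
        ident = (envelope.resource_type, envelope.logical_id)
        current = latest.get(ident)
        if current is None or envelope.last_updated >= current.last_updated:
            latest[ident] = envelope
    return list(latest.values())
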