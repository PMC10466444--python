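"""Reader → Processor → Writer orchestration with a bulk/incremental switch.

A bulk run empties the target and reloads every source resource.  An
incremental run filters the source to the closed change-data-capture window,
collapses multiple versions of one resource to its final state, and applies
delete-then-reinsert semantics per resource: verify existence via the
tracking key, delete what was found, and (unless the resource is deleted in
the source) insert freshly mapped rows with new surrogate ids.  Patient and
Encounter resources are instead updated in place so that ``person_id`` and
``visit_occurrence_id`` stay stable and referential integrity is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Sequence

from .omop_store import (
    OmopDatabase,
    TrackingKey,
    initialize_schema,
)
from .prefixes import PREFIX_FOR_TYPE
from .semantic_mapping import (
    DOMAIN_CONCEPT_ID,
    REL_HAS_STAGE,
    REL_STAGE_OF,
    CareSiteSpec,
    MappingOutput,
    MiniVocabulary,
    map_resource,
)
from .source_model import (
    FhirEnvelope,
    LoadConfig,
    collapse_versions,
    filter_window,
    read_gateway_table,
    read_ndjson,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EtlJobReport",
    "compute_tracking_key",
    "run_job",
    "run_bulk",
    "run_incremental",
    "PROCESSING_ORDER",
]

#: dependency-safe processing order: FK targets before dependents
PROCESSING_ORDER = (
    "Patient",
    "Encounter",
    "Medication",
    "Condition",
    "Observation",
    "Procedure",
    "MedicationAdministration",
    "MedicationStatement",
)

#: date columns contributing to a person's observation period
_EVENT_DATE_COLUMNS = {
    "visit_occurrence": ("visit_start_date", "visit_end_date"),
    "visit_detail": ("visit_detail_start_date", "visit_detail_end_date"),
    "condition_occurrence": ("condition_start_date",),
    "drug_exposure": ("drug_exposure_start_date", "drug_exposure_end_date"),
    "procedure_occurrence": ("procedure_date",),
    "measurement": ("measurement_date",),
    "observation": ("observation_date",),
}

PERIOD_TYPE_CONCEPT = 44814724


@dataclass
class EtlJobReport:
    """Per-run counters and final table sizes."""

    mode: str
    window: tuple[datetime, datetime] | None = None
    read: int = 0
    filtered: int = 0
    collapsed: int = 0
    deleted_resources: int = 0
    rows_deleted: int = 0
    rows_inserted: int = 0
    rows_updated: int = 0
    per_table_counts: dict[str, int] = field(default_factory=dict)
    started: datetime | None = None
    finished: datetime | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "mode": self.mode,
            "window": [ts.isoformat() for ts in self.window] if self.window else None,
            "read": self.read,
            "filtered": self.filtered,
            "collapsed": self.collapsed,
            "deleted_resources": self.deleted_resources,
            "rows_deleted": self.rows_deleted,
            "rows_inserted": self.rows_inserted,
            "rows_updated": self.rows_updated,
            "per_table_counts": dict(self.per_table_counts),
            "started": self.started.isoformat() if self.started else None,
            "finished": self.finished.isoformat() if self.finished else None,
        }


def compute_tracking_key(
    envelope: FhirEnvelope, prefixes: dict[str, str] = PREFIX_FOR_TYPE
) -> TrackingKey:
    """Qualify the envelope's id and identifier with its type prefix."""
    prefix = prefixes.get(envelope.resource_type)
    if prefix is None:
        raise ValueError(f"unregistered resource type {envelope.resource_type!r}")
    identifier = (
        f"{prefix}-{envelope.identifier}" if envelope.identifier else ""
    )
    return TrackingKey(f"{prefix}-{envelope.logical_id}", identifier)


class _Job:
    """State of one running ETL job (one transaction)."""

    def __init__(
        self,
        db: OmopDatabase,
        vocab: MiniVocabulary,
        report: EtlJobReport,
        fresh_target: bool,
    ):
        self.db = db
        self.vocab = vocab
        self.report = report
        # after a truncate every existence check is vacuously empty
        self.fresh_target = fresh_target
        self.touched_persons: set[int] = set()
        self._care_site_cache: dict[str, int] = {}

    # -- shared insert machinery ------------------------------------------

    def _ensure_care_site(self, spec: CareSiteSpec) -> int:
        qualified = spec.key.fhir_logical_id
        cached = self._care_site_cache.get(qualified)
        if cached is not None:
            return cached
        if not self.fresh_target:
            existing = self.db.find_row_id("care_site", spec.key)
            if existing is not None:
                self._care_site_cache[qualified] = existing
                return existing
        (care_site_id,) = self.db.insert_rows("care_site", [spec.row], spec.key)
        self.report.rows_inserted += 1
        self._care_site_cache[qualified] = care_site_id
        return care_site_id

    def _insert_fact_links(
        self, out: MappingOutput, inserted: dict[str, list[int]], key: TrackingKey
    ) -> None:
        fact_rows = []
        for link in out.fact_links:
            id_1 = inserted[link.table_1][link.index_1]
            id_2 = inserted[link.table_2][link.index_2]
            domain_1 = DOMAIN_CONCEPT_ID[link.table_1]
            domain_2 = DOMAIN_CONCEPT_ID[link.table_2]
            fact_rows.append(
                {
                    "domain_concept_id_1": domain_1,
                    "fact_id_1": id_1,
                    "domain_concept_id_2": domain_2,
                    "fact_id_2": id_2,
                    "relationship_concept_id": REL_HAS_STAGE,
                }
            )
            fact_rows.append(
                {
                    "domain_concept_id_1": domain_2,
                    "fact_id_1": id_2,
                    "domain_concept_id_2": domain_1,
                    "fact_id_2": id_1,
                    "relationship_concept_id": REL_STAGE_OF,
                }
            )
        if fact_rows:
            self.db.insert_rows("fact_relationship", fact_rows, key)
            self.report.rows_inserted += len(fact_rows)

    def _insert_output(self, out: MappingOutput, key: TrackingKey) -> None:
        """Insert all mapped rows for one envelope (creation path)."""
        inserted: dict[str, list[int]] = {}
        person_id: int | None = None
        visit_id: int | None = None
        care_site_id: int | None = None
        if out.care_site is not None:
            care_site_id = self._ensure_care_site(out.care_site)
        for table in (
            "person",
            "visit_occurrence",
            "visit_detail",
            "condition_occurrence",
            "drug_exposure",
            "procedure_occurrence",
            "measurement",
            "observation",
            "death",
        ):
            rows = out.rows_by_table.get(table)
            if not rows:
                continue
            patched = []
            for row in rows:
                row = dict(row)
                if table == "death" and person_id is not None:
                    row["person_id"] = person_id
                if table == "visit_occurrence" and care_site_id is not None:
                    row["care_site_id"] = care_site_id
                if table == "visit_detail":
                    row["visit_occurrence_id"] = visit_id
                    row["care_site_id"] = care_site_id
                patched.append(row)
            ids = self.db.insert_rows(table, patched, key)
            inserted[table] = ids
            self.report.rows_inserted += len(ids)
            if table == "person":
                person_id = ids[0]
            if table == "visit_occurrence":
                visit_id = ids[0]
        self._insert_fact_links(out, inserted, key)
        for table, rows in out.rows_by_table.items():
            for row in rows:
                pid = row.get("person_id")
                if pid is not None:
                    self.touched_persons.add(pid)
        if person_id is not None:
            self.touched_persons.add(person_id)

    # -- per-envelope processing ------------------------------------------

    def process(self, envelope: FhirEnvelope) -> None:
        key = compute_tracking_key(envelope)
        if envelope.resource_type == "Patient":
            self._process_patient(envelope, key)
        elif envelope.resource_type == "Encounter":
            self._process_encounter(envelope, key)
        else:
            self._process_generic(envelope, key)

    def _process_generic(self, envelope: FhirEnvelope, key: TrackingKey) -> None:
        if not self.fresh_target:
            self.touched_persons |= self.db.person_ids_of_key(key)
            removed = self.db.delete_by_tracking(key)
            self.report.rows_deleted += removed
        if envelope.deleted:
            self.report.deleted_resources += 1
            return
        out = map_resource(envelope, self.vocab, self.db)
        if out.medication_code is not None:
            self.db.set_medication_code(key.fhir_logical_id, out.medication_code)
        self._insert_output(out, key)

    def _process_patient(self, envelope: FhirEnvelope, key: TrackingKey) -> None:
        person_id = (
            None if self.fresh_target else self.db.find_row_id("person", key)
        )
        if envelope.deleted:
            self.report.deleted_resources += 1
            if person_id is None:
                return
            self._cascade_delete_person(person_id, key)
            return
        out = map_resource(envelope, self.vocab, self.db)
        if person_id is None:
            self._insert_output(out, key)
            return
        # in-place update: person_id preserved, non-key columns overwritten
        person_row = out.rows_by_table["person"][0]
        self.db.update_row("person", person_id, person_row)
        self.report.rows_updated += 1
        old_death = [
            rid for table, rid in self.db.lookup_tracking(key) if table == "death"
        ]
        self.report.rows_deleted += self.db.delete_table_rows("death", old_death)
        for death_row in out.rows_by_table.get("death", []):
            death_row = dict(death_row)
            death_row["person_id"] = person_id
            self.db.insert_rows("death", [death_row], key)
            self.report.rows_inserted += 1
        self.touched_persons.add(person_id)

    def _process_encounter(self, envelope: FhirEnvelope, key: TrackingKey) -> None:
        visit_id = (
            None
            if self.fresh_target
            else self.db.find_row_id("visit_occurrence", key)
        )
        if envelope.deleted:
            self.report.deleted_resources += 1
            if visit_id is None:
                return
            self._cascade_delete_encounter(visit_id, key)
            return
        out = map_resource(envelope, self.vocab, self.db)
        if visit_id is None:
            self._insert_output(out, key)
            return
        care_site_id = (
            self._ensure_care_site(out.care_site) if out.care_site else None
        )
        visit_row = dict(out.rows_by_table["visit_occurrence"][0])
        visit_row["care_site_id"] = care_site_id
        self.db.update_row("visit_occurrence", visit_id, visit_row)
        self.report.rows_updated += 1
        old_details = [
            rid
            for table, rid in self.db.lookup_tracking(key)
            if table == "visit_detail"
        ]
        self.report.rows_deleted += self.db.delete_table_rows(
            "visit_detail", old_details
        )
        details = []
        for detail in out.rows_by_table.get("visit_detail", []):
            detail = dict(detail)
            detail["visit_occurrence_id"] = visit_id
            detail["care_site_id"] = care_site_id
            details.append(detail)
        if details:
            self.db.insert_rows("visit_detail", details, key)
            self.report.rows_inserted += len(details)
        self.touched_persons.add(visit_row["person_id"])

    # -- cascades (the source is silent on these; logged prominently) ------

    def _cascade_delete_person(self, person_id: int, key: TrackingKey) -> None:
        dependents = self.db.keys_referencing("person_id", person_id)
        dependents.discard(key.fhir_logical_id)
        logger.warning(
            "cascade delete of %s removes %d dependent resources",
            key.fhir_logical_id,
            len(dependents),
        )
        # leaves first, then encounters, then the person's own rows
        for qualified in sorted(dependents, key=lambda k: k.startswith("enc-")):
            self.report.rows_deleted += self.db.delete_by_tracking(
                TrackingKey(qualified)
            )
        self.report.rows_deleted += self.db.delete_by_tracking(key)
        self.touched_persons.discard(person_id)

    def _cascade_delete_encounter(self, visit_id: int, key: TrackingKey) -> None:
        self.touched_persons |= self.db.person_ids_of_key(key)
        dependents = self.db.keys_referencing("visit_occurrence_id", visit_id)
        dependents.discard(key.fhir_logical_id)
        logger.warning(
            "cascade delete of %s removes %d dependent resources",
            key.fhir_logical_id,
            len(dependents),
        )
        for qualified in dependents:
            self.report.rows_deleted += self.db.delete_by_tracking(
                TrackingKey(qualified)
            )
        self.report.rows_deleted += self.db.delete_by_tracking(key)

    # -- observation-period maintenance ------------------------------------

    def recompute_observation_periods(self) -> None:
        """One observation_period per touched person, spanning their events."""
        db = self.db
        persons = sorted(self.touched_persons)
        persons = [
            pid
            for pid in persons
            if db.get_row("person", pid) is not None
        ]
        if not persons:
            return
        spans: dict[int, tuple[str, str]] = {}
        for chunk_start in range(0, len(persons), 500):
            chunk = persons[chunk_start : chunk_start + 500]
            marks = ", ".join(["?"] * len(chunk))
            for table, date_columns in _EVENT_DATE_COLUMNS.items():
                mins = ", ".join(f"MIN({c}) AS min_{c}" for c in date_columns)
                maxs = ", ".join(f"MAX({c}) AS max_{c}" for c in date_columns)
                for row in db.connection.execute(
                    f"SELECT person_id, {mins}, {maxs} FROM {table} "
                    f"WHERE person_id IN ({marks}) GROUP BY person_id",
                    chunk,
                ):
                    pid = row["person_id"]
                    lo_hi = spans.get(pid)
                    for column in date_columns:
                        for value in (row[f"min_{column}"], row[f"max_{column}"]):
                            if value is None:
                                continue
                            if lo_hi is None:
                                lo_hi = (value, value)
                            else:
                                lo_hi = (min(lo_hi[0], value), max(lo_hi[1], value))
                    if lo_hi is not None:
                        spans[pid] = lo_hi
        rows: list[dict[str, Any]] = []
        keys: list[TrackingKey] = []
        for pid in persons:
            patient_key = db.patient_key_of(pid)
            if patient_key is None:
                continue
            old = [
                row["observation_period_id"]
                for row in db.connection.execute(
                    "SELECT observation_period_id FROM observation_period "
                    "WHERE person_id = ?",
                    (pid,),
                )
            ]
            db.delete_table_rows("observation_period", old)
            lo_hi = spans.get(pid)
            if lo_hi is None:
                person = db.get_row("person", pid)
                birth = (
                    f"{person['year_of_birth']:04d}-"
                    f"{person['month_of_birth'] or 1:02d}-"
                    f"{person['day_of_birth'] or 1:02d}"
                )
                lo_hi = (birth, birth)
            rows.append(
                {
                    "person_id": pid,
                    "observation_period_start_date": lo_hi[0],
                    "observation_period_end_date": lo_hi[1],
                    "period_type_concept_id": PERIOD_TYPE_CONCEPT,
                }
            )
            keys.append(patient_key)
        db.insert_rows_keyed("observation_period", rows, keys)


def _seed_vocabulary(db: OmopDatabase, vocab: MiniVocabulary) -> None:
    count = db.connection.execute(
        "SELECT COUNT(*) FROM source_to_concept_map"
    ).fetchone()[0]
    if count == 0:
        db.insert_untracked(
            "source_to_concept_map", vocab.source_to_concept_map_rows()
        )


def run_job(
    db: OmopDatabase,
    envelopes: Sequence[FhirEnvelope],
    *,
    mode: str,
    window: tuple[datetime, datetime] | None = None,
    vocab: MiniVocabulary | None = None,
) -> EtlJobReport:
    """Execute one load job over already-read envelopes (one transaction).

    ``mode`` is ``"bulk"`` (truncate, then process everything) or
    ``"incremental"`` (filter to the closed ``window``, no truncation).
    Any failure rolls the target back to its pre-job state.
    """
    if mode not in ("bulk", "incremental"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "incremental" and window is None:
        raise ValueError("incremental mode requires a window")
    vocab = vocab or MiniVocabulary.default()
    report = EtlJobReport(
        mode=mode, window=window, started=datetime.now(timezone.utc)
    )
    report.read = len(envelopes)
    if mode == "incremental":
        config = LoadConfig(
            bulkload_enabled=False,
            data_begindate=window[0],
            data_enddate=window[1],
        )
        selected = filter_window(envelopes, config)
    else:
        selected = list(envelopes)
    report.filtered = len(selected)
    collapsed = collapse_versions(selected)
    report.collapsed = len(collapsed)
    order = {rt: i for i, rt in enumerate(PROCESSING_ORDER)}
    collapsed.sort(key=lambda e: order.get(e.resource_type, len(order)))
    try:
        if mode == "bulk":
            db.truncate_all()
        _seed_vocabulary(db, vocab)
        job = _Job(db, vocab, report, fresh_target=(mode == "bulk"))
        logger.info("job start mode=%s envelopes=%d", mode, len(collapsed))
        for envelope in collapsed:
            job.process(envelope)
        job.recompute_observation_periods()
        report.per_table_counts = db.count_per_table()
        report.finished = datetime.now(timezone.utc)
        db.commit()
        logger.info(
            "job finished mode=%s inserted=%d deleted=%d updated=%d",
            mode,
            report.rows_inserted,
            report.rows_deleted,
            report.rows_updated,
        )
    except Exception:
        db.rollback()
        logger.exception("job aborted; target restored to pre-job state")
        raise
    return report


def _read_source(config: LoadConfig) -> list[FhirEnvelope]:
    if config.source_kind == "ndjson":
        return read_ndjson(config.source_path)
    return read_gateway_table(config.source_path)


def _open_target(config: LoadConfig) -> OmopDatabase:
    from pathlib import Path

    path = Path(config.target_path)
    if path.exists() and path.stat().st_size > 0:
        return OmopDatabase.open(path)
    return initialize_schema(config.target_path, config.tracking_strategy)


def run_bulk(
    config: LoadConfig, vocab: MiniVocabulary | None = None
) -> EtlJobReport:
    """Full reload driven by a :class:`LoadConfig` pointing at files."""
    if not config.bulkload_enabled:
        raise ValueError("run_bulk requires bulkload_enabled=True")
    db = _open_target(config)
    try:
        return run_job(db, _read_source(config), mode="bulk", vocab=vocab)
    finally:
        db.close()


def run_incremental(
    config: LoadConfig, vocab: MiniVocabulary | None = None
) -> EtlJobReport:
    """Windowed incremental load driven by a :class:`LoadConfig`."""
    if config.bulkload_enabled:
        raise ValueError("run_incremental requires bulkload_enabled=False")
    db = _open_target(config)
    try:
        return run_job(
            db,
            _read_source(config),
            mode="incremental",
            window=(config.data_begindate, config.data_enddate),
            vocab=vocab,
        )
    finally:
        db.close()
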