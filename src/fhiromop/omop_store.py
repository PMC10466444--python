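"""Embedded OMOP CDM v5.3.1 target store with FHIR-identity tracking.

The store keeps the 13 standardized tables in a single SQLite file (or in
memory) and records, for every standardized row, which FHIR resource it was
derived from.  Two interchangeable strategies exist:

* ``columns`` — every standardized table carries two extra columns,
  ``fhir_logical_id`` and ``fhir_identifier``;
* ``mapping_tables`` — the standardized tables are stock OMOP and a separate
  ``etl_tracking_*`` table per resource type stores
  ``(fhir_logical_id, fhir_identifier, omop_table, omop_id)`` rows.

Both strategies answer the same two questions — "which OMOP rows came from
this FHIR resource?" and "delete them" — with identical results.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

from .prefixes import PREFIX_FOR_TYPE, TYPE_FOR_PREFIX, prefix_of

__all__ = [
    "TrackingKey",
    "OmopDatabase",
    "IdSpaceExhausted",
    "initialize_schema",
    "truncate_all",
    "insert_rows",
    "lookup_tracking",
    "delete_by_tracking",
    "count_per_table",
    "STANDARD_TABLES",
    "SURROGATE_ID",
    "MAX_DEFAULT_ID",
]

MAX_DEFAULT_ID = 2**63 - 1

STRATEGIES = ("columns", "mapping_tables")

# OMOP CDM v5.3.1 column subset for the 13 target tables.
STANDARD_TABLES: dict[str, list[tuple[str, str]]] = {
    "person": [
        ("person_id", "INTEGER PRIMARY KEY"),
        ("gender_concept_id", "INTEGER NOT NULL"),
        ("year_of_birth", "INTEGER NOT NULL"),
        ("month_of_birth", "INTEGER"),
        ("day_of_birth", "INTEGER"),
        ("birth_datetime", "TEXT"),
        ("race_concept_id", "INTEGER NOT NULL"),
        ("ethnicity_concept_id", "INTEGER NOT NULL"),
        ("location_id", "INTEGER"),
        ("provider_id", "INTEGER"),
        ("care_site_id", "INTEGER"),
        ("person_source_value", "TEXT"),
        ("gender_source_value", "TEXT"),
        ("gender_source_concept_id", "INTEGER"),
        ("race_source_value", "TEXT"),
        ("race_source_concept_id", "INTEGER"),
        ("ethnicity_source_value", "TEXT"),
        ("ethnicity_source_concept_id", "INTEGER"),
    ],
    "observation_period": [
        ("observation_period_id", "INTEGER PRIMARY KEY"),
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("observation_period_start_date", "TEXT NOT NULL"),
        ("observation_period_end_date", "TEXT NOT NULL"),
        ("period_type_concept_id", "INTEGER NOT NULL"),
    ],
    "visit_occurrence": [
        ("visit_occurrence_id", "INTEGER PRIMARY KEY"),
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("visit_concept_id", "INTEGER NOT NULL"),
        ("visit_start_date", "TEXT NOT NULL"),
        ("visit_start_datetime", "TEXT"),
        ("visit_end_date", "TEXT NOT NULL"),
        ("visit_end_datetime", "TEXT"),
        ("visit_type_concept_id", "INTEGER NOT NULL"),
        ("provider_id", "INTEGER"),
        ("care_site_id", "INTEGER REFERENCES care_site(care_site_id)"),
        ("visit_source_value", "TEXT"),
        ("visit_source_concept_id", "INTEGER"),
        ("admitting_source_concept_id", "INTEGER"),
        ("admitting_source_value", "TEXT"),
        ("discharge_to_concept_id", "INTEGER"),
        ("discharge_to_source_value", "TEXT"),
        ("preceding_visit_occurrence_id", "INTEGER"),
    ],
    "visit_detail": [
        ("visit_detail_id", "INTEGER PRIMARY KEY"),
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("visit_detail_concept_id", "INTEGER NOT NULL"),
        ("visit_detail_start_date", "TEXT NOT NULL"),
        ("visit_detail_start_datetime", "TEXT"),
        ("visit_detail_end_date", "TEXT NOT NULL"),
        ("visit_detail_end_datetime", "TEXT"),
        ("visit_detail_type_concept_id", "INTEGER NOT NULL"),
        ("provider_id", "INTEGER"),
        ("care_site_id", "INTEGER REFERENCES care_site(care_site_id)"),
        ("visit_detail_source_value", "TEXT"),
        ("visit_detail_source_concept_id", "INTEGER"),
        ("admitting_source_value", "TEXT"),
        ("admitting_source_concept_id", "INTEGER"),
        ("discharge_to_source_value", "TEXT"),
        ("discharge_to_concept_id", "INTEGER"),
        ("preceding_visit_detail_id", "INTEGER"),
        ("visit_detail_parent_id", "INTEGER"),
        (
            "visit_occurrence_id",
            "INTEGER NOT NULL REFERENCES visit_occurrence(visit_occurrence_id)",
        ),
    ],
    "condition_occurrence": [
        ("condition_occurrence_id", "INTEGER PRIMARY KEY"),
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("condition_concept_id", "INTEGER NOT NULL"),
        ("condition_start_date", "TEXT NOT NULL"),
        ("condition_start_datetime", "TEXT"),
        ("condition_end_date", "TEXT"),
        ("condition_end_datetime", "TEXT"),
        ("condition_type_concept_id", "INTEGER NOT NULL"),
        ("condition_status_concept_id", "INTEGER"),
        ("stop_reason", "TEXT"),
        ("provider_id", "INTEGER"),
        (
            "visit_occurrence_id",
            "INTEGER REFERENCES visit_occurrence(visit_occurrence_id)",
        ),
        ("visit_detail_id", "INTEGER"),
        ("condition_source_value", "TEXT"),
        ("condition_source_concept_id", "INTEGER"),
        ("condition_status_source_value", "TEXT"),
    ],
    "drug_exposure": [
        ("drug_exposure_id", "INTEGER PRIMARY KEY"),
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("drug_concept_id", "INTEGER NOT NULL"),
        ("drug_exposure_start_date", "TEXT NOT NULL"),
        ("drug_exposure_start_datetime", "TEXT"),
        ("drug_exposure_end_date", "TEXT NOT NULL"),
        ("drug_exposure_end_datetime", "TEXT"),
        ("verbatim_end_date", "TEXT"),
        ("drug_type_concept_id", "INTEGER NOT NULL"),
        ("stop_reason", "TEXT"),
        ("refills", "INTEGER"),
        ("quantity", "REAL"),
        ("days_supply", "INTEGER"),
        ("sig", "TEXT"),
        ("route_concept_id", "INTEGER"),
        ("lot_number", "TEXT"),
        ("provider_id", "INTEGER"),
        (
            "visit_occurrence_id",
            "INTEGER REFERENCES visit_occurrence(visit_occurrence_id)",
        ),
        ("visit_detail_id", "INTEGER"),
        ("drug_source_value", "TEXT"),
        ("drug_source_concept_id", "INTEGER"),
        ("route_source_value", "TEXT"),
        ("dose_unit_source_value", "TEXT"),
    ],
    "procedure_occurrence": [
        ("procedure_occurrence_id", "INTEGER PRIMARY KEY"),
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("procedure_concept_id", "INTEGER NOT NULL"),
        ("procedure_date", "TEXT NOT NULL"),
        ("procedure_datetime", "TEXT"),
        ("procedure_type_concept_id", "INTEGER NOT NULL"),
        ("modifier_concept_id", "INTEGER"),
        ("quantity", "INTEGER"),
        ("provider_id", "INTEGER"),
        (
            "visit_occurrence_id",
            "INTEGER REFERENCES visit_occurrence(visit_occurrence_id)",
        ),
        ("visit_detail_id", "INTEGER"),
        ("procedure_source_value", "TEXT"),
        ("procedure_source_concept_id", "INTEGER"),
        ("modifier_source_value", "TEXT"),
    ],
    "measurement": [
        ("measurement_id", "INTEGER PRIMARY KEY"),
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("measurement_concept_id", "INTEGER NOT NULL"),
        ("measurement_date", "TEXT NOT NULL"),
        ("measurement_datetime", "TEXT"),
        ("measurement_time", "TEXT"),
        ("measurement_type_concept_id", "INTEGER NOT NULL"),
        ("operator_concept_id", "INTEGER"),
        ("value_as_number", "REAL"),
        ("value_as_concept_id", "INTEGER"),
        ("unit_concept_id", "INTEGER"),
        ("range_low", "REAL"),
        ("range_high", "REAL"),
        ("provider_id", "INTEGER"),
        (
            "visit_occurrence_id",
            "INTEGER REFERENCES visit_occurrence(visit_occurrence_id)",
        ),
        ("visit_detail_id", "INTEGER"),
        ("measurement_source_value", "TEXT"),
        ("measurement_source_concept_id", "INTEGER"),
        ("unit_source_value", "TEXT"),
        ("value_source_value", "TEXT"),
    ],
    "observation": [
        ("observation_id", "INTEGER PRIMARY KEY"),
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("observation_concept_id", "INTEGER NOT NULL"),
        ("observation_date", "TEXT NOT NULL"),
        ("observation_datetime", "TEXT"),
        ("observation_type_concept_id", "INTEGER NOT NULL"),
        ("value_as_number", "REAL"),
        ("value_as_string", "TEXT"),
        ("value_as_concept_id", "INTEGER"),
        ("qualifier_concept_id", "INTEGER"),
        ("unit_concept_id", "INTEGER"),
        ("provider_id", "INTEGER"),
        (
            "visit_occurrence_id",
            "INTEGER REFERENCES visit_occurrence(visit_occurrence_id)",
        ),
        ("visit_detail_id", "INTEGER"),
        ("observation_source_value", "TEXT"),
        ("observation_source_concept_id", "INTEGER"),
        ("unit_source_value", "TEXT"),
        ("qualifier_source_value", "TEXT"),
    ],
    "death": [
        ("person_id", "INTEGER NOT NULL REFERENCES person(person_id)"),
        ("death_date", "TEXT NOT NULL"),
        ("death_datetime", "TEXT"),
        ("death_type_concept_id", "INTEGER NOT NULL"),
        ("cause_concept_id", "INTEGER"),
        ("cause_source_value", "TEXT"),
        ("cause_source_concept_id", "INTEGER"),
    ],
    "care_site": [
        ("care_site_id", "INTEGER PRIMARY KEY"),
        ("care_site_name", "TEXT"),
        ("place_of_service_concept_id", "INTEGER"),
        ("location_id", "INTEGER"),
        ("care_site_source_value", "TEXT"),
        ("place_of_service_source_value", "TEXT"),
    ],
    "fact_relationship": [
        ("domain_concept_id_1", "INTEGER NOT NULL"),
        ("fact_id_1", "INTEGER NOT NULL"),
        ("domain_concept_id_2", "INTEGER NOT NULL"),
        ("fact_id_2", "INTEGER NOT NULL"),
        ("relationship_concept_id", "INTEGER NOT NULL"),
    ],
    "source_to_concept_map": [
        ("source_code", "TEXT NOT NULL"),
        ("source_concept_id", "INTEGER NOT NULL"),
        ("source_vocabulary_id", "TEXT NOT NULL"),
        ("source_code_description", "TEXT"),
        ("target_concept_id", "INTEGER NOT NULL"),
        ("target_vocabulary_id", "TEXT NOT NULL"),
        ("valid_start_date", "TEXT NOT NULL"),
        ("valid_end_date", "TEXT NOT NULL"),
        ("invalid_reason", "TEXT"),
    ],
}

#: surrogate-id column per table; death, fact_relationship and
#: source_to_concept_map have none (OMOP keys them differently).
SURROGATE_ID: dict[str, str] = {
    "person": "person_id",
    "observation_period": "observation_period_id",
    "visit_occurrence": "visit_occurrence_id",
    "visit_detail": "visit_detail_id",
    "condition_occurrence": "condition_occurrence_id",
    "drug_exposure": "drug_exposure_id",
    "procedure_occurrence": "procedure_occurrence_id",
    "measurement": "measurement_id",
    "observation": "observation_id",
    "care_site": "care_site_id",
}

#: deletion visits children before parents so FK constraints never trip
DELETE_ORDER = (
    "fact_relationship",
    "measurement",
    "observation",
    "condition_occurrence",
    "drug_exposure",
    "procedure_occurrence",
    "visit_detail",
    "visit_occurrence",
    "death",
    "observation_period",
    "person",
    "care_site",
    "source_to_concept_map",
)

TRACKING_COLUMNS = ("fhir_logical_id", "fhir_identifier")


class IdSpaceExhausted(RuntimeError):
    """Raised when a table's surrogate-id sequence would exceed its maximum."""


@dataclass(frozen=True)
class TrackingKey:
    """Prefix-qualified FHIR identity of one source resource.

    ``fhir_logical_id`` is always present (e.g. ``con-c9``);
    ``fhir_identifier`` may be empty when the resource carried no business
    identifier.
    """

    fhir_logical_id: str
    fhir_identifier: str = ""

    def __post_init__(self) -> None:
        prefix_of(self.fhir_logical_id)  # validates registration

    @property
    def prefix(self) -> str:
        return prefix_of(self.fhir_logical_id)


def _tracking_table_for(key: TrackingKey) -> str:
    resource_type = TYPE_FOR_PREFIX[key.prefix]
    return f"etl_tracking_{resource_type.lower()}"


TRACKING_TABLES = tuple(
    f"etl_tracking_{resource_type.lower()}" for resource_type in PREFIX_FOR_TYPE
)


class OmopDatabase:
    """Handle on one OMOP CDM target (SQLite file or ``:memory:``)."""

    def __init__(self, connection: sqlite3.Connection, strategy: str, max_id: int):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown tracking strategy {strategy!r}")
        self.connection = connection
        self.strategy = strategy
        self.max_id = max_id
        self._next_ids: dict[str, int] = {}
        self.connection.execute("PRAGMA foreign_keys = ON")
        self.connection.row_factory = sqlite3.Row

    # -- lifecycle ---------------------------------------------------------

    @classmethod
    def initialize(
        cls,
        target_path: str | Path,
        strategy: str = "columns",
        *,
        overwrite: bool = False,
        max_id: int = MAX_DEFAULT_ID,
    ) -> "OmopDatabase":
        """Create the target schema at ``target_path``.

        Refuses to touch an existing non-empty target unless ``overwrite``.
        """
        path = str(target_path)
        if path != ":memory:":
            file = Path(path)
            if file.exists() and file.stat().st_size > 0:
                if not overwrite:
                    raise FileExistsError(
                        f"target {path} already exists; pass overwrite=True"
                    )
                file.unlink()
        connection = sqlite3.connect(path)
        db = cls(connection, strategy, max_id)
        db._create_schema()
        db.commit()
        return db

    @classmethod
    def open(
        cls, target_path: str | Path, *, max_id: int | None = None
    ) -> "OmopDatabase":
        """Open an existing target, restoring its recorded strategy."""
        path = Path(target_path)
        if not path.exists():
            raise FileNotFoundError(f"no target database at {target_path}")
        connection = sqlite3.connect(str(path))
        row = connection.execute(
            "SELECT value FROM etl_meta WHERE key = 'strategy'"
        ).fetchone()
        if row is None:
            raise ValueError(f"{target_path} is not an initialized target")
        strategy = row[0]
        stored_max = connection.execute(
            "SELECT value FROM etl_meta WHERE key = 'max_id'"
        ).fetchone()
        effective_max = max_id if max_id is not None else int(stored_max[0])
        db = cls(connection, strategy, effective_max)
        db._load_sequences()
        return db

    def close(self) -> None:
        self.connection.close()

    def commit(self) -> None:
        self._flush_sequences()
        self.connection.commit()

    def rollback(self) -> None:
        self.connection.rollback()
        self._load_sequences()

    # -- schema ------------------------------------------------------------

    def _create_schema(self) -> None:
        cur = self.connection
        for table, columns in STANDARD_TABLES.items():
            cols = list(columns)
            if self.strategy == "columns":
                cols += [(c, "TEXT") for c in TRACKING_COLUMNS]
            ddl = ", ".join(f"{name} {sqltype}" for name, sqltype in cols)
            cur.execute(f"CREATE TABLE {table} ({ddl})")
            if self.strategy == "columns":
                cur.execute(
                    f"CREATE INDEX idx_{table}_flid ON {table} (fhir_logical_id)"
                )
                cur.execute(
                    f"CREATE INDEX idx_{table}_fid ON {table} (fhir_identifier)"
                )
            if "person_id" in {n for n, _ in columns} and table != "person":
                cur.execute(f"CREATE INDEX idx_{table}_pid ON {table} (person_id)")
        if self.strategy == "mapping_tables":
            for tracking in TRACKING_TABLES:
                cur.execute(
                    f"CREATE TABLE {tracking} ("
                    "fhir_logical_id TEXT NOT NULL, "
                    "fhir_identifier TEXT NOT NULL DEFAULT '', "
                    "omop_table TEXT NOT NULL, "
                    "omop_id INTEGER NOT NULL)"
                )
                cur.execute(
                    f"CREATE INDEX idx_{tracking}_flid ON {tracking} (fhir_logical_id)"
                )
                cur.execute(
                    f"CREATE INDEX idx_{tracking}_fid ON {tracking} (fhir_identifier)"
                )
        cur.execute(
            "CREATE TABLE etl_id_sequence (table_name TEXT PRIMARY KEY, "
            "next_id INTEGER NOT NULL)"
        )
        cur.execute("CREATE TABLE etl_meta (key TEXT PRIMARY KEY, value TEXT)")
        cur.execute(
            "CREATE TABLE etl_medication_cache (fhir_logical_id TEXT PRIMARY KEY, "
            "drug_code TEXT NOT NULL)"
        )
        cur.execute(
            "INSERT INTO etl_meta (key, value) VALUES ('strategy', ?)",
            (self.strategy,),
        )
        cur.execute(
            "INSERT INTO etl_meta (key, value) VALUES ('max_id', ?)",
            (str(self.max_id),),
        )
        for table in SURROGATE_ID:
            cur.execute(
                "INSERT INTO etl_id_sequence (table_name, next_id) VALUES (?, 1)",
                (table,),
            )
            self._next_ids[table] = 1

    def _load_sequences(self) -> None:
        self._next_ids = {
            row["table_name"]: row["next_id"]
            for row in self.connection.execute("SELECT * FROM etl_id_sequence")
        }

    def _flush_sequences(self) -> None:
        self.connection.executemany(
            "UPDATE etl_id_sequence SET next_id = ? WHERE table_name = ?",
            [(nxt, table) for table, nxt in self._next_ids.items()],
        )

    # -- bulk reset --------------------------------------------------------

    def truncate_all(self) -> None:
        """Empty every standardized and tracking table and reset sequences."""
        for table in DELETE_ORDER:
            self.connection.execute(f"DELETE FROM {table}")
        if self.strategy == "mapping_tables":
            for tracking in TRACKING_TABLES:
                self.connection.execute(f"DELETE FROM {tracking}")
        self.connection.execute("DELETE FROM etl_medication_cache")
        for table in SURROGATE_ID:
            self._next_ids[table] = 1

    # -- inserts -----------------------------------------------------------

    def insert_rows(
        self, table: str, rows: Sequence[dict[str, Any]], key: TrackingKey
    ) -> list[int]:
        """Insert ``rows`` under one tracking key; returns assigned ids.

        For tables without a surrogate id the SQLite rowids are returned so
        tracking and deletion work uniformly.
        """
        return self.insert_rows_keyed(table, rows, [key] * len(rows))

    def insert_rows_keyed(
        self,
        table: str,
        rows: Sequence[dict[str, Any]],
        keys: Sequence[TrackingKey],
    ) -> list[int]:
        if table not in STANDARD_TABLES:
            raise ValueError(f"unknown table {table!r}")
        if len(rows) != len(keys):
            raise ValueError("rows and keys must align")
        if not rows:
            return []
        surrogate = SURROGATE_ID.get(table)
        assigned: list[int] = []
        prepared: list[dict[str, Any]] = []
        if surrogate is not None:
            nxt = self._next_ids[table]
            if nxt + len(rows) - 1 > self.max_id:
                raise IdSpaceExhausted(f"id space exhausted in table {table}")
            for row in rows:
                row = dict(row)
                row[surrogate] = nxt
                assigned.append(nxt)
                nxt += 1
                prepared.append(row)
            self._next_ids[table] = nxt
        else:
            prepared = [dict(row) for row in rows]
        ids: list[int] = []
        for row, key in zip(prepared, keys):
            if self.strategy == "columns":
                row["fhir_logical_id"] = key.fhir_logical_id
                row["fhir_identifier"] = key.fhir_identifier
            columns = list(row)
            placeholders = ", ".join(["?"] * len(columns))
            sql = (
                f"INSERT INTO {table} ({', '.join(columns)}) "
                f"VALUES ({placeholders})"
            )
            cursor = self.connection.execute(sql, [row[c] for c in columns])
            row_id = row.get(surrogate) if surrogate else cursor.lastrowid
            ids.append(int(row_id))
            if self.strategy == "mapping_tables":
                self.connection.execute(
                    f"INSERT INTO {_tracking_table_for(key)} "
                    "(fhir_logical_id, fhir_identifier, omop_table, omop_id) "
                    "VALUES (?, ?, ?, ?)",
                    (key.fhir_logical_id, key.fhir_identifier, table, row_id),
                )
        return ids

    def insert_untracked(self, table: str, rows: Sequence[dict[str, Any]]) -> None:
        """Insert rows outside tracking (source_to_concept_map seeds)."""
        if table not in STANDARD_TABLES:
            raise ValueError(f"unknown table {table!r}")
        for row in rows:
            columns = list(row)
            placeholders = ", ".join(["?"] * len(columns))
            self.connection.execute(
                f"INSERT INTO {table} ({', '.join(columns)}) "
                f"VALUES ({placeholders})",
                [row[c] for c in columns],
            )

    def delete_table_rows(self, table: str, row_ids: Sequence[int]) -> int:
        """Delete specific rows of one table along with their tracking entries."""
        if not row_ids:
            return 0
        surrogate = SURROGATE_ID.get(table)
        id_expr = surrogate if surrogate else "rowid"
        removed = 0
        for chunk_start in range(0, len(row_ids), 500):
            chunk = list(row_ids[chunk_start : chunk_start + 500])
            marks = ", ".join(["?"] * len(chunk))
            cursor = self.connection.execute(
                f"DELETE FROM {table} WHERE {id_expr} IN ({marks})", chunk
            )
            removed += cursor.rowcount
            if self.strategy == "mapping_tables":
                for tracking in TRACKING_TABLES:
                    self.connection.execute(
                        f"DELETE FROM {tracking} WHERE omop_table = ? "
                        f"AND omop_id IN ({marks})",
                        [table, *chunk],
                    )
        return removed

    # -- tracking ----------------------------------------------------------

    def _key_predicate(self, key: TrackingKey) -> tuple[str, tuple]:
        if key.fhir_identifier:
            return (
                "(fhir_logical_id = ? OR fhir_identifier = ?)",
                (key.fhir_logical_id, key.fhir_identifier),
            )
        return ("fhir_logical_id = ?", (key.fhir_logical_id,))

    def lookup_tracking(self, key: TrackingKey) -> list[tuple[str, int]]:
        """List every ``(table, id)`` derived from the keyed FHIR resource."""
        hits: list[tuple[str, int]] = []
        if self.strategy == "columns":
            predicate, params = self._key_predicate(key)
            for table in DELETE_ORDER:
                surrogate = SURROGATE_ID.get(table)
                id_expr = surrogate if surrogate else "rowid"
                for row in self.connection.execute(
                    f"SELECT {id_expr} AS rid FROM {table} WHERE {predicate}", params
                ):
                    hits.append((table, row["rid"]))
        else:
            predicate, params = self._key_predicate(key)
            tracking = _tracking_table_for(key)
            order = {t: i for i, t in enumerate(DELETE_ORDER)}
            rows = self.connection.execute(
                f"SELECT omop_table, omop_id FROM {tracking} WHERE {predicate}",
                params,
            ).fetchall()
            hits = sorted(
                ((r["omop_table"], r["omop_id"]) for r in rows),
                key=lambda hit: (order[hit[0]], hit[1]),
            )
        return hits

    def delete_by_tracking(self, key: TrackingKey) -> int:
        """Remove every standardized row derived from the keyed resource."""
        hits = self.lookup_tracking(key)
        removed = 0
        for table, row_id in hits:
            surrogate = SURROGATE_ID.get(table)
            id_expr = surrogate if surrogate else "rowid"
            cursor = self.connection.execute(
                f"DELETE FROM {table} WHERE {id_expr} = ?", (row_id,)
            )
            removed += cursor.rowcount
        if self.strategy == "mapping_tables" and hits:
            predicate, params = self._key_predicate(key)
            self.connection.execute(
                f"DELETE FROM {_tracking_table_for(key)} WHERE {predicate}", params
            )
        if key.fhir_logical_id.startswith("med-"):
            self.connection.execute(
                "DELETE FROM etl_medication_cache WHERE fhir_logical_id = ?",
                (key.fhir_logical_id,),
            )
        return removed

    # -- counting / fetching ----------------------------------------------

    def count_per_table(self) -> dict[str, int]:
        """Exact row counts for the 13 standardized tables."""
        return {
            table: self.connection.execute(
                f"SELECT COUNT(*) FROM {table}"
            ).fetchone()[0]
            for table in STANDARD_TABLES
        }

    def fetch_all(self, table: str) -> list[dict[str, Any]]:
        return [
            dict(row) for row in self.connection.execute(f"SELECT * FROM {table}")
        ]

    def find_row_id(self, table: str, key: TrackingKey) -> int | None:
        """First id in ``table`` derived from ``key`` (None when absent)."""
        for hit_table, row_id in self.lookup_tracking(key):
            if hit_table == table:
                return row_id
        return None

    def get_row(self, table: str, row_id: int) -> dict[str, Any] | None:
        surrogate = SURROGATE_ID.get(table)
        id_expr = surrogate if surrogate else "rowid"
        row = self.connection.execute(
            f"SELECT * FROM {table} WHERE {id_expr} = ?", (row_id,)
        ).fetchone()
        return dict(row) if row else None

    def update_row(self, table: str, row_id: int, values: dict[str, Any]) -> None:
        surrogate = SURROGATE_ID.get(table)
        id_expr = surrogate if surrogate else "rowid"
        assignments = ", ".join(f"{col} = ?" for col in values)
        self.connection.execute(
            f"UPDATE {table} SET {assignments} WHERE {id_expr} = ?",
            [*values.values(), row_id],
        )

    # -- reverse lookups used by cascades and maintenance ------------------

    def _keys_for_rows(self, table: str, row_ids: Iterable[int]) -> set[str]:
        ids = list(row_ids)
        if not ids:
            return set()
        if self.strategy == "columns":
            surrogate = SURROGATE_ID.get(table)
            id_expr = surrogate if surrogate else "rowid"
            marks = ", ".join(["?"] * len(ids))
            return {
                row["fhir_logical_id"]
                for row in self.connection.execute(
                    f"SELECT DISTINCT fhir_logical_id FROM {table} "
                    f"WHERE {id_expr} IN ({marks})",
                    ids,
                )
            }
        keys: set[str] = set()
        marks = ", ".join(["?"] * len(ids))
        for tracking in TRACKING_TABLES:
            for row in self.connection.execute(
                f"SELECT DISTINCT fhir_logical_id FROM {tracking} "
                f"WHERE omop_table = ? AND omop_id IN ({marks})",
                [table, *ids],
            ):
                keys.add(row["fhir_logical_id"])
        return keys

    def keys_referencing(self, column: str, value: int) -> set[str]:
        """Qualified logical ids of resources owning rows where column=value."""
        keys: set[str] = set()
        for table, columns in STANDARD_TABLES.items():
            if column not in {name for name, _ in columns}:
                continue
            surrogate = SURROGATE_ID.get(table)
            id_expr = surrogate if surrogate else "rowid"
            ids = [
                row["rid"]
                for row in self.connection.execute(
                    f"SELECT {id_expr} AS rid FROM {table} WHERE {column} = ?",
                    (value,),
                )
            ]
            keys |= self._keys_for_rows(table, ids)
        return keys

    def person_ids_of_key(self, key: TrackingKey) -> set[int]:
        """person_id values appearing on rows tracked by ``key``."""
        persons: set[int] = set()
        for table, row_id in self.lookup_tracking(key):
            if "person_id" not in {n for n, _ in STANDARD_TABLES[table]}:
                continue
            row = self.get_row(table, row_id)
            if row and row.get("person_id") is not None:
                persons.add(row["person_id"])
        return persons

    def patient_key_of(self, person_id: int) -> TrackingKey | None:
        """Tracking key of the person row with this id, if any."""
        if self.strategy == "columns":
            row = self.connection.execute(
                "SELECT fhir_logical_id, fhir_identifier FROM person "
                "WHERE person_id = ?",
                (person_id,),
            ).fetchone()
        else:
            row = self.connection.execute(
                "SELECT fhir_logical_id, fhir_identifier FROM etl_tracking_patient "
                "WHERE omop_table = 'person' AND omop_id = ?",
                (person_id,),
            ).fetchone()
        if row is None:
            return None
        return TrackingKey(row["fhir_logical_id"], row["fhir_identifier"] or "")

    def id_to_key_map(self, table: str) -> dict[int, str]:
        """Map surrogate id (or rowid) to owning qualified logical id."""
        surrogate = SURROGATE_ID.get(table)
        id_expr = surrogate if surrogate else "rowid"
        if self.strategy == "columns":
            return {
                row["rid"]: row["fhir_logical_id"]
                for row in self.connection.execute(
                    f"SELECT {id_expr} AS rid, fhir_logical_id FROM {table}"
                )
            }
        mapping: dict[int, str] = {}
        for tracking in TRACKING_TABLES:
            for row in self.connection.execute(
                f"SELECT omop_id, fhir_logical_id FROM {tracking} "
                "WHERE omop_table = ?",
                (table,),
            ):
                mapping[row["omop_id"]] = row["fhir_logical_id"]
        return mapping

    # -- medication reference cache ---------------------------------------

    def set_medication_code(self, qualified_id: str, drug_code: str) -> None:
        self.connection.execute(
            "INSERT INTO etl_medication_cache (fhir_logical_id, drug_code) "
            "VALUES (?, ?) ON CONFLICT(fhir_logical_id) "
            "DO UPDATE SET drug_code = excluded.drug_code",
            (qualified_id, drug_code),
        )

    def get_medication_code(self, qualified_id: str) -> str | None:
        row = self.connection.execute(
            "SELECT drug_code FROM etl_medication_cache WHERE fhir_logical_id = ?",
            (qualified_id,),
        ).fetchone()
        return row["drug_code"] if row else None


# module-level functional facade mirroring the operation names


def initialize_schema(
    target_path: str | Path,
    strategy: str = "columns",
    *,
    overwrite: bool = False,
    max_id: int = MAX_DEFAULT_ID,
) -> OmopDatabase:
    return OmopDatabase.initialize(
        target_path, strategy, overwrite=overwrite, max_id=max_id
    )


def truncate_all(db: OmopDatabase) -> OmopDatabase:
    db.truncate_all()
    return db


def insert_rows(
    db: OmopDatabase, table: str, rows: Sequence[dict[str, Any]], key: TrackingKey
) -> list[int]:
    return db.insert_rows(table, rows, key)


def lookup_tracking(db: OmopDatabase, key: TrackingKey) -> list[tuple[str, int]]:
    return db.lookup_tracking(key)


def delete_by_tracking(db: OmopDatabase, key: TrackingKey) -> int:
    return db.delete_by_tracking(key)


def count_per_table(db: OmopDatabase) -> dict[str, int]:
    return db.count_per_table()
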