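"""Bulk-vs-incremental and columns-vs-mapping-tables comparisons.

Equality is checked per table by raw row count and by canonical content:
surrogate ids and every column referencing one are replaced by the tracking
key of the row they point at, so two targets loaded through different paths
(or different tracking strategies) compare equal exactly when they describe
the same clinical facts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from datetime import datetime, time as dtime, timedelta, timezone
from typing import Any

from .etl_engine import run_job
from .omop_store import (
    STANDARD_TABLES,
    SURROGATE_ID,
    OmopDatabase,
    initialize_schema,
)
from .semantic_mapping import DOMAIN_CONCEPT_ID, MiniVocabulary
from .synthetic_data import CudProfile, GeneratorConfig, generate_baseline, simulate_day

__all__ = [
    "TableComparison",
    "ComparisonReport",
    "compare_databases",
    "canonical_tables",
    "run_test_design_1",
    "run_test_design_2",
]

_TABLE_FOR_DOMAIN_CONCEPT = {v: k for k, v in DOMAIN_CONCEPT_ID.items()}

#: columns replaced by the tracking key of the row they reference
_FK_TARGET = {
    "person_id": "person",
    "visit_occurrence_id": "visit_occurrence",
    "visit_detail_id": "visit_detail",
    "care_site_id": "care_site",
}

#: columns dropped entirely from canonical content
_DROPPED = {
    "fhir_logical_id",
    "fhir_identifier",
    "preceding_visit_occurrence_id",
    "preceding_visit_detail_id",
    "visit_detail_parent_id",
}


@dataclass(frozen=True)
class TableComparison:
    count_a: int
    count_b: int
    content_equal: bool

    @property
    def count_equal(self) -> bool:
        return self.count_a == self.count_b

    @property
    def equal(self) -> bool:
        return self.count_equal and self.content_equal


@dataclass
class ComparisonReport:
    per_table: dict[str, TableComparison]
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def overall_equal(self) -> bool:
        return all(tc.equal for tc in self.per_table.values())

    def to_dict(self) -> dict[str, Any]:
        return {
            "per_table": {
                table: {
                    "count_a": tc.count_a,
                    "count_b": tc.count_b,
                    "count_equal": tc.count_equal,
                    "content_equal": tc.content_equal,
                }
                for table, tc in self.per_table.items()
            },
            "overall_equal": self.overall_equal,
            "timings_seconds": dict(self.timings),
        }


def canonical_tables(db: OmopDatabase) -> dict[str, list[tuple]]:
    """Sorted, surrogate-id-free projection of every standardized table."""
    key_maps = {table: db.id_to_key_map(table) for table in SURROGATE_ID}
    canonical: dict[str, list[tuple]] = {}
    for table, columns in STANDARD_TABLES.items():
        own_id = SURROGATE_ID.get(table)
        rows_out: list[tuple] = []
        for row in db.fetch_all(table):
            values: list[tuple[str, str]] = []
            if table == "fact_relationship":
                for side in ("1", "2"):
                    domain = row[f"domain_concept_id_{side}"]
                    target_table = _TABLE_FOR_DOMAIN_CONCEPT.get(domain)
                    fact_key = (
                        key_maps.get(target_table, {}).get(row[f"fact_id_{side}"])
                        if target_table
                        else None
                    )
                    values.append((f"fact_key_{side}", str(fact_key)))
            for name, _ in columns:
                if name in _DROPPED or name == own_id:
                    continue
                if name.startswith("fact_id_"):
                    continue
                value = row.get(name)
                if name in _FK_TARGET:
                    value = key_maps[_FK_TARGET[name]].get(value) if value else None
                values.append((name, "" if value is None else str(value)))
            rows_out.append(tuple(values))
        rows_out.sort()
        canonical[table] = rows_out
    return canonical


def compare_databases(db_a: OmopDatabase, db_b: OmopDatabase) -> ComparisonReport:
    """Compare two targets by raw counts and canonical content per table."""
    counts_a = db_a.count_per_table()
    counts_b = db_b.count_per_table()
    content_a = canonical_tables(db_a)
    content_b = canonical_tables(db_b)
    per_table = {
        table: TableComparison(
            count_a=counts_a[table],
            count_b=counts_b[table],
            content_equal=content_a[table] == content_b[table],
        )
        for table in STANDARD_TABLES
    }
    return ComparisonReport(per_table=per_table)


def _build_inputs(
    gen_config: GeneratorConfig,
    profile: CudProfile | None,
    seed: int | None,
    vocab: MiniVocabulary,
):
    if seed is not None:
        gen_config = replace(gen_config, seed=seed)
    baseline = generate_baseline(gen_config, vocab)
    day = gen_config.base_date + timedelta(days=gen_config.span_days)
    if profile is None:
        profile = CudProfile.default_for(baseline, seed=gen_config.seed + 1)
    delta = simulate_day(baseline, profile, day, vocab)
    window = (
        datetime.combine(day, dtime(0), tzinfo=timezone.utc),
        datetime.combine(day, dtime(0), tzinfo=timezone.utc) + timedelta(days=1),
    )
    return baseline, delta, window


def run_test_design_2(
    gen_config: GeneratorConfig,
    profile: CudProfile | None = None,
    seed: int | None = None,
    strategy: str = "columns",
    vocab: MiniVocabulary | None = None,
    keep_databases: bool = False,
) -> ComparisonReport | tuple[ComparisonReport, OmopDatabase, OmopDatabase]:
    """Bulk(B∪D) versus bulk(B)+incremental(D) on fresh in-memory targets.

    The report's ``overall_equal`` is the data-correctness verdict; timings
    (wall-clock seconds) are informational.
    """
    vocab = vocab or MiniVocabulary.default()
    baseline, delta, window = _build_inputs(gen_config, profile, seed, vocab)

    db_a = initialize_schema(":memory:", strategy)
    t0 = time.perf_counter()
    run_job(db_a, list(baseline) + list(delta), mode="bulk", vocab=vocab)
    t_bulk_all = time.perf_counter() - t0

    db_b = initialize_schema(":memory:", strategy)
    t0 = time.perf_counter()
    run_job(db_b, baseline, mode="bulk", vocab=vocab)
    t_bulk_base = time.perf_counter() - t0
    t0 = time.perf_counter()
    run_job(db_b, delta, mode="incremental", window=window, vocab=vocab)
    t_incremental = time.perf_counter() - t0

    report = compare_databases(db_a, db_b)
    report.timings = {
        "bulk_baseline_plus_delta": t_bulk_all,
        "bulk_baseline": t_bulk_base,
        "incremental_delta": t_incremental,
    }
    if keep_databases:
        return report, db_a, db_b
    db_a.close()
    db_b.close()
    return report


def run_test_design_1(
    gen_config: GeneratorConfig,
    profile: CudProfile | None = None,
    seed: int | None = None,
    vocab: MiniVocabulary | None = None,
) -> dict[str, Any]:
    """Columns versus mapping-tables strategy on identical inputs.

    Asserts content equality of the standardized tables and reports the
    relative timings of the two strategies (no absolute expectations).
    """
    vocab = vocab or MiniVocabulary.default()
    baseline, delta, window = _build_inputs(gen_config, profile, seed, vocab)
    databases: dict[str, OmopDatabase] = {}
    timings: dict[str, dict[str, float]] = {}
    for strategy in ("columns", "mapping_tables"):
        db = initialize_schema(":memory:", strategy)
        t0 = time.perf_counter()
        run_job(db, baseline, mode="bulk", vocab=vocab)
        t_bulk = time.perf_counter() - t0
        t0 = time.perf_counter()
        run_job(db, delta, mode="incremental", window=window, vocab=vocab)
        t_incremental = time.perf_counter() - t0
        databases[strategy] = db
        timings[strategy] = {
            "bulk": t_bulk,
            "incremental": t_incremental,
            "total": t_bulk + t_incremental,
        }
    comparison = compare_databases(databases["columns"], databases["mapping_tables"])
    for db in databases.values():
        db.close()
    columns_total = timings["columns"]["total"]
    ratio = (
        timings["mapping_tables"]["total"] / columns_total
        if columns_total > 0
        else float("nan")
    )
    return {
        "content_identical": comparison.overall_equal,
        "per_table": comparison.to_dict()["per_table"],
        "timings_seconds": timings,
        "mapping_tables_over_columns_ratio": ratio,
    }
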