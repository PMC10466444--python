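from __future__ import annotations

import itertools
import json
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, strategies as st

from fhiromop.source_model import (
    FhirEnvelope,
    LoadConfig,
    collapse_versions,
    filter_window,
    parse_timestamp,
    read_gateway_table,
    read_ndjson,
)

from conftest import make_envelope, ts


# -- read_ndjson -----------------------------------------------------------


def test_read_ndjson_direct_field_mapping(tmp_path):
    path = tmp_path / "src.ndjson"
    path.write_text(
        '{"resourceType":"Patient","id":"p1",'
        '"meta":{"lastUpdated":"2023-01-02T08:00:00Z"},'
        '"identifier":[{"system":"sys","value":"A1"}]}\n'
    )
    (envelope,) = read_ndjson(path)
    assert envelope.logical_id == "p1"
    assert envelope.resource_type == "Patient"
    assert envelope.identifier == "sys|A1"
    assert envelope.deleted is False
    assert envelope.last_updated == ts(2, 8)


def test_read_ndjson_empty_file(tmp_path):
    path = tmp_path / "empty.ndjson"
    path.write_text("")
    assert read_ndjson(path) == []


def test_read_ndjson_missing_id_names_line(tmp_path):
    lines = [
        json.dumps(
            {
                "resourceType": "Patient",
                "id": f"p{i}",
                "meta": {"lastUpdated": "2023-01-02T08:00:00Z"},
            }
        )
        for i in range(3)
    ]
    lines.append(
        json.dumps(
            {"resourceType": "Patient", "meta": {"lastUpdated": "2023-01-02T08:00:00Z"}}
        )
    )
    path = tmp_path / "bad.ndjson"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="line 4"):
        read_ndjson(path)


def test_read_ndjson_malformed_json_names_line(tmp_path):
    path = tmp_path / "bad.ndjson"
    path.write_text("{not json}\n")
    with pytest.raises(ValueError, match="line 1"):
        read_ndjson(path)


def test_read_ndjson_missing_last_updated_names_resource(tmp_path):
    path = tmp_path / "bad.ndjson"
    path.write_text('{"resourceType":"Condition","id":"c7"}\n')
    with pytest.raises(ValueError, match="Condition/c7"):
        read_ndjson(path)


def test_read_ndjson_deleted_tag(tmp_path):
    path = tmp_path / "del.ndjson"
    path.write_text(
        '{"resourceType":"Condition","id":"c9","meta":'
        '{"lastUpdated":"2023-01-02T10:00:00Z","tag":[{"code":"DELETED"}]}}\n'
    )
    (envelope,) = read_ndjson(path)
    assert envelope.deleted is True
    assert envelope.payload == {}


# -- read_gateway_table ----------------------------------------------------


def test_gateway_deleted_row(tmp_path):
    path = tmp_path / "gw.csv"
    path.write_text(
        "fhir_id,type,data,last_updated_at,is_deleted\n"
        "c9,Condition,,2023-01-02T10:00:00Z,true\n"
    )
    (envelope,) = read_gateway_table(path)
    assert envelope.deleted is True
    assert envelope.resource_type == "Condition"
    assert envelope.payload == {}


def test_gateway_missing_column(tmp_path):
    path = tmp_path / "gw.csv"
    path.write_text("fhir_id,type,data,is_deleted\nc9,Condition,,false\n")
    with pytest.raises(ValueError, match="missing column last_updated_at"):
        read_gateway_table(path)


def test_gateway_two_versions_both_read(tmp_path):
    payload = json.dumps(
        {
            "resourceType": "Condition",
            "id": "c1",
            "meta": {"lastUpdated": "2023-01-02T10:00:00Z"},
        }
    ).replace('"', '""')
    path = tmp_path / "gw.csv"
    path.write_text(
        "fhir_id,type,data,last_updated_at,is_deleted\n"
        f'c1,Condition,"{payload}",2023-01-02T10:00:00Z,false\n'
        f'c1,Condition,"{payload}",2023-01-02T11:00:00Z,false\n'
    )
    envelopes = read_gateway_table(path)
    assert len(envelopes) == 2  # collapsing happens later


# -- filter_window ---------------------------------------------------------


def incremental_config(begin, end) -> LoadConfig:
    return LoadConfig(bulkload_enabled=False, data_begindate=begin, data_enddate=end)


def test_window_closed_interval_boundaries():
    begin, end = ts(2), ts(3)
    inside_low = make_envelope("Patient", "a", last_updated=begin)
    inside_high = make_envelope("Patient", "b", last_updated=end)
    before = make_envelope("Patient", "c", last_updated=begin - timedelta(seconds=1))
    after = make_envelope("Patient", "d", last_updated=end + timedelta(seconds=1))
    result = filter_window(
        [inside_low, inside_high, before, after], incremental_config(begin, end)
    )
    assert result == [inside_low, inside_high]


def test_window_spanning_everything_is_identity():
    envelopes = [
        make_envelope("Patient", f"p{i}", last_updated=ts(2 + i)) for i in range(4)
    ]
    result = filter_window(envelopes, incremental_config(ts(1), ts(30)))
    assert result == envelopes


def test_filter_window_rejects_bulk_config():
    with pytest.raises(ValueError):
        filter_window([], LoadConfig(bulkload_enabled=True))


@given(
    st.lists(
        st.integers(min_value=0, max_value=10_000),
        max_size=40,
    ),
    st.integers(min_value=0, max_value=10_000),
    st.integers(min_value=0, max_value=10_000),
)
def test_filter_window_idempotent(offsets, lo, hi):
    lo, hi = min(lo, hi), max(lo, hi)
    base = datetime(2023, 1, 1, tzinfo=timezone.utc)
    envelopes = [
        make_envelope("Patient", f"p{i}", last_updated=base + timedelta(minutes=m))
        for i, m in enumerate(offsets)
    ]
    config = incremental_config(
        base + timedelta(minutes=lo), base + timedelta(minutes=hi)
    )
    once = filter_window(envelopes, config)
    assert filter_window(once, config) == once


# -- collapse_versions -----------------------------------------------------


def test_collapse_update_update_delete_any_order():
    versions = [
        make_envelope("Condition", "c1", last_updated=ts(2, 8)),
        make_envelope("Condition", "c1", last_updated=ts(2, 9)),
        make_envelope("Condition", "c1", last_updated=ts(2, 10), deleted=True),
    ]
    for ordering in itertools.permutations(versions):
        (survivor,) = collapse_versions(list(ordering))
        assert survivor.deleted is True
        assert survivor.last_updated == ts(2, 10)


def test_collapse_distinct_ids_is_identity():
    envelopes = [make_envelope("Condition", f"c{i}") for i in range(5)]
    assert collapse_versions(envelopes) == envelopes


def test_collapse_tie_breaks_by_source_order_last_wins():
    first = make_envelope("Condition", "c1", last_updated=ts(2, 8))
    second = make_envelope(
        "Condition", "c1", last_updated=ts(2, 8), identifier="sys|X"
    )
    (survivor,) = collapse_versions([first, second])
    assert survivor is second


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=5),
            st.integers(min_value=0, max_value=500),
        ),
        max_size=40,
    )
)
def test_collapse_cardinality_is_distinct_pair_count(pairs):
    base = datetime(2023, 1, 1, tzinfo=timezone.utc)
    envelopes = [
        make_envelope(
            "Condition", f"c{ident}", last_updated=base + timedelta(minutes=m)
        )
        for ident, m in pairs
    ]
    expected = len({(e.resource_type, e.logical_id) for e in envelopes})
    assert len(collapse_versions(envelopes)) == expected


# -- LoadConfig ------------------------------------------------------------


def test_load_config_requires_window_for_incremental():
    with pytest.raises(ValueError):
        LoadConfig(bulkload_enabled=False)
    with pytest.raises(ValueError):
        LoadConfig(bulkload_enabled=False, data_begindate=ts(3), data_enddate=ts(2))


def test_load_config_bulk_ignores_window():
    LoadConfig(bulkload_enabled=True)  # no error


def test_load_config_from_properties(tmp_path):
    path = tmp_path / "etl.properties"
    path.write_text(
        "# comment\n"
        "APP_BULKLOAD_ENABLED=false\n"
        "DATA_BEGINDATE=2023-04-01T00:00:00Z\n"
        "DATA_ENDDATE=2023-04-01T23:59:59Z\n"
        "TRACKING_STRATEGY=mapping_tables\n"
        "SOURCE_KIND=gateway_table\n"
        "SOURCE_PATH=/tmp/in.csv\n"
        "TARGET_PATH=/tmp/omop.db\n"
    )
    config = LoadConfig.from_properties(path)
    assert config.bulkload_enabled is False
    assert config.data_begindate == datetime(2023, 4, 1, tzinfo=timezone.utc)
    assert config.tracking_strategy == "mapping_tables"
    assert config.source_kind == "gateway_table"


def test_parse_timestamp_normalizes_to_utc():
    assert parse_timestamp("2023-01-02T09:00:00+01:00") == ts(2, 8)
    assert parse_timestamp("2023-01-02T08:00:00") == ts(2, 8)


def test_envelope_requires_logical_id():
    with pytest.raises(ValueError):
        FhirEnvelope(
            logical_id="",
            resource_type="Patient",
            identifier="",
            payload={},
            last_updated=ts(2),
        )
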