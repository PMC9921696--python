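"""Relational ledger of computation results with provenance.

Every calculator run is persisted with its complete parameter set, the
trajectory-store version it saw, scalar results (value, uncertainty,
units) and any series data (ACF curves, RDF curves, running integrals).
A record is *fresh* only if the calculator name and every parameter
match exactly and the store version is unchanged — any ingest makes all
prior records stale, so cached results are never served across data
changes.

Parameter matching is exact on a canonicalised serialisation: keys
sorted recursively, floats rendered via ``float.hex`` so the comparison
is bitwise.  Non-numerical presentation options (anything under the
reserved key ``plot_options``) are excluded from the match key.

Backend: a single sqlite file per project (stdlib ``sqlite3``).
"""

from __future__ import annotations

import json
import sqlite3
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

_SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS computations (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    experiment TEXT NOT NULL DEFAULT '',
    calculator TEXT NOT NULL,
    params_key TEXT NOT NULL,
    params_json TEXT NOT NULL,
    store_version INTEGER NOT NULL,
    timestamp REAL NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_comp ON computations (calculator, params_key, store_version);
CREATE TABLE IF NOT EXISTS scalar_results (
    comp_id INTEGER REFERENCES computations (id),
    name TEXT NOT NULL,
    value REAL,
    uncertainty REAL,
    units TEXT
);
CREATE TABLE IF NOT EXISTS series_results (
    comp_id INTEGER REFERENCES computations (id),
    name TEXT NOT NULL,
    shape TEXT NOT NULL,
    data TEXT NOT NULL
);
"""

_EXCLUDED_KEYS = {"plot_options"}


def canonicalize_params(params: Mapping[str, Any]) -> str:
    """Deterministic, bitwise-exact serialisation of a parameter map."""

    def conv(v):
        if isinstance(v, Mapping):
            return {str(k): conv(v[k]) for k in sorted(v)}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (bool, int, str)) or v is None:
            return v
        if isinstance(v, (float, np.floating)):
            return float(v).hex()
        if isinstance(v, np.integer):
            return int(v)
        return repr(v)

    filtered = {k: v for k, v in params.items() if k not in _EXCLUDED_KEYS}
    return json.dumps(conv(filtered), sort_keys=True, separators=(",", ":"))


@dataclass
class ComputationRecord:
    """One calculator run: parameters, provenance and all outputs."""

    calculator_name: str
    parameters: dict[str, Any]
    store_version_at_run: int
    scalar_results: list[tuple[str, float, float, str]] = field(default_factory=list)
    series_results: dict[str, np.ndarray] = field(default_factory=dict)
    experiment: str = ""
    timestamp: float = 0.0
    record_id: int | None = None

    def scalar(self, name: str) -> tuple[float, float]:
        """(value, uncertainty) of a named scalar result."""
        for n, v, u, _units in self.scalar_results:
            if n == name:
                return v, u
        raise KeyError(name)


class ResultsLedger:
    """Queryable store of :class:`ComputationRecord` objects."""

    def __init__(self, path: str | Path | None = None):
        self._db = sqlite3.connect(str(path) if path is not None else ":memory:")
        self._db.executescript(_SCHEMA)
        self._db.execute(
            "INSERT OR IGNORE INTO meta VALUES ('schema_version', ?)",
            (str(_SCHEMA_VERSION),),
        )
        self._db.commit()

    def close(self) -> None:
        self._db.close()

    # -- writes ------------------------------------------------------------

    def put_record(self, record: ComputationRecord) -> int:
        for _n, _v, unc, _u in record.scalar_results:
            if unc is not None and unc < 0:
                raise ValueError("uncertainty must be non-negative")
        cur = self._db.execute(
            "INSERT INTO computations (experiment, calculator, params_key, params_json,"
            " store_version, timestamp) VALUES (?,?,?,?,?,?)",
            (
                record.experiment,
                record.calculator_name,
                canonicalize_params(record.parameters),
                json.dumps(record.parameters, default=str, sort_keys=True),
                record.store_version_at_run,
                record.timestamp or time.time(),
            ),
        )
        rid = cur.lastrowid
        for name, value, unc, units in record.scalar_results:
            self._db.execute(
                "INSERT INTO scalar_results VALUES (?,?,?,?,?)",
                (rid, name, float(value), None if unc is None else float(unc), units),
            )
        for name, arr in record.series_results.items():
            a = np.asarray(arr, dtype=float)
            self._db.execute(
                "INSERT INTO series_results VALUES (?,?,?,?)",
                (rid, name, json.dumps(a.shape), json.dumps(a.ravel().tolist())),
            )
        self._db.commit()
        record.record_id = rid
        return rid

    # -- reads -------------------------------------------------------------

    def _load(self, row) -> ComputationRecord:
        rid, experiment, calculator, params_json, version, ts = row
        rec = ComputationRecord(
            calculator_name=calculator,
            parameters=json.loads(params_json),
            store_version_at_run=version,
            experiment=experiment,
            timestamp=ts,
            record_id=rid,
        )
        for name, value, unc, units in self._db.execute(
            "SELECT name, value, uncertainty, units FROM scalar_results WHERE comp_id=?",
            (rid,),
        ):
            rec.scalar_results.append((name, value, unc, units))
        for name, shape, data in self._db.execute(
            "SELECT name, shape, data FROM series_results WHERE comp_id=?", (rid,)
        ):
            rec.series_results[name] = np.asarray(json.loads(data)).reshape(json.loads(shape))
        return rec

    _SELECT = ("SELECT id, experiment, calculator, params_json, store_version,"
               " timestamp FROM computations")

    def find_fresh(
        self,
        calculator_name: str,
        parameters: Mapping[str, Any],
        current_store_version: int,
        experiment: str = "",
    ) -> ComputationRecord | None:
        """Latest record matching exactly and computed at the current version."""
        rows = self._db.execute(
            self._SELECT + " WHERE calculator=? AND params_key=? AND store_version=?"
            " AND experiment=? ORDER BY id DESC LIMIT 1",
            (calculator_name, canonicalize_params(parameters),
             current_store_version, experiment),
        ).fetchall()
        return self._load(rows[0]) if rows else None

    def query(
        self,
        calculator_name: str | None = None,
        experiment: str | None = None,
        **param_filters: Any,
    ) -> list[ComputationRecord]:
        """All records, optionally filtered by calculator/experiment/parameters."""
        clauses, args = [], []
        if calculator_name is not None:
            clauses.append("calculator=?")
            args.append(calculator_name)
        if experiment is not None:
            clauses.append("experiment=?")
            args.append(experiment)
        sql = self._SELECT + ((" WHERE " + " AND ".join(clauses)) if clauses else "")
        records = [self._load(r) for r in self._db.execute(sql, args)]
        if param_filters:
            records = [
                r for r in records
                if all(r.parameters.get(k) == v for k, v in param_filters.items())
            ]
        return records

    def export_csv(self, calculator_name: str, path: str | Path) -> None:
        """Flat CSV of all scalar results of one calculator."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "experiment", "store_version", "parameters",
                        "result", "value", "uncertainty", "units"])
            for rec in self.query(calculator_name):
                for name, value, unc, units in rec.scalar_results:
                    w.writerow([rec.record_id, rec.experiment, rec.store_version_at_run,
                                json.dumps(rec.parameters, sort_keys=True, default=str),
                                name, value, unc, units])
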