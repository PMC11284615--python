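"""SQLite storage of SEND studies: one table per domain, loaded verbatim.

The database layer performs no transformation of XPT content: character
variables land as TEXT, numerics as REAL, dates stay ISO 8601 text exactly as
submitted. Interpretation (age arithmetic, phase assignment, codelist
mapping) is deferred entirely to the query layer, so the database remains a
faithful pooled copy of the source transport files.

Imports are study-granular and transactional: a study either lands complete
or not at all, and batch imports continue past failed folders. A registry
table tracks which STUDYIDs are present; every import/delete is appended to a
plain-text log beside the database file.
"""

from __future__ import annotations

import datetime as _dt
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    AlreadyInitializedError,
    ClosedHandleError,
    DuplicateStudyError,
    SendhcError,
)
from .manifest import MANIFEST_VERSION, load_manifest, storage_table
from .xpt import read_study_folder

logger = logging.getLogger(__name__)

_META_TABLE = "sendhc_meta"
_REGISTRY_TABLE = "sendhc_studies"


@dataclass
class DbHandle:
    """Open connection to a sendhc SQLite database."""

    db_path: str
    created_new: bool
    _conn: sqlite3.Connection | None = None

    @property
    def connection(self) -> sqlite3.Connection:
        if self._conn is None:
            raise ClosedHandleError(f"database handle for {self.db_path} is closed")
        return self._conn

    @property
    def closed(self) -> bool:
        return self._conn is None


@dataclass
class ImportReport:
    """Outcome of a batch import: one entry per attempted study folder."""

    entries: list[dict] = field(default_factory=list)

    def add(self, studyid, folder, status, message="", row_counts=None):
        self.entries.append(
            {
                "studyid": studyid,
                "folder": str(folder),
                "status": status,  # ok | skipped | failed
                "message": message,
                "row_counts": dict(row_counts or {}),
            }
        )

    def count(self, status: str) -> int:
        return sum(1 for e in self.entries if e["status"] == status)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (e["studyid"], e["folder"], e["status"], e["message"],
                 sum(e["row_counts"].values()))
                for e in self.entries
            ],
            columns=["STUDYID", "FOLDER", "STATUS", "MESSAGE", "ROWS"],
        )


def _log_path(db: DbHandle) -> Path:
    return Path(str(db.db_path) + ".log")


def _log(db: DbHandle, message: str) -> None:
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    with open(_log_path(db), "a", encoding="utf-8") as fh:
        fh.write(f"{stamp}\t{message}\n")


def init_environment(db_path, create: bool = True) -> DbHandle:
    """Connect to an existing database, or create a new empty one."""
    db_path = Path(db_path)
    exists = db_path.exists()
    if not exists and not create:
        raise SendhcError(f"database {db_path} does not exist (create=False)")
    try:
        conn = sqlite3.connect(db_path, isolation_level=None)
    except sqlite3.Error as exc:  # pragma: no cover - unreadable paths
        raise SendhcError(f"cannot open database {db_path}: {exc}") from exc
    conn.execute("PRAGMA foreign_keys=ON")
    return DbHandle(db_path=str(db_path), created_new=not exists, _conn=conn)


def disconnect(db: DbHandle) -> None:
    """Close the handle; double disconnect is a no-op."""
    if db._conn is not None:
        db._conn.close()
        db._conn = None


def _user_tables(conn) -> list[str]:
    rows = conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
    ).fetchall()
    return [r[0] for r in rows]


def _table_columns(conn, table: str) -> list[str]:
    return [r[1] for r in conn.execute(f'PRAGMA table_info("{table}")')]


def create_schema(db: DbHandle) -> int:
    """Create one table per manifest domain plus metadata/registry tables."""
    conn = db.connection
    manifest = load_manifest()
    existing = set(_user_tables(conn))
    if existing & set(manifest):
        raise AlreadyInitializedError(
            f"{db.db_path} already carries a SEND schema; no partial rebuild"
        )
    created = 0
    conn.execute("BEGIN")
    try:
        for domain, variables in manifest.items():
            cols = ", ".join(
                f'"{name}" {"REAL" if kind == "numeric" else "TEXT"}'
                for name, kind, _ in variables
            )
            conn.execute(f'CREATE TABLE "{domain}" ({cols})')
            created += 1
        conn.execute(f'CREATE TABLE "{_META_TABLE}" (key TEXT PRIMARY KEY, value TEXT)')
        conn.execute(
            f'INSERT INTO "{_META_TABLE}" VALUES (?, ?)',
            ("manifest_version", MANIFEST_VERSION),
        )
        conn.execute(
            f'CREATE TABLE "{_REGISTRY_TABLE}" '
            "(studyid TEXT PRIMARY KEY, folder TEXT, imported_at TEXT)"
        )
        conn.execute("COMMIT")
    except Exception:
        conn.execute("ROLLBACK")
        raise
    return created


def manifest_version(db: DbHandle) -> str:
    row = db.connection.execute(
        f'SELECT value FROM "{_META_TABLE}" WHERE key=?', ("manifest_version",)
    ).fetchone()
    return row[0] if row else ""


def list_studies(db: DbHandle) -> list[str]:
    return [
        r[0]
        for r in db.connection.execute(
            f'SELECT studyid FROM "{_REGISTRY_TABLE}" ORDER BY studyid'
        )
    ]


def _ensure_table(conn, table: str, variables) -> None:
    existing = set(_user_tables(conn))
    if table not in existing:
        cols = ", ".join(
            f'"{v.name}" {"REAL" if v.kind == "numeric" else "TEXT"}'
            for v in variables
        )
        conn.execute(f'CREATE TABLE "{table}" ({cols})')
        return
    have = set(_table_columns(conn, table))
    for v in variables:
        if v.name not in have:
            affinity = "REAL" if v.kind == "numeric" else "TEXT"
            conn.execute(f'ALTER TABLE "{table}" ADD COLUMN "{v.name}" {affinity}')


def _delete_study_rows(conn, studyid: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for table in _user_tables(conn):
        if table in (_META_TABLE, _REGISTRY_TABLE):
            continue
        if "STUDYID" not in _table_columns(conn, table):
            continue
        cur = conn.execute(f'DELETE FROM "{table}" WHERE STUDYID=?', (studyid,))
        if cur.rowcount:
            counts[table] = cur.rowcount
    conn.execute(f'DELETE FROM "{_REGISTRY_TABLE}" WHERE studyid=?', (studyid,))
    return counts


def import_one_study(db: DbHandle, folder, replace: bool = False) -> str:
    """Import one study folder verbatim; transactional per study."""
    conn = db.connection
    bundle = read_study_folder(folder)  # raises before any DB mutation
    studyid = bundle.studyid
    known = studyid in list_studies(db)
    if known and not replace:
        raise DuplicateStudyError(
            f"study {studyid!r} already in database (use replace=True)"
        )
    conn.execute("BEGIN")
    try:
        if known:
            _delete_study_rows(conn, studyid)
        row_counts: dict[str, int] = {}
        for code, table in bundle.domains.items():
            dest = storage_table(code)
            _ensure_table(conn, dest, table.variables)
            cols = _table_columns(conn, dest)
            placeholders = ", ".join("?" for _ in cols)
            collist = ", ".join(f'"{c}"' for c in cols)
            rows = [
                tuple(rec.get(c) for c in cols) for rec in table.records
            ]
            conn.executemany(
                f'INSERT INTO "{dest}" ({collist}) VALUES ({placeholders})', rows
            )
            row_counts[dest] = row_counts.get(dest, 0) + len(rows)
        conn.execute(
            f'INSERT INTO "{_REGISTRY_TABLE}" VALUES (?, ?, ?)',
            (studyid, str(folder), _dt.datetime.now().isoformat(timespec="seconds")),
        )
        conn.execute("COMMIT")
    except Exception:
        conn.execute("ROLLBACK")
        raise
    _log(db, f"import\t{studyid}\t{folder}\t{sum(row_counts.values())} rows")
    return studyid


def import_studies(db: DbHandle, root, replace: bool = False) -> ImportReport:
    """Import every subdirectory of ``root`` (recursive) holding XPT files.

    Failures do not abort the batch; each attempted folder gets one report
    entry with status ok/skipped/failed.
    """
    root = Path(root)
    if not root.is_dir():
        raise SendhcError(f"study root {root} does not exist")
    report = ImportReport()
    candidates = sorted(
        {p.parent for p in root.rglob("*") if p.suffix.lower() == ".xpt"}
    )
    for folder in candidates:
        try:
            studyid = import_one_study(db, folder, replace=replace)
            counts = {
                t: db.connection.execute(
                    f'SELECT COUNT(*) FROM "{t}" WHERE STUDYID=?', (studyid,)
                ).fetchone()[0]
                for t in _user_tables(db.connection)
                if t not in (_META_TABLE, _REGISTRY_TABLE)
                and "STUDYID" in _table_columns(db.connection, t)
            }
            report.add(studyid, folder, "ok",
                       row_counts={t: c for t, c in counts.items() if c})
        except DuplicateStudyError as exc:
            report.add("", folder, "skipped", str(exc))
        except SendhcError as exc:
            report.add("", folder, "failed", str(exc))
            logger.warning("import of %s failed: %s", folder, exc)
    _log(
        db,
        f"import_batch\t{root}\tok={report.count('ok')} "
        f"skipped={report.count('skipped')} failed={report.count('failed')}",
    )
    return report


def create_indexes(db: DbHandle) -> int:
    """Index STUDYID everywhere and (STUDYID, USUBJID) on subject domains.

    Returns the number of indexes newly created; re-running is a no-op.
    """
    conn = db.connection
    existing = {
        r[0]
        for r in conn.execute("SELECT name FROM sqlite_master WHERE type='index'")
    }
    created = 0
    for table in _user_tables(conn):
        if table in (_META_TABLE, _REGISTRY_TABLE):
            continue
        cols = _table_columns(conn, table)
        if "STUDYID" not in cols:
            continue
        name = f"ix_{table}_studyid"
        if name not in existing:
            conn.execute(f'CREATE INDEX "{name}" ON "{table}" (STUDYID)')
            created += 1
        if "USUBJID" in cols:
            name = f"ix_{table}_subj"
            if name not in existing:
                conn.execute(
                    f'CREATE INDEX "{name}" ON "{table}" (STUDYID, USUBJID)'
                )
                created += 1
    return created


def delete_studies(db: DbHandle, studyids) -> dict[str, int]:
    """Remove all rows of the listed studies; unknown ids delete 0 rows."""
    conn = db.connection
    out: dict[str, int] = {}
    for studyid in studyids:
        conn.execute("BEGIN")
        try:
            counts = _delete_study_rows(conn, studyid)
            conn.execute("COMMIT")
        except Exception:
            conn.execute("ROLLBACK")
            raise
        out[studyid] = sum(counts.values())
        _log(db, f"delete\t{studyid}\t{out[studyid]} rows")
    return out
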