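"""Embedded metadata catalog.

Repos, commits, pipeline spec versions and jobs are tracked in a single
SQLite database inside the workspace, so all metadata survives process
restarts.  Blob contents never live here — only path→address mappings and
provenance records; the bytes stay in the object store.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .errors import AlreadyExistsError, NotFoundError
from .filetree import FileTree
from .objectstore import ObjectRef

_SCHEMA = """
CREATE TABLE IF NOT EXISTS repos (
    name TEXT PRIMARY KEY,
    head TEXT
);
CREATE TABLE IF NOT EXISTS commits (
    id TEXT PRIMARY KEY,
    repo TEXT NOT NULL REFERENCES repos(name),
    ordinal INTEGER NOT NULL,
    parent TEXT,
    tree TEXT NOT NULL,
    provenance TEXT NOT NULL,
    origin TEXT NOT NULL CHECK (origin IN ('user', 'job')),
    finished INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE IF NOT EXISTS pipeline_specs (
    name TEXT NOT NULL,
    spec_version TEXT NOT NULL,
    spec_json TEXT NOT NULL,
    created INTEGER NOT NULL,
    PRIMARY KEY (name, spec_version)
);
CREATE TABLE IF NOT EXISTS pipelines (
    name TEXT PRIMARY KEY,
    current_version TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS jobs (
    id TEXT PRIMARY KEY,
    ordinal INTEGER NOT NULL,
    pipeline TEXT NOT NULL,
    spec_version TEXT NOT NULL,
    input_commits TEXT NOT NULL,
    side_commits TEXT NOT NULL,
    state TEXT NOT NULL CHECK (state IN ('running', 'success', 'failure')),
    output_commit TEXT,
    datums TEXT NOT NULL
);
"""


@dataclass(frozen=True)
class CommitRecord:
    """An immutable snapshot of one repository state."""

    id: str
    repo: str
    ordinal: int
    parent: str | None
    tree: FileTree
    provenance_inputs: tuple[tuple[str, str], ...]  # (repo, commit id)
    spec_version: str | None
    origin: str  # 'user' | 'job'
    finished: bool = True

    def tree_hash(self) -> str:
        return self.tree.tree_hash()


@dataclass(frozen=True)
class DatumRecord:
    root: str
    datum_id: str
    status: str  # 'skipped' | 'success' | 'failure'
    duration: float
    outputs: dict[str, str] = field(default_factory=dict)  # '/path' -> address
    error: str | None = None


@dataclass(frozen=True)
class JobRecord:
    id: str
    ordinal: int
    pipeline: str
    spec_version: str
    input_commits: tuple[str, ...]
    side_commits: tuple[tuple[str, str], ...]  # (repo, commit id) of whole-mounted inputs
    state: str  # 'running' | 'success' | 'failure'
    output_commit: str | None
    datums: tuple[DatumRecord, ...]

    @property
    def processed(self) -> int:
        return sum(1 for d in self.datums if d.status == "success")

    @property
    def skipped(self) -> int:
        return sum(1 for d in self.datums if d.status == "skipped")

    @property
    def failed(self) -> int:
        return sum(1 for d in self.datums if d.status == "failure")


def _tree_to_json(tree: FileTree) -> str:
    return json.dumps(
        {p: [r.address, r.size] for p, r in sorted(tree.entries.items())},
        separators=(",", ":"),
    )


def _tree_from_json(text: str) -> FileTree:
    raw = json.loads(text)
    return FileTree({p: ObjectRef(address=a, size=s) for p, (a, s) in raw.items()})


class Catalog:
    """SQLite-backed store for all engine metadata."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- repos ---------------------------------------------------------------

    def create_repo(self, name: str) -> None:
        try:
            with self._conn:
                self._conn.execute("INSERT INTO repos (name, head) VALUES (?, NULL)", (name,))
        except sqlite3.IntegrityError:
            raise AlreadyExistsError(f"repo {name!r} already exists") from None

    def repo_exists(self, name: str) -> bool:
        row = self._conn.execute("SELECT 1 FROM repos WHERE name = ?", (name,)).fetchone()
        return row is not None

    def list_repos(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT name FROM repos ORDER BY name")]

    def head(self, repo: str) -> str | None:
        row = self._conn.execute("SELECT head FROM repos WHERE name = ?", (repo,)).fetchone()
        if row is None:
            raise NotFoundError(f"repo {repo!r} does not exist")
        return row[0]

    # -- commits -------------------------------------------------------------

    def next_commit_ordinal(self, repo: str) -> int:
        row = self._conn.execute(
            "SELECT COALESCE(MAX(ordinal), 0) FROM commits WHERE repo = ?", (repo,)
        ).fetchone()
        return row[0] + 1

    def insert_commit(self, commit: CommitRecord) -> None:
        provenance = {
            "inputs": [list(pair) for pair in commit.provenance_inputs],
            "spec_version": commit.spec_version,
        }
        with self._conn:
            self._conn.execute(
                "INSERT INTO commits (id, repo, ordinal, parent, tree, provenance, origin, finished)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    commit.id,
                    commit.repo,
                    commit.ordinal,
                    commit.parent,
                    _tree_to_json(commit.tree),
                    json.dumps(provenance, separators=(",", ":")),
                    commit.origin,
                    int(commit.finished),
                ),
            )
            self._conn.execute(
                "UPDATE repos SET head = ? WHERE name = ?", (commit.id, commit.repo)
            )

    def get_commit(self, commit_id: str) -> CommitRecord:
        row = self._conn.execute(
            "SELECT id, repo, ordinal, parent, tree, provenance, origin, finished"
            " FROM commits WHERE id = ?",
            (commit_id,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"commit {commit_id!r} does not exist")
        provenance = json.loads(row[5])
        return CommitRecord(
            id=row[0],
            repo=row[1],
            ordinal=row[2],
            parent=row[3],
            tree=_tree_from_json(row[4]),
            provenance_inputs=tuple((r, c) for r, c in provenance["inputs"]),
            spec_version=provenance["spec_version"],
            origin=row[6],
            finished=bool(row[7]),
        )

    def list_commits(self, repo: str) -> list[CommitRecord]:
        if not self.repo_exists(repo):
            raise NotFoundError(f"repo {repo!r} does not exist")
        ids = self._conn.execute(
            "SELECT id FROM commits WHERE repo = ? ORDER BY ordinal", (repo,)
        ).fetchall()
        return [self.get_commit(i) for (i,) in ids]

    # -- pipelines -----------------------------------------------------------

    def upsert_pipeline(self, name: str, spec_version: str, spec_json: str) -> None:
        with self._conn:
            count = self._conn.execute(
                "SELECT COUNT(*) FROM pipeline_specs WHERE name = ?", (name,)
            ).fetchone()[0]
            self._conn.execute(
                "INSERT OR IGNORE INTO pipeline_specs (name, spec_version, spec_json, created)"
                " VALUES (?, ?, ?, ?)",
                (name, spec_version, spec_json, count + 1),
            )
            self._conn.execute(
                "INSERT INTO pipelines (name, current_version) VALUES (?, ?)"
                " ON CONFLICT(name) DO UPDATE SET current_version = excluded.current_version",
                (name, spec_version),
            )

    def pipeline_exists(self, name: str) -> bool:
        row = self._conn.execute("SELECT 1 FROM pipelines WHERE name = ?", (name,)).fetchone()
        return row is not None

    def list_pipelines(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT name FROM pipelines ORDER BY name")]

    def current_spec_version(self, name: str) -> str:
        row = self._conn.execute(
            "SELECT current_version FROM pipelines WHERE name = ?", (name,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"pipeline {name!r} does not exist")
        return row[0]

    def get_spec_json(self, name: str, spec_version: str) -> str:
        row = self._conn.execute(
            "SELECT spec_json FROM pipeline_specs WHERE name = ? AND spec_version = ?",
            (name, spec_version),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"pipeline {name!r} has no spec version {spec_version!r}")
        return row[0]

    # -- jobs ----------------------------------------------------------------

    def next_job_ordinal(self) -> int:
        row = self._conn.execute("SELECT COALESCE(MAX(ordinal), 0) FROM jobs").fetchone()
        return row[0] + 1

    def insert_job(self, job: JobRecord) -> None:
        datums = [
            {
                "root": d.root,
                "datum_id": d.datum_id,
                "status": d.status,
                "duration": d.duration,
                "outputs": d.outputs,
                "error": d.error,
            }
            for d in job.datums
        ]
        with self._conn:
            self._conn.execute(
                "INSERT INTO jobs (id, ordinal, pipeline, spec_version, input_commits,"
                " side_commits, state, output_commit, datums)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    job.id,
                    job.ordinal,
                    job.pipeline,
                    job.spec_version,
                    json.dumps(list(job.input_commits)),
                    json.dumps([list(p) for p in job.side_commits]),
                    job.state,
                    job.output_commit,
                    json.dumps(datums, separators=(",", ":")),
                ),
            )

    def _job_from_row(self, row: Any) -> JobRecord:
        datums = tuple(
            DatumRecord(
                root=d["root"],
                datum_id=d["datum_id"],
                status=d["status"],
                duration=d["duration"],
                outputs=d["outputs"],
                error=d.get("error"),
            )
            for d in json.loads(row[8])
        )
        return JobRecord(
            id=row[0],
            ordinal=row[1],
            pipeline=row[2],
            spec_version=row[3],
            input_commits=tuple(json.loads(row[4])),
            side_commits=tuple((r, c) for r, c in json.loads(row[5])),
            state=row[6],
            output_commit=row[7],
            datums=datums,
        )

    _JOB_COLS = (
        "id, ordinal, pipeline, spec_version, input_commits, side_commits,"
        " state, output_commit, datums"
    )

    def get_job(self, job_id: str) -> JobRecord:
        row = self._conn.execute(
            f"SELECT {self._JOB_COLS} FROM jobs WHERE id = ?", (job_id,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"job {job_id!r} does not exist")
        return self._job_from_row(row)

    def list_jobs(self, pipeline: str | None = None) -> list[JobRecord]:
        if pipeline is None:
            rows = self._conn.execute(
                f"SELECT {self._JOB_COLS} FROM jobs ORDER BY ordinal"
            ).fetchall()
        else:
            rows = self._conn.execute(
                f"SELECT {self._JOB_COLS} FROM jobs WHERE pipeline = ? ORDER BY ordinal",
                (pipeline,),
            ).fetchall()
        return [self._job_from_row(r) for r in rows]

    def latest_successful_job(self, pipeline: str, spec_version: str) -> JobRecord | None:
        row = self._conn.execute(
            f"SELECT {self._JOB_COLS} FROM jobs"
            " WHERE pipeline = ? AND spec_version = ? AND state = 'success'"
            " ORDER BY ordinal DESC LIMIT 1",
            (pipeline, spec_version),
        ).fetchone()
        return self._job_from_row(row) if row is not None else None
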