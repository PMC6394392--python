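"""The workspace: versioned data repositories plus the pipeline system.

A workspace directory holds the content-addressed object store
(``objects/``), the metadata catalog (``catalog.db``) and a scratch area
for execution sandboxes.  Opening the same directory again restores all
repos, commits, pipelines and jobs.

Data model
----------
A *repository* is a named, linear chain of immutable commits.  Each commit
snapshots a complete file tree; unchanged files share blob addresses with
the parent (copy-on-write), so committing k changed files on an n-file tree
stores at most k new blobs.  Commit ids are ``<repo>@<n>`` with n the
1-based ordinal — deterministic and human-readable; content equality is
always asserted via tree hashes, never via ids.

A *pipeline* declares how one repo's commits are transformed into another's:
the input tree is partitioned into datums by a glob pattern, each datum runs
the stage command in an isolated sandbox, and the merged outputs become a
new commit on the pipeline's output repo, carrying provenance (input commit
ids + spec version).  New input commits trigger jobs, which cascade
downstream in topological order; a failed job makes no output commit and
stops its branch of the cascade.

Incrementality: a datum whose content hash matches one processed by the
most recent successful job of the same pipeline at the same spec version —
with identical side-input trees — is skipped, and its previous outputs are
carried forward.  The engine guarantees the resulting head equals what a
from-scratch run on the same input commit would produce.
"""

from __future__ import annotations

import shutil
from pathlib import Path
from typing import Mapping

import networkx as nx

from .catalog import Catalog, CommitRecord, DatumRecord, JobRecord
from .errors import (
    AlreadyExistsError,
    DAGViolationError,
    NotFoundError,
    ValidationError,
)
from .executor import DatumResult, execute_datum, run_workers
from .filetree import DiffResult, FileTree, diff_trees
from .globdatums import Datum, partition
from .objectstore import LocalDirBackend, ObjectRef, ObjectStore, StoreStats
from .pipelinespec import PipelineSpec, validate_name


class Workspace:
    """One engine instance rooted at a directory; all state persists there."""

    def __init__(self, root: str | Path):
        # absolute: sandbox commands run with a different working directory
        self.root = Path(root).resolve()
        self.root.mkdir(parents=True, exist_ok=True)
        self.store = ObjectStore(LocalDirBackend(self.root / "objects"))
        self.catalog = Catalog(self.root / "catalog.db")
        self.scratch = self.root / "scratch"

    def close(self) -> None:
        self.catalog.close()
        shutil.rmtree(self.scratch, ignore_errors=True)

    # -- repositories --------------------------------------------------------

    def create_repo(self, name: str) -> str:
        validate_name(name, "repo name")
        self.catalog.create_repo(name)
        return name

    def list_repos(self) -> list[str]:
        return self.catalog.list_repos()

    def head_commit(self, repo: str) -> CommitRecord | None:
        head = self.catalog.head(repo)
        return self.catalog.get_commit(head) if head is not None else None

    def get_commit(self, commit_id: str) -> CommitRecord:
        return self.catalog.get_commit(commit_id)

    def list_commits(self, repo: str) -> list[CommitRecord]:
        return self.catalog.list_commits(repo)

    def _commit_tree(
        self,
        repo: str,
        tree: FileTree,
        origin: str,
        provenance_inputs: tuple[tuple[str, str], ...] = (),
        spec_version: str | None = None,
    ) -> CommitRecord:
        if origin == "user" and spec_version is not None:
            raise ValidationError("user commits carry no spec version")
        if origin == "job" and (spec_version is None or not provenance_inputs):
            raise ValidationError("job commits need >=1 input commit and a spec version")
        ordinal = self.catalog.next_commit_ordinal(repo)
        parent = self.catalog.head(repo)
        commit = CommitRecord(
            id=f"{repo}@{ordinal}",
            repo=repo,
            ordinal=ordinal,
            parent=parent,
            tree=tree,
            provenance_inputs=provenance_inputs,
            spec_version=spec_version,
            origin=origin,
        )
        self.catalog.insert_commit(commit)
        return commit

    def commit_files(
        self, repo: str, changes: Mapping[str, bytes | None]
    ) -> CommitRecord:
        """Make a user commit: apply additions/updates/deletions to the head tree.

        ``None`` values are deletion markers.  Unchanged paths share their
        parent's blob addresses; only new content is written to the store.
        """
        if not self.catalog.repo_exists(repo):
            raise NotFoundError(f"repo {repo!r} does not exist")
        head = self.head_commit(repo)
        base = head.tree if head is not None else FileTree()
        refs: dict[str, ObjectRef | None] = {}
        for path, content in changes.items():
            if content is None:
                refs[path] = None
            elif isinstance(content, bytes):
                refs[path] = self.store.put(content)
            else:
                raise ValidationError(
                    f"file content must be bytes or None (deletion), got {type(content).__name__}"
                )
        return self._commit_tree(repo, base.with_changes(refs), origin="user")

    def get_file(self, commit_id: str, path: str) -> bytes:
        commit = self.catalog.get_commit(commit_id)
        ref = commit.tree.get(path)
        if ref is None:
            raise NotFoundError(f"path {path!r} not found in {commit_id}")
        return self.store.get(ref)

    def diff_commits(self, old_id: str | None, new_id: str) -> DiffResult:
        new = self.catalog.get_commit(new_id)
        old = self.catalog.get_commit(old_id) if old_id is not None else None
        if old is not None and old.repo != new.repo:
            raise ValidationError(
                f"cannot diff commits of different repos: {old.repo!r} vs {new.repo!r}"
            )
        return diff_trees(old.tree if old is not None else None, new.tree)

    def store_stats(self) -> StoreStats:
        return self.store.stats()

    # -- pipelines -----------------------------------------------------------

    def _pipeline_graph(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        for name in self.catalog.list_pipelines():
            spec = self.get_pipeline_spec(name)
            for repo in spec.input_repos:
                graph.add_edge(repo, spec.name)
        return graph

    def get_pipeline_spec(self, name: str, spec_version: str | None = None) -> PipelineSpec:
        if spec_version is None:
            spec_version = self.catalog.current_spec_version(name)
        return PipelineSpec.from_json(self.catalog.get_spec_json(name, spec_version))

    def create_pipeline(self, spec: PipelineSpec) -> str:
        """Register a pipeline stage, creating its output repo.

        Re-registering an existing pipeline with a changed spec records a
        new spec version (which forces a full recompute on the next job);
        colliding with an unrelated repo name is an error, as is any edge
        that would make the repo/pipeline graph cyclic.
        """
        if spec.name in spec.input_repos:
            raise DAGViolationError(f"pipeline {spec.name!r} cannot consume its own output")
        for repo in spec.input_repos:
            if not self.catalog.repo_exists(repo):
                raise NotFoundError(f"input repo {repo!r} does not exist")
        is_update = self.catalog.pipeline_exists(spec.name)
        if not is_update and self.catalog.repo_exists(spec.name):
            raise AlreadyExistsError(
                f"cannot create pipeline {spec.name!r}: a repo with that name exists"
            )
        graph = self._pipeline_graph()
        for repo in spec.input_repos:
            graph.add_edge(repo, spec.name)
        if not nx.is_directed_acyclic_graph(graph):
            raise DAGViolationError(
                f"pipeline {spec.name!r} would create a cycle in the pipeline graph"
            )
        self.catalog.upsert_pipeline(spec.name, spec.spec_version, spec.to_json())
        if not is_update:
            self.catalog.create_repo(spec.name)
        return spec.spec_version

    def list_pipelines(self) -> list[str]:
        return self.catalog.list_pipelines()

    # -- job execution -------------------------------------------------------

    def _consumers(self, repo: str) -> list[str]:
        """Pipelines whose partitioned (triggering) input is ``repo``."""
        names = []
        for name in self.catalog.list_pipelines():
            if self.get_pipeline_spec(name).input_repo == repo:
                names.append(name)
        return sorted(names)

    def on_commit(self, commit_id: str) -> list[JobRecord]:
        """Trigger all pipelines consuming the commit's repo, cascading downstream.

        Jobs run in topological order: a downstream pipeline is only
        triggered once its upstream job has succeeded and committed output.
        A failed job stops its branch; other branches still run.
        """
        commit = self.catalog.get_commit(commit_id)
        jobs: list[JobRecord] = []
        queue: list[tuple[str, str]] = [(commit.repo, commit.id)]
        while queue:
            repo, cid = queue.pop(0)
            for pipeline in self._consumers(repo):
                job = self.run_job(pipeline, cid)
                jobs.append(job)
                if job.state == "success" and job.output_commit is not None:
                    queue.append((pipeline, job.output_commit))
        return jobs

    def _side_state(self, spec: PipelineSpec) -> tuple[tuple[tuple[str, str], ...], dict[str, FileTree]]:
        commits: list[tuple[str, str]] = []
        trees: dict[str, FileTree] = {}
        for side in spec.side_inputs:
            head = self.head_commit(side.repo)
            commits.append((side.repo, head.id if head is not None else ""))
            trees[side.name] = head.tree if head is not None else FileTree()
        return tuple(commits), trees

    def _side_tree_hashes(self, side_commits: tuple[tuple[str, str], ...]) -> tuple[str, ...]:
        hashes = []
        for _repo, cid in side_commits:
            hashes.append(self.catalog.get_commit(cid).tree_hash() if cid else "")
        return tuple(hashes)

    def _reusable_outputs(
        self, spec: PipelineSpec, side_commits: tuple[tuple[str, str], ...]
    ) -> dict[str, dict[str, str]]:
        """Map datum_id → output path→address from the last reusable job.

        Reuse requires the same pipeline, the same spec version and
        byte-identical side-input trees; otherwise previous results might
        not equal what a fresh execution would produce.
        """
        reference = self.catalog.latest_successful_job(spec.name, spec.spec_version)
        if reference is None:
            return {}
        if self._side_tree_hashes(reference.side_commits) != self._side_tree_hashes(side_commits):
            return {}
        return {
            d.datum_id: d.outputs
            for d in reference.datums
            if d.status in ("success", "skipped")
        }

    def run_job(self, pipeline: str, input_commit_id: str) -> JobRecord:
        """Execute one job: partition, skip unchanged datums, run the rest.

        On success the merged outputs (carried-forward plus fresh) become a
        new commit on the output repo with full provenance.  On any datum
        failure — or an output path collision between datums — the job is
        recorded as failed and the output repo head is left untouched.
        """
        spec = self.get_pipeline_spec(pipeline)
        input_commit = self.catalog.get_commit(input_commit_id)
        if input_commit.repo != spec.input_repo:
            raise ValidationError(
                f"commit {input_commit_id} belongs to {input_commit.repo!r},"
                f" not pipeline input {spec.input_repo!r}"
            )
        datums = partition(input_commit.tree, spec.glob)
        side_commits, side_trees = self._side_state(spec)
        reusable = self._reusable_outputs(spec, side_commits)

        to_run: list[Datum] = []
        records: dict[str, DatumRecord] = {}
        for datum in datums:
            prior = reusable.get(datum.datum_id)
            if prior is not None:
                records[datum.root] = DatumRecord(
                    root=datum.root,
                    datum_id=datum.datum_id,
                    status="skipped",
                    duration=0.0,
                    outputs=dict(prior),
                )
            else:
                to_run.append(datum)

        results: list[DatumResult] = run_workers(
            to_run,
            spec.parallelism,
            lambda d: execute_datum(spec, d, self.store, side_trees, self.scratch),
        )
        for result in results:
            outputs = {
                path: self.store.put(content).address
                for path, content in sorted(result.outputs.items())
            }
            records[result.datum.root] = DatumRecord(
                root=result.datum.root,
                datum_id=result.datum.datum_id,
                status="success" if result.ok else "failure",
                duration=result.duration,
                outputs=outputs if result.ok else {},
                error=result.error,
            )

        ordered = tuple(records[d.root] for d in datums)
        ordinal = self.catalog.next_job_ordinal()
        job_id = f"job-{ordinal}"
        failed = [d for d in ordered if d.status == "failure"]
        error_note = None
        if not failed:
            # merge outputs; a path produced by two datums is nondeterministic
            # under parallel completion and therefore a hard failure
            merged: dict[str, ObjectRef] = {}
            owners: dict[str, str] = {}
            collision = None
            for record in ordered:
                for path, address in record.outputs.items():
                    if path in merged:
                        collision = (path, owners[path], record.root)
                        break
                    merged[path] = ObjectRef(address=address, size=len(self.store.get(address)))
                    owners[path] = record.root
                if collision:
                    break
            if collision:
                path, first, second = collision
                error_note = (
                    f"output collision: datums {first!r} and {second!r} both wrote {path!r}"
                )
        if failed or error_note:
            job = JobRecord(
                id=job_id,
                ordinal=ordinal,
                pipeline=pipeline,
                spec_version=spec.spec_version,
                input_commits=(input_commit_id,),
                side_commits=side_commits,
                state="failure",
                output_commit=None,
                datums=ordered if not error_note else tuple(
                    DatumRecord(
                        root=d.root, datum_id=d.datum_id, status=d.status,
                        duration=d.duration, outputs=d.outputs,
                        error=d.error or error_note,
                    )
                    for d in ordered
                ),
            )
            self.catalog.insert_job(job)
            return job

        provenance = ((spec.input_repo, input_commit_id),) + tuple(
            (repo, cid) for repo, cid in side_commits if cid
        )
        output_commit = self._commit_tree(
            spec.name,
            FileTree(merged),
            origin="job",
            provenance_inputs=provenance,
            spec_version=spec.spec_version,
        )
        job = JobRecord(
            id=job_id,
            ordinal=self.catalog.next_job_ordinal(),
            pipeline=pipeline,
            spec_version=spec.spec_version,
            input_commits=(input_commit_id,),
            side_commits=side_commits,
            state="success",
            output_commit=output_commit.id,
            datums=ordered,
        )
        self.catalog.insert_job(job)
        return job

    def flush_commit(self, commit_id: str) -> list[JobRecord]:
        """Return all jobs downstream of a commit (execution is synchronous,
        so by the time this returns every cascade has settled)."""
        seen_commits = {commit_id}
        frontier = [commit_id]
        jobs: list[JobRecord] = []
        all_jobs = self.catalog.list_jobs()
        while frontier:
            cid = frontier.pop(0)
            for job in all_jobs:
                if cid in job.input_commits and job not in jobs:
                    jobs.append(job)
                    if job.output_commit and job.output_commit not in seen_commits:
                        seen_commits.add(job.output_commit)
                        frontier.append(job.output_commit)
        return jobs
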