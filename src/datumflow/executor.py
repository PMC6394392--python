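"""Sandboxed datum execution.

Each datum runs in a throwaway scratch directory that reproduces the
pipeline filesystem contract: the datum's files appear read-only under
``pfs/<mount name>/``, each side input's full tree under ``pfs/<its
mount>/``, and the command writes its results into an initially empty
``pfs/out/``.  The environment variable ``PFS_ROOT`` points at the sandbox's
``pfs`` directory so commands are location-independent.  Exit code 0 means
success and everything under ``pfs/out`` becomes the datum's output; any
nonzero exit (or an unlaunchable command) marks the datum failed, with
stderr captured for diagnostics.  The sandbox is deleted afterwards either
way.

Execution is by local subprocess, not containers: the contract preserved is
the mount layout and the exit-code semantics, not the packaging.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
import time
import uuid
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .errors import ValidationError
from .filetree import FileTree
from .globdatums import Datum, datum_sandbox_paths
from .objectstore import ObjectStore
from .pipelinespec import PipelineSpec


@dataclass
class DatumResult:
    datum: Datum
    ok: bool
    outputs: dict[str, bytes] = field(default_factory=dict)  # '/path' -> bytes
    duration: float = 0.0  # seconds of wall time in the subprocess
    error: str | None = None


def _materialize(root: Path, files: Mapping[str, bytes]) -> None:
    for rel, content in files.items():
        target = root / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(content)


def _collect_outputs(out_dir: Path) -> dict[str, bytes]:
    outputs: dict[str, bytes] = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file():
            rel = path.relative_to(out_dir).as_posix()
            outputs["/" + rel] = path.read_bytes()
    return outputs


def execute_datum(
    spec: PipelineSpec,
    datum: Datum,
    store: ObjectStore,
    side_trees: Mapping[str, FileTree] | None = None,
    scratch_root: str | os.PathLike[str] | None = None,
) -> DatumResult:
    """Run the stage command against one datum in a fresh sandbox."""
    side_trees = side_trees or {}
    base = Path(scratch_root) if scratch_root is not None else Path(tempfile.gettempdir())
    base = base.resolve()  # PFS_ROOT must stay valid from the sandbox cwd
    base.mkdir(parents=True, exist_ok=True)
    sandbox = base / f"datum-{uuid.uuid4().hex}"
    pfs = sandbox / "pfs"
    try:
        (pfs / "out").mkdir(parents=True)
        _materialize(
            pfs / spec.mount_name,
            {rel: store.get(ref) for rel, ref in datum_sandbox_paths(datum).items()},
        )
        for mount, tree in side_trees.items():
            (pfs / mount).mkdir(parents=True, exist_ok=True)
            _materialize(pfs / mount, {p[1:]: store.get(r) for p, r in tree.entries.items()})

        env = dict(os.environ)
        env.update(spec.transform_env)
        env["PFS_ROOT"] = str(pfs)
        started = time.perf_counter()
        try:
            proc = subprocess.run(
                list(spec.transform_cmd),
                cwd=sandbox,
                env=env,
                capture_output=True,
                text=True,
            )
        except OSError as exc:  # command not found / not executable
            return DatumResult(
                datum=datum,
                ok=False,
                duration=time.perf_counter() - started,
                error=f"cannot launch {spec.transform_cmd[0]!r}: {exc}",
            )
        duration = time.perf_counter() - started
        if proc.returncode != 0:
            return DatumResult(
                datum=datum,
                ok=False,
                duration=duration,
                error=(
                    f"command exited with status {proc.returncode}"
                    + (f"; stderr:\n{proc.stderr.strip()}" if proc.stderr.strip() else "")
                ),
            )
        return DatumResult(
            datum=datum, ok=True, outputs=_collect_outputs(pfs / "out"), duration=duration
        )
    finally:
        shutil.rmtree(sandbox, ignore_errors=True)


def run_workers(
    datums: Sequence[Datum],
    parallelism: int,
    execute: Callable[[Datum], DatumResult],
) -> list[DatumResult]:
    """Execute datums with at most ``parallelism`` in flight at once.

    Results are returned in submission order, so the merged output is
    independent of completion order; a completion-order trace is available
    on each result's duration/ordering.  ``parallelism=1`` degrades to a
    plain sequential loop.
    """
    if not isinstance(parallelism, int) or parallelism < 1:
        raise ValidationError(f"parallelism must be >= 1, got {parallelism!r}")
    if not datums:
        return []
    if parallelism == 1:
        return [execute(d) for d in datums]
    with ThreadPoolExecutor(max_workers=parallelism) as pool:
        futures = [pool.submit(execute, d) for d in datums]
        return [f.result() for f in futures]
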