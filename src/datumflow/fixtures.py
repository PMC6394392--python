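"""Synthetic workflow fixtures: a toy peak-picking pipeline, end to end.

The generator emulates the topology of a typical LC-MS preprocessing
workflow at toy scale — a per-sample scatter stage, a gather stage, and a
report stage — without any mass-spectrometry chemistry:

* inputs: one CSV per sample with pseudo-random (mz, rt, intensity) peaks;
* ``peaks``     (glob ``/*``): filters each sample's rows by an intensity
  threshold — one datum per sample, embarrassingly parallel;
* ``aggregate`` (glob ``/``): concatenates all filtered samples and counts
  peaks per sample — necessarily a single datum;
* ``report``    (glob ``/``): renders summary statistics from the counts.

Everything is a plain-text file and a small interpreter one-liner, so the
whole engine — partitioning, incremental skipping, cascading, provenance —
is exercisable with no external tools and is bit-reproducible from
(n_samples, peaks_per_sample, seed).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalog import JobRecord
from .errors import JobFailedError, ValidationError
from .pipelinespec import PipelineSpec, SideInput
from .provenance import explain
from .workspace import Workspace

INTENSITY_THRESHOLD = 500.0  # fixture stage-1 filter cutoff, on a 0..1000 scale

_STAGE1_SCRIPT = """\
import os, pathlib
pfs = pathlib.Path(os.environ["PFS_ROOT"])
threshold = float(os.environ.get("INTENSITY_MIN", "500"))
for sample in sorted((pfs / "in").rglob("*.csv")):
    lines = sample.read_text().splitlines()
    kept = [lines[0]]
    kept += [l for l in lines[1:] if l and float(l.split(",")[2]) >= threshold]
    out = pfs / "out" / (sample.stem + ".peaks.csv")
    out.write_text("\\n".join(kept) + "\\n")
"""

_STAGE2_SCRIPT = """\
import os, pathlib
pfs = pathlib.Path(os.environ["PFS_ROOT"])
rows, counts = [], []
for peaks in sorted((pfs / "in").rglob("*.peaks.csv")):
    body = [l for l in peaks.read_text().splitlines()[1:] if l]
    sample = peaks.name[: -len(".peaks.csv")]
    counts.append(f"{sample}\\t{len(body)}")
    rows += [f"{sample},{l}" for l in body]
(pfs / "out" / "peaks_all.csv").write_text(
    "\\n".join(["sample,mz,rt,intensity"] + rows) + "\\n")
(pfs / "out" / "counts.tsv").write_text("\\n".join(counts) + "\\n")
"""

_STAGE3_SCRIPT = """\
import os, pathlib
pfs = pathlib.Path(os.environ["PFS_ROOT"])
counts = [l.split("\\t") for l in
          (pfs / "in" / "counts.tsv").read_text().splitlines() if l]
total = sum(int(n) for _, n in counts)
mean = total / len(counts) if counts else 0.0
report = [
    f"samples: {len(counts)}",
    f"total_peaks: {total}",
    f"mean_peaks_per_sample: {mean:.2f}",
]
(pfs / "out" / "report.txt").write_text("\\n".join(report) + "\\n")
"""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study; generation is a pure function of these."""

    n_samples: int
    peaks_per_sample: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.peaks_per_sample < 1:
            raise ValidationError(f"peaks_per_sample must be >= 1, got {self.peaks_per_sample}")


def sample_csv(spec: FixtureSpec, index: int) -> bytes:
    """Deterministic CSV for one sample: columns mz, rt, intensity.

    mz spans a plausible small-molecule range (50-1000), rt a 15-minute
    gradient in seconds, intensity 0-1000 so roughly half the peaks clear
    the stage-1 threshold.  Each sample gets an independent substream, so
    adding a sample never perturbs existing ones.
    """
    rng = np.random.default_rng([spec.seed, index])
    lines = ["mz,rt,intensity"]
    for _ in range(spec.peaks_per_sample):
        mz = rng.uniform(50.0, 1000.0)
        rt = rng.uniform(0.0, 900.0)
        intensity = rng.uniform(0.0, 1000.0)
        lines.append(f"{mz:.4f},{rt:.2f},{intensity:.2f}")
    return ("\n".join(lines) + "\n").encode()


def pipeline_specs(input_repo: str = "samples") -> list[PipelineSpec]:
    """The three-stage scatter → gather → report plan over ``input_repo``."""
    python = sys.executable or "python"
    return [
        PipelineSpec(
            name="peaks",
            transform_cmd=(python, "-c", _STAGE1_SCRIPT),
            transform_env={"INTENSITY_MIN": str(INTENSITY_THRESHOLD)},
            input_repo=input_repo,
            glob="/*",
            input_name="in",
        ),
        PipelineSpec(
            name="aggregate",
            transform_cmd=(python, "-c", _STAGE2_SCRIPT),
            input_repo="peaks",
            glob="/",
            input_name="in",
        ),
        PipelineSpec(
            name="report",
            transform_cmd=(python, "-c", _STAGE3_SCRIPT),
            input_repo="aggregate",
            glob="/",
            input_name="in",
        ),
    ]


def generate_fixture(spec: FixtureSpec, workspace: str | Path) -> dict[str, list[Path]]:
    """Write the sample CSVs and the three pipeline spec JSONs to disk.

    Returns {"inputs": [...], "pipelines": [...]} with the created paths.
    Running it twice with the same FixtureSpec produces byte-identical files.
    """
    root = Path(workspace)
    inputs_dir = root / "inputs"
    specs_dir = root / "pipelines"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    specs_dir.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(spec.n_samples)))
    inputs = []
    for index in range(spec.n_samples):
        path = inputs_dir / f"sample_{index + 1:0{width}d}.csv"
        path.write_bytes(sample_csv(spec, index))
        inputs.append(path)
    spec_paths = []
    for pspec in pipeline_specs():
        path = specs_dir / f"{pspec.name}.json"
        path.write_text(pspec.to_json() + "\n")
        spec_paths.append(path)
    return {"inputs": inputs, "pipelines": spec_paths}


@dataclass
class DemoResult:
    report: str
    lineage_text: str
    jobs: list[JobRecord]
    final_commit: str
    final_tree_hash: str


def run_demo(workspace: str | Path, fixture: FixtureSpec | None = None) -> DemoResult:
    """Run the whole toy study: commit samples, build the 3-stage DAG, cascade.

    Creates (or reuses) an engine at ``workspace`` (fixture files go under
    ``<workspace>/fixture``), commits every generated sample CSV into the
    ``samples`` repo, registers the three pipelines and lets the commit
    cascade run.  Raises JobFailedError with diagnostics if any stage fails.
    """
    fixture = fixture or FixtureSpec(n_samples=3, peaks_per_sample=20, seed=0)
    root = Path(workspace)
    generated = generate_fixture(fixture, root / "fixture")
    ws = Workspace(root)
    try:
        return _run_demo(ws, generated)
    finally:
        ws.close()


def _run_demo(ws: Workspace, generated: dict[str, list[Path]]) -> DemoResult:
    if "samples" not in ws.list_repos():
        ws.create_repo("samples")
    changes = {f"/{p.name}": p.read_bytes() for p in generated["inputs"]}
    commit = ws.commit_files("samples", changes)

    for path in generated["pipelines"]:
        ws.create_pipeline(PipelineSpec.from_json(path.read_text()))

    jobs = ws.on_commit(commit.id)
    failed = [j for j in jobs if j.state != "success"]
    if failed:
        details = "; ".join(
            f"{j.pipeline}: " + "; ".join(d.error or d.status for d in j.datums if d.status == "failure")
            for j in failed
        )
        raise JobFailedError(f"demo pipeline failed — {details}")

    head = ws.head_commit("report")
    assert head is not None
    report = ws.get_file(head.id, "/report.txt").decode()
    return DemoResult(
        report=report,
        lineage_text=explain(ws, head.id),
        jobs=jobs,
        final_commit=head.id,
        final_tree_hash=head.tree_hash(),
    )
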