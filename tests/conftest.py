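import pytest

from datumflow import FileTree, ObjectRef, Workspace
from datumflow.objectstore import content_address


@pytest.fixture
def ws(tmp_path):
    workspace = Workspace(tmp_path / "ws")
    yield workspace
    workspace.close()


def make_tree(files: dict[str, bytes]) -> FileTree:
    """Build a FileTree directly from path→bytes, without an object store."""
    return FileTree(
        {path: ObjectRef(address=content_address(data), size=len(data)) for path, data in files.items()}
    )


# a tiny 3-stage scatter → gather → report DAG built from shell one-liners,
# used by the pipeline, provenance and acceptance tests
SCATTER_CMD = (
    "sh",
    "-c",
    'for f in "$PFS_ROOT"/in/*; do n=$(basename "$f");'
    ' tr a-z A-Z < "$f" > "$PFS_ROOT/out/$n.up"; done',
)
GATHER_CMD = (
    "sh",
    "-c",
    'cat "$PFS_ROOT"/in/* > "$PFS_ROOT/out/all.txt";'
    ' wc -c < "$PFS_ROOT/out/all.txt" > "$PFS_ROOT/out/size.txt"',
)
REPORT_CMD = (
    "sh",
    "-c",
    'cat "$PFS_ROOT"/in/size.txt "$PFS_ROOT"/in/all.txt > "$PFS_ROOT/out/report.txt"',
)


def build_three_stage_dag(workspace: Workspace, input_repo: str = "raw") -> None:
    from datumflow import PipelineSpec

    workspace.create_repo(input_repo)
    workspace.create_pipeline(
        PipelineSpec(name="upper", transform_cmd=SCATTER_CMD, input_repo=input_repo,
                     glob="/*", input_name="in")
    )
    workspace.create_pipeline(
        PipelineSpec(name="gather", transform_cmd=GATHER_CMD, input_repo="upper",
                     glob="/", input_name="in")
    )
    workspace.create_pipeline(
        PipelineSpec(name="summary", transform_cmd=REPORT_CMD, input_repo="gather",
                     glob="/", input_name="in")
    )
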