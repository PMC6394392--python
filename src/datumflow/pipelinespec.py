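"""Declarative pipeline specifications.

A pipeline stage is described by a JSON document:

    {"pipeline": {"name": "toolB"},
     "transform": {"cmd": ["sh", "-c", "..."], "env": {...}, "image": "optional"},
     "input": {"pfs": {"repo": "RepoA", "glob": "/*", "name": "in"}},
     "side_inputs": [{"repo": "params", "name": "params"}],
     "parallelism_spec": {"constant": 4}}

The stage's name doubles as its output repository name.  The primary input
is partitioned into datums by the glob pattern; side inputs are mounted
whole (every datum sees their full tree).  ``image`` is retained as inert
metadata so specs round-trip, but execution is by local subprocess.

Every semantically distinct spec has a distinct ``spec_version``: the
SHA-256 of its canonical JSON serialization.  The spec version participates
in provenance and in the reuse rule — outputs computed under one version
are never carried forward under another.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

from .errors import ValidationError
from .globdatums import parse_glob

NAME_RE = re.compile(r"^[A-Za-z0-9_-]+$")


def validate_name(name: str, kind: str = "name") -> str:
    if not isinstance(name, str) or not NAME_RE.match(name):
        raise ValidationError(f"invalid {kind} {name!r}: must match [A-Za-z0-9_-]+")
    return name


@dataclass(frozen=True)
class SideInput:
    repo: str
    name: str  # mount name under pfs/

    def __post_init__(self) -> None:
        validate_name(self.repo, "repo name")
        validate_name(self.name, "mount name")


@dataclass(frozen=True)
class PipelineSpec:
    """One declarative stage: name, command, partitioned input, parallelism."""

    name: str
    transform_cmd: tuple[str, ...]
    input_repo: str
    glob: str = "/"
    input_name: str | None = None  # mount name; defaults to the repo name
    transform_env: dict[str, str] = field(default_factory=dict)
    image: str | None = None  # inert metadata; does not affect execution
    side_inputs: tuple[SideInput, ...] = ()
    parallelism: int = 1

    def __post_init__(self) -> None:
        validate_name(self.name, "pipeline name")
        validate_name(self.input_repo, "repo name")
        if self.input_name is not None:
            validate_name(self.input_name, "mount name")
            if self.input_name == self.input_repo:  # normalize the default
                object.__setattr__(self, "input_name", None)
        if not self.transform_cmd:
            raise ValidationError("transform cmd must be a non-empty argument vector")
        parse_glob(self.glob)
        if not isinstance(self.parallelism, int) or self.parallelism < 1:
            raise ValidationError(f"parallelism must be a positive integer, got {self.parallelism!r}")
        mounts = [self.mount_name] + [s.name for s in self.side_inputs]
        if len(set(mounts)) != len(mounts) or "out" in mounts:
            raise ValidationError(f"mount names must be unique and not 'out': {mounts}")

    @property
    def mount_name(self) -> str:
        return self.input_name if self.input_name is not None else self.input_repo

    @property
    def input_repos(self) -> tuple[str, ...]:
        """All repos this stage reads: the partitioned input plus side inputs."""
        return (self.input_repo,) + tuple(s.repo for s in self.side_inputs)

    def canonical_json(self) -> str:
        """Canonical serialization of the semantic fields.

        ``image`` is excluded: it is documentation-only here and does not
        change what the stage computes, so it must not invalidate reuse.
        """
        doc = {
            "name": self.name,
            "cmd": list(self.transform_cmd),
            "env": dict(sorted(self.transform_env.items())),
            "input": {"repo": self.input_repo, "glob": self.glob, "name": self.mount_name},
            "side_inputs": [{"repo": s.repo, "name": s.name} for s in self.side_inputs],
            "parallelism": self.parallelism,
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    @property
    def spec_version(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()

    def to_json(self) -> str:
        """Render the external JSON document (round-trippable, includes image)."""
        doc: dict = {
            "pipeline": {"name": self.name},
            "transform": {"cmd": list(self.transform_cmd)},
            "input": {"pfs": {"repo": self.input_repo, "glob": self.glob, "name": self.mount_name}},
            "parallelism_spec": {"constant": self.parallelism},
        }
        if self.transform_env:
            doc["transform"]["env"] = dict(self.transform_env)
        if self.image is not None:
            doc["transform"]["image"] = self.image
        if self.side_inputs:
            doc["side_inputs"] = [{"repo": s.repo, "name": s.name} for s in self.side_inputs]
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineSpec":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"pipeline spec is not valid JSON: {exc}") from exc
        try:
            name = doc["pipeline"]["name"]
            transform = doc["transform"]
            cmd = transform["cmd"]
            pfs = doc["input"]["pfs"]
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"pipeline spec is missing required field: {exc}") from exc
        if not isinstance(cmd, list) or not all(isinstance(a, str) for a in cmd):
            raise ValidationError("transform.cmd must be a list of strings")
        side = tuple(
            SideInput(repo=s["repo"], name=s.get("name", s["repo"]))
            for s in doc.get("side_inputs", [])
        )
        parallelism = doc.get("parallelism_spec", {}).get("constant", 1)
        return cls(
            name=name,
            transform_cmd=tuple(cmd),
            transform_env=dict(transform.get("env", {})),
            image=transform.get("image"),
            input_repo=pfs["repo"],
            glob=pfs.get("glob", "/"),
            input_name=pfs.get("name"),
            side_inputs=side,
            parallelism=parallelism,
        )
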