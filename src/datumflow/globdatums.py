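"""Glob-pattern partitioning of file trees into datums.

A datum is the minimal unit of computation: the subset of an input tree
rooted at one match of the pipeline's glob pattern.  The dialect is
deliberately small:

* ``/``   — the whole tree is a single datum;
* ``/*``  — every top-level entry (file, or directory with everything under
  it) is its own datum;
* general patterns of literal components where ``*`` matches any run of
  non-slash characters, e.g. ``/plates/*`` or ``/run_*``.

``**``, ``?`` and character classes are unsupported.  Because every root
matched by one pattern has the same number of path components, match roots
never nest, which keeps datum file sets disjoint and output merging
well-defined.

A datum's identity is a content hash of its (root-relative path, address)
pairs, so it depends only on the datum's own file names and bytes — never
on commit ids or timestamps.  Identical datum ids across two commits are
what licenses the engine to skip recomputation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError
from .filetree import FileTree, hash_entry_pairs
from .objectstore import ObjectRef

_COMPONENT_RE = re.compile(r"^[^/\0]+$")


def parse_glob(pattern: str) -> list[str]:
    """Validate a glob pattern, returning its component list ('' for '/')."""
    if not isinstance(pattern, str) or not pattern.startswith("/"):
        raise ValidationError(f"glob pattern must start with '/': {pattern!r}")
    if pattern == "/":
        return []
    if pattern.endswith("/"):
        raise ValidationError(f"glob pattern must not end with '/': {pattern!r}")
    components = pattern[1:].split("/")
    for comp in components:
        if not _COMPONENT_RE.match(comp):
            raise ValidationError(f"empty glob component in {pattern!r}")
        if "**" in comp:
            raise ValidationError("'**' is not supported in glob patterns")
        if "?" in comp or "[" in comp or "]" in comp:
            raise ValidationError(
                f"unsupported glob syntax in {pattern!r}: only '*' wildcards are allowed"
            )
    return components


def _component_regex(component: str) -> re.Pattern[str]:
    parts = [re.escape(piece) for piece in component.split("*")]
    return re.compile("^" + "[^/]*".join(parts) + "$")


@dataclass(frozen=True)
class Datum:
    """One unit of computation: a match root and the files at/under it."""

    root: str
    files: dict[str, ObjectRef] = field(compare=False)

    @property
    def datum_id(self) -> str:
        """Content hash over (root-relative path, address); commit-independent."""
        return hash_entry_pairs(
            (_relative_to_root(path, self.root), ref.address)
            for path, ref in self.files.items()
        )


def _relative_to_root(path: str, root: str) -> str:
    if root == "/":
        return path[1:]
    if path == root:  # the root matched a single file
        return root.rsplit("/", 1)[-1]
    if not path.startswith(root + "/"):
        raise ValidationError(f"path {path!r} is outside datum root {root!r}")
    return path[len(root) + 1 :]


def partition(tree: FileTree, pattern: str) -> list[Datum]:
    """Split ``tree`` into datums according to ``pattern``, ordered by root.

    ``/`` yields one datum holding every file (zero datums on an empty
    tree — there is nothing to compute).  Any other pattern yields one
    datum per distinct matching root, holding all files at or under that
    root.
    """
    components = parse_glob(pattern)
    if not components:
        if len(tree) == 0:
            return []
        return [Datum(root="/", files=tree.entries)]

    regexes = [_component_regex(c) for c in components]
    by_root: dict[str, dict[str, ObjectRef]] = {}
    for path, ref in tree.entries.items():
        parts = path[1:].split("/")
        if len(parts) < len(regexes):
            continue
        if all(rx.match(part) for rx, part in zip(regexes, parts)):
            root = "/" + "/".join(parts[: len(regexes)])
            by_root.setdefault(root, {})[path] = ref
    return [
        Datum(root=root, files=by_root[root])
        for root in sorted(by_root, key=str.encode)
    ]


@dataclass(frozen=True)
class DatumDiff:
    """Datum-level difference between two partitions of the same pattern."""

    unchanged: tuple[Datum, ...]
    changed: tuple[Datum, ...]  # new or modified, from the new tree
    removed: tuple[str, ...]  # roots present only in the old tree


def datum_diff(old_tree: FileTree | None, new_tree: FileTree, pattern: str) -> DatumDiff:
    """Classify the new tree's datums against the old tree's.

    Datums are matched by root; equal datum ids mean unchanged (and hence
    skippable), anything else is changed.  ``old_tree=None`` marks every
    datum changed — a from-scratch run.
    """
    new_datums = partition(new_tree, pattern)
    if old_tree is None:
        return DatumDiff(unchanged=(), changed=tuple(new_datums), removed=())
    old_by_root = {d.root: d for d in partition(old_tree, pattern)}
    unchanged: list[Datum] = []
    changed: list[Datum] = []
    for datum in new_datums:
        old = old_by_root.get(datum.root)
        if old is not None and old.datum_id == datum.datum_id:
            unchanged.append(datum)
        else:
            changed.append(datum)
    new_roots = {d.root for d in new_datums}
    removed = tuple(sorted((r for r in old_by_root if r not in new_roots), key=str.encode))
    return DatumDiff(unchanged=tuple(unchanged), changed=tuple(changed), removed=removed)


def datum_sandbox_paths(datum: Datum) -> dict[str, ObjectRef]:
    """Repo-root-relative paths for materializing a datum under its mount.

    Files keep their full repository paths (minus the leading slash) inside
    ``pfs/<mount>/`` so that a gather stage reading the whole repository and
    a scatter stage reading one file see the same layout.
    """
    return {path[1:]: ref for path, ref in datum.files.items()}


def workload_sizes(datums: Sequence[Datum]) -> list[int]:
    """Total byte size per datum — a convenient proxy workload for the scheduler."""
    return [sum(ref.size for ref in d.files.values()) for d in datums]
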