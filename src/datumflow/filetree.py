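"""Immutable file trees: path → blob mappings with a canonical content hash.

A tree is the payload of a commit.  Paths are absolute ('/' rooted),
slash-separated, with no trailing slash and no '..' components.
Directories are implicit: a directory exists exactly when some file path
has it as a prefix, so an empty directory cannot be represented — the same
semantics as an object store namespace.

The tree hash is a Merkle-style digest over the canonical serialization
``path\\0address\\n`` with entries sorted bytewise by path, so two trees hash
equal exactly when they contain the same (path, content) pairs, regardless
of insertion order or which commits produced them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError
from .objectstore import ObjectRef


def validate_path(path: str) -> str:
    if not path.startswith("/"):
        raise ValidationError(f"path must start with '/': {path!r}")
    if path != "/" and path.endswith("/"):
        raise ValidationError(f"path must not end with '/': {path!r}")
    parts = path[1:].split("/")
    if any(part in ("", ".", "..") for part in parts):
        raise ValidationError(f"path has empty or relative components: {path!r}")
    return path


class FileTree:
    """Immutable mapping of absolute file paths to object references."""

    __slots__ = ("_entries",)

    def __init__(self, entries: Mapping[str, ObjectRef] | None = None):
        entries = dict(entries or {})
        for path in entries:
            validate_path(path)
        # A path cannot be both a file and a directory prefix of another
        # file: such a tree could never be materialized on a filesystem.
        prefixes = sorted(entries)
        for shorter, longer in zip(prefixes, prefixes[1:]):
            if longer.startswith(shorter + "/"):
                raise ValidationError(
                    f"{shorter!r} is both a file and a parent of {longer!r}"
                )
        self._entries = entries

    @property
    def entries(self) -> dict[str, ObjectRef]:
        return dict(self._entries)

    def paths(self) -> list[str]:
        return sorted(self._entries, key=str.encode)

    def get(self, path: str) -> ObjectRef | None:
        return self._entries.get(path)

    def __contains__(self, path: str) -> bool:
        return path in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FileTree) and self._entries == other._entries

    def __hash__(self) -> int:
        return hash(self.tree_hash())

    def with_changes(self, changes: Mapping[str, ObjectRef | None]) -> "FileTree":
        """Copy-on-write derivation: apply additions/updates/deletions.

        A value of ``None`` deletes the path; unchanged paths keep their
        existing ObjectRefs so no content is duplicated.
        """
        entries = dict(self._entries)
        for path, ref in changes.items():
            validate_path(path)
            if ref is None:
                if path not in entries:
                    raise ValidationError(f"cannot delete nonexistent path {path!r}")
                del entries[path]
            else:
                entries[path] = ref
        return FileTree(entries)

    def canonical_serialization(self) -> bytes:
        lines = []
        for path in self.paths():
            lines.append(path.encode() + b"\0" + self._entries[path].address.encode() + b"\n")
        return b"".join(lines)

    def tree_hash(self) -> str:
        """SHA-256 of the canonical serialization; order-independent by construction."""
        return hashlib.sha256(self.canonical_serialization()).hexdigest()


@dataclass(frozen=True)
class DiffResult:
    """Path-level difference between two trees of the same repository."""

    added: frozenset[str] = field(default_factory=frozenset)
    modified: frozenset[str] = field(default_factory=frozenset)
    deleted: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_empty(self) -> bool:
        return not (self.added or self.modified or self.deleted)


def diff_trees(old: FileTree | None, new: FileTree) -> DiffResult:
    """Compare two trees; ``old=None`` means everything in ``new`` is added."""
    old_entries = old.entries if old is not None else {}
    new_entries = new.entries
    added = frozenset(p for p in new_entries if p not in old_entries)
    deleted = frozenset(p for p in old_entries if p not in new_entries)
    modified = frozenset(
        p
        for p in new_entries
        if p in old_entries and new_entries[p].address != old_entries[p].address
    )
    return DiffResult(added=added, modified=modified, deleted=deleted)


def hash_entry_pairs(pairs: Iterable[tuple[str, str]]) -> str:
    """Digest of sorted (relative path, address) pairs — shared by datum ids."""
    digest = hashlib.sha256()
    for path, address in sorted(pairs, key=lambda p: p[0].encode()):
        digest.update(path.encode() + b"\0" + address.encode() + b"\n")
    return digest.hexdigest()
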