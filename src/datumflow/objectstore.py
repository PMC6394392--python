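"""Content-addressed, deduplicating blob store.

Blobs are immutable byte strings named by the SHA-256 hex digest of their
contents, so identical content is stored exactly once and an address is
stable across processes and machines.  The store delegates persistence to a
small backend interface; the required backend writes blobs into a local
directory with a two-level fan-out by digest prefix.  An S3-compatible
backend can implement the same four methods and be slotted in unchanged.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Protocol

from .errors import NotFoundError, StorageError


def content_address(content: bytes) -> str:
    """SHA-256 hex digest of ``content`` — the blob's permanent name."""
    return hashlib.sha256(content).hexdigest()


@dataclass(frozen=True)
class ObjectRef:
    """Handle to an immutable blob: its content address and byte length."""

    address: str
    size: int

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("blob size cannot be negative")


@dataclass(frozen=True)
class StoreStats:
    object_count: int
    total_bytes: int


class BlobBackend(Protocol):
    """Minimal persistence contract behind the store."""

    def write(self, address: str, content: bytes) -> None: ...

    def read(self, address: str) -> bytes: ...

    def exists(self, address: str) -> bool: ...

    def list(self) -> Iterator[str]: ...


class LocalDirBackend:
    """Blob-per-file backend under a root directory.

    Files live at ``<root>/<aa>/<bb>/<digest>`` (two-level fan-out on the
    digest prefix) so no single directory grows unboundedly.  Writes go
    through a temporary file plus atomic rename, so a crashed write never
    leaves a corrupt blob at its final address.
    """

    def __init__(self, root: str | os.PathLike[str]):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, address: str) -> Path:
        return self.root / address[:2] / address[2:4] / address

    def write(self, address: str, content: bytes) -> None:
        path = self._path(address)
        if path.exists():
            return
        try:
            path.parent.mkdir(parents=True, exist_ok=True)
            tmp = path.with_name(path.name + f".tmp.{os.getpid()}")
            tmp.write_bytes(content)
            os.replace(tmp, path)
        except OSError as exc:  # pragma: no cover - depends on host filesystem
            raise StorageError(f"cannot write blob {address}: {exc}") from exc

    def read(self, address: str) -> bytes:
        path = self._path(address)
        try:
            return path.read_bytes()
        except FileNotFoundError:
            raise NotFoundError(f"no object with address {address}") from None
        except OSError as exc:  # pragma: no cover
            raise StorageError(f"cannot read blob {address}: {exc}") from exc

    def exists(self, address: str) -> bool:
        return self._path(address).exists()

    def list(self) -> Iterator[str]:
        for first in sorted(p for p in self.root.iterdir() if p.is_dir()):
            for second in sorted(p for p in first.iterdir() if p.is_dir()):
                for blob in sorted(p for p in second.iterdir() if p.is_file()):
                    if ".tmp." not in blob.name:
                        yield blob.name


class ObjectStore:
    """Deduplicating content-addressed store over a pluggable backend."""

    def __init__(self, backend: BlobBackend):
        self.backend = backend

    def put(self, content: bytes) -> ObjectRef:
        """Store ``content`` and return its handle.

        Re-putting identical bytes is a no-op on the backend: the address is
        a pure function of content, so the object count never grows for a
        duplicate.
        """
        address = content_address(content)
        if not self.backend.exists(address):
            self.backend.write(address, content)
        return ObjectRef(address=address, size=len(content))

    def get(self, ref: ObjectRef | str) -> bytes:
        """Return exactly the bytes stored under ``ref``."""
        address = ref.address if isinstance(ref, ObjectRef) else ref
        return self.backend.read(address)

    def contains(self, address: str) -> bool:
        return self.backend.exists(address)

    def stats(self) -> StoreStats:
        count = 0
        total = 0
        for address in self.backend.list():
            count += 1
            total += len(self.backend.read(address))
        return StoreStats(object_count=count, total_bytes=total)
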