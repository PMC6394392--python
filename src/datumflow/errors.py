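"""Exception hierarchy for the datumflow engine."""


class DatumflowError(Exception):
    """Base class for all engine errors."""


class ValidationError(DatumflowError):
    """Invalid user input: bad name, bad path, bad glob, bad parameter."""


class NotFoundError(DatumflowError):
    """A repo, commit, file, blob or job that does not exist."""


class AlreadyExistsError(DatumflowError):
    """Name collision on repo or pipeline creation."""


class StorageError(DatumflowError):
    """Backend read/write failure in the object store."""


class DAGViolationError(DatumflowError):
    """A pipeline definition would introduce a cycle in the repo/pipeline graph."""


class JobFailedError(DatumflowError):
    """Raised by callers that require a job to succeed (e.g. the demo driver)."""
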