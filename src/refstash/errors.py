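"""Exception hierarchy.

Every domain failure raised by this package derives from :class:`RefstashError`
so callers (notably the CLI) can map "domain error" to a single exit code while
letting programming errors propagate.
"""

from __future__ import annotations


class RefstashError(Exception):
    """Base class for all domain errors raised by refstash."""


class ConfigError(RefstashError):
    """Malformed registry or CLI configuration document."""


class LocFormatError(RefstashError):
    """A location file (or loc-format text) does not parse against its table spec."""


class EntryValidationError(RefstashError):
    """A table entry violates its table's column contract."""


class DuplicateKeyError(RefstashError):
    """Two rows share a key-column value in a table that forbids duplicates."""


class KeyConflictError(RefstashError):
    """An incoming entry reuses an existing key with different column values."""


class UnknownTableError(RefstashError):
    """A table name is not declared in the registry."""


class RecipeError(RefstashError):
    """A recipe document is malformed or inconsistent with the registry config."""


class BindingError(RefstashError):
    """Parameter bindings do not satisfy a recipe's parameter declarations."""


class TranslationError(RefstashError):
    """A value translation references an undefined placeholder or cannot apply."""


class BundleError(RefstashError):
    """A params/entries JSON bundle is malformed or violates the recipe contract."""


class InstallCollisionError(RefstashError):
    """The target asset directory is already populated; refusing to overwrite."""


class RunFailure(RefstashError):
    """A recipe execution terminated without committing (failed or rolled back)."""

    def __init__(self, message: str, record=None):
        super().__init__(message)
        self.record = record


class ProvenanceError(RefstashError):
    """Run-record store violation (duplicate run id, unknown run, bad record)."""


class ReplayError(RefstashError):
    """A recorded run cannot be replayed (e.g. recipe version unavailable)."""


class InjectedFailure(RefstashError):
    """Raised by test/diagnostic failpoints to simulate a crash inside a run."""
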