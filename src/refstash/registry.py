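"""Data-table registry backed by tab-separated location files.

A *data table* is a named registry of reference-data entries (rows) with a
fixed, ordered set of columns — the classic example is a ``bwa_indexes`` table
whose rows say, for each genome build, where the alignment index lives on
disk. Analysis tools consult the table; administrators (or, here, recipes)
append to it. Each table is persisted as a *location file* (".loc"): UTF-8
text, one row per line, columns joined by TAB, ``#`` full-line comments,
``\\n`` line terminator, no quoting or escaping. Values containing TAB or a
newline are rejected rather than escaped — loc files stay grep-able.

The :class:`Registry` keeps every table's rows in memory, mirrors them to the
loc files, and keeps both sides coherent: a successful append is visible to
queries immediately (no reload or restart step) and is already on disk.
Persistence is strictly append-only over the original bytes — comments and
blank lines a human left in a loc file are preserved verbatim — and atomic:
the new content is written to a temporary file in the same directory and
renamed over the original, under an advisory ``fcntl`` lock, so a reader never
observes a torn file and a crash leaves either the old or the new state.

Entry identity is the *key column* (named ``value`` by convention, the entry
"ID"). Appending a row whose key already exists is either a silent no-op (all
columns identical — idempotent re-registration) or a hard error (any column
differs — silent overwrite would falsify provenance).
"""

from __future__ import annotations

import fcntl
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    ConfigError,
    DuplicateKeyError,
    EntryValidationError,
    KeyConflictError,
    LocFormatError,
    UnknownTableError,
)

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

# characters that would corrupt the TAB-separated, line-oriented dialect
_FORBIDDEN_CHARS = ("\t", "\n", "\r")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    """One named column at a fixed 0-based position within a table."""

    name: str
    position: int

    def __post_init__(self):
        if not _IDENT_RE.match(self.name):
            raise ConfigError(f"invalid column name {self.name!r}")
        if self.position < 0:
            raise ConfigError(f"column {self.name!r}: negative position")


@dataclass(frozen=True)
class DataTableSpec:
    """Schema of one data table: ordered columns, loc path, identity column.

    Parameters
    ----------
    name
        Table identifier, unique within a registry.
    columns
        Ordered columns; positions must be exactly 0..k-1.
    loc_path
        Path of the location file, relative to the registry root.
    key_column
        Column giving an entry its identity (default ``"value"``).
    allow_duplicates
        If False (default) two rows may not share a key value.
    """

    name: str
    columns: tuple[ColumnSpec, ...]
    loc_path: str
    key_column: str = "value"
    allow_duplicates: bool = False

    def __post_init__(self):
        if not _IDENT_RE.match(self.name):
            raise ConfigError(f"invalid table name {self.name!r}")
        if not self.loc_path:
            raise ConfigError(f"table {self.name!r}: empty loc_path")
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ConfigError(f"table {self.name!r}: duplicate column names")
        if [c.position for c in self.columns] != list(range(len(self.columns))):
            raise ConfigError(
                f"table {self.name!r}: column positions must be 0..{len(self.columns) - 1} in order"
            )
        if self.key_column not in names:
            raise ConfigError(
                f"table {self.name!r}: key column {self.key_column!r} not among columns {names}"
            )

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)


@dataclass(frozen=True)
class TableEntry:
    """One row: a mapping column-name -> string value."""

    values: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, column: str) -> str:
        return self.values[column]

    def validate(self, spec: DataTableSpec) -> None:
        declared = set(spec.column_names)
        got = set(self.values)
        if got != declared:
            missing = sorted(declared - got)
            extra = sorted(got - declared)
            parts = []
            if missing:
                parts.append(f"missing columns {missing}")
            if extra:
                parts.append(f"undeclared columns {extra}")
            raise EntryValidationError(f"table {spec.name!r}: " + "; ".join(parts))
        for col, val in self.values.items():
            if not isinstance(val, str):
                raise EntryValidationError(
                    f"table {spec.name!r}, column {col!r}: value must be a string"
                )
            for ch in _FORBIDDEN_CHARS:
                if ch in val:
                    raise EntryValidationError(
                        f"table {spec.name!r}, column {col!r}: value contains {ch!r}"
                    )
        if not self.values[spec.key_column]:
            raise EntryValidationError(
                f"table {spec.name!r}: key column {spec.key_column!r} is empty"
            )

    def key(self, spec: DataTableSpec) -> str:
        return self.values[spec.key_column]


# ---------------------------------------------------------------------------
# loc text codec
# ---------------------------------------------------------------------------

def parse_loc_text(text: str, spec: DataTableSpec) -> list[TableEntry]:
    """Parse loc-format text into entries, in file order.

    Empty lines, whitespace-only lines and lines whose first non-whitespace
    character is ``#`` are skipped. Every other line must split on TAB into
    exactly one field per declared column.

    Raises
    ------
    LocFormatError
        If a line has the wrong field count (the message names the 1-based
        line number).
    DuplicateKeyError
        If two rows share a key value and the table forbids duplicates.
    """
    ncol = len(spec.columns)
    entries: list[TableEntry] = []
    seen_keys: set[str] = set()
    for lineno, line in enumerate(text.split("\n"), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = line.rstrip("\r").split("\t")
        if len(fields) != ncol:
            raise LocFormatError(
                f"table {spec.name!r}, line {lineno}: expected {ncol} "
                f"TAB-separated fields, got {len(fields)}"
            )
        entry = TableEntry(dict(zip(spec.column_names, fields)))
        entry.validate(spec)
        key = entry.key(spec)
        if not spec.allow_duplicates:
            if key in seen_keys:
                raise DuplicateKeyError(
                    f"table {spec.name!r}, line {lineno}: duplicate key {key!r}"
                )
            seen_keys.add(key)
        entries.append(entry)
    return entries


def render_loc_text(entries: Sequence[TableEntry], spec: DataTableSpec) -> str:
    """Render entries as loc-format text: one TAB-joined line each, ``\\n``-terminated.

    Deterministic byte output for a given input; the persistence twin of
    :func:`parse_loc_text`.
    """
    lines = []
    for entry in entries:
        entry.validate(spec)
        lines.append("\t".join(entry.values[name] for name in spec.column_names))
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# registry config
# ---------------------------------------------------------------------------

def parse_registry_config(doc) -> list[DataTableSpec]:
    """Turn a parsed config document (mapping) into validated table specs.

    Expected shape::

        tables:
          - name: all_fasta
            columns: [value, dbkey, name, path]
            loc_path: all_fasta.loc
            key_column: value        # optional, default "value"
            allow_duplicates: false  # optional, default false
    """
    if not isinstance(doc, Mapping) or "tables" not in doc:
        raise ConfigError("registry config must be a mapping with a 'tables' list")
    raw_tables = doc["tables"]
    if not isinstance(raw_tables, Sequence) or isinstance(raw_tables, (str, bytes)):
        raise ConfigError("'tables' must be a list")
    specs: list[DataTableSpec] = []
    seen: set[str] = set()
    for i, item in enumerate(raw_tables):
        if not isinstance(item, Mapping):
            raise ConfigError(f"tables[{i}] must be a mapping")
        try:
            name = item["name"]
            columns = item["columns"]
            loc_path = item["loc_path"]
        except KeyError as exc:
            raise ConfigError(f"tables[{i}]: missing required field {exc}") from None
        if not isinstance(columns, Sequence) or isinstance(columns, (str, bytes)):
            raise ConfigError(f"table {name!r}: 'columns' must be a list of names")
        spec = DataTableSpec(
            name=name,
            columns=tuple(ColumnSpec(c, pos) for pos, c in enumerate(columns)),
            loc_path=str(loc_path),
            key_column=item.get("key_column", "value"),
            allow_duplicates=bool(item.get("allow_duplicates", False)),
        )
        if spec.name in seen:
            raise ConfigError(f"table {spec.name!r} declared twice")
        seen.add(spec.name)
        specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# the live registry
# ---------------------------------------------------------------------------

@dataclass
class _TableState:
    spec: DataTableSpec
    entries: list[TableEntry]
    raw_bytes: bytes  # current on-disk bytes (b"" if the loc file is absent)


class Registry:
    """Live, queryable registry state backed by location files.

    Outside a commit's critical section the in-memory rows of every table
    equal the parse of its loc file; :meth:`append_entries` maintains this by
    updating memory only after the on-disk rename has succeeded.
    """

    def __init__(self, registry_root: Path, data_root: Path,
                 table_specs: Iterable[DataTableSpec]):
        self.registry_root = Path(registry_root)
        self.data_root = Path(data_root)
        self.data_root.mkdir(parents=True, exist_ok=True)
        if not os.access(self.data_root, os.W_OK):
            raise ConfigError(f"data_root {self.data_root} is not writable")
        self._tables: dict[str, _TableState] = {}
        for spec in table_specs:
            if spec.name in self._tables:
                raise ConfigError(f"table {spec.name!r} declared twice")
            loc = self.loc_file(spec)
            if loc.exists():
                raw = loc.read_bytes()
                entries = parse_loc_text(raw.decode("utf-8"), spec)
            else:
                raw = b""
                entries = []
            self._tables[spec.name] = _TableState(spec, entries, raw)

    # -- introspection ------------------------------------------------------

    def loc_file(self, spec: DataTableSpec | str) -> Path:
        if isinstance(spec, str):
            spec = self.table_spec(spec)
        return self.registry_root / spec.loc_path

    @property
    def table_names(self) -> list[str]:
        return list(self._tables)

    def table_spec(self, table: str) -> DataTableSpec:
        return self._state(table).spec

    def _state(self, table: str) -> _TableState:
        try:
            return self._tables[table]
        except KeyError:
            raise UnknownTableError(f"unknown table {table!r}") from None

    # -- queries ------------------------------------------------------------

    def query_entries(self, table: str,
                      filter: Mapping[str, str] | None = None) -> list[TableEntry]:
        """Entries of *table* matching all filter pairs exactly, in insertion order."""
        state = self._state(table)
        if not filter:
            return list(state.entries)
        unknown = set(filter) - set(state.spec.column_names)
        if unknown:
            raise UnknownTableError(
                f"table {table!r}: unknown filter column(s) {sorted(unknown)}"
            )
        return [e for e in state.entries
                if all(e.values[c] == v for c, v in filter.items())]

    # -- mutation -----------------------------------------------------------

    def append_entries(self, table: str, entries: Sequence[TableEntry]) -> int:
        """Append entries to *table*, atomically persisting to its loc file.

        Returns the number of entries actually added. Incoming entries whose
        key matches an existing row are skipped if every column matches
        (idempotent) and rejected with :class:`KeyConflictError` — committing
        nothing — if any column differs. All validation happens before any
        byte is written: the commit is all-or-nothing.
        """
        state = self._state(table)
        spec = state.spec
        to_add: list[TableEntry] = []
        existing_by_key = {e.key(spec): e for e in state.entries}
        for entry in entries:
            entry.validate(spec)
            key = entry.key(spec)
            if not spec.allow_duplicates:
                prior = existing_by_key.get(key)
                if prior is not None:
                    if prior.values == dict(entry.values):
                        continue  # full-row duplicate: silently skipped
                    raise KeyConflictError(
                        f"table {table!r}: key {key!r} already present with "
                        f"different values"
                    )
                existing_by_key[key] = entry
            to_add.append(entry)
        if not to_add:
            return 0
        new_bytes = state.raw_bytes + render_loc_text(to_add, spec).encode("utf-8")
        self._commit_bytes(state, new_bytes)
        state.entries.extend(to_add)
        return len(to_add)

    def _commit_bytes(self, state: _TableState, new_bytes: bytes) -> None:
        """Atomically replace the loc file's content with *new_bytes*.

        Write-temp-then-rename in the loc file's own directory (rename is
        atomic on POSIX within a filesystem); a sidecar ``.lock`` file with an
        exclusive ``flock`` serializes concurrent commits.
        """
        loc = self.loc_file(state.spec)
        loc.parent.mkdir(parents=True, exist_ok=True)
        lock_path = loc.with_name(loc.name + ".lock")
        lock_fd = os.open(lock_path, os.O_CREAT | os.O_RDWR, 0o644)
        try:
            fcntl.flock(lock_fd, fcntl.LOCK_EX)
            fd, tmp_name = tempfile.mkstemp(prefix=loc.name + ".", dir=loc.parent)
            try:
                with os.fdopen(fd, "wb") as fh:
                    fh.write(new_bytes)
                    fh.flush()
                    os.fsync(fh.fileno())
                os.replace(tmp_name, loc)
            except BaseException:
                try:
                    os.unlink(tmp_name)
                except OSError:
                    pass
                raise
        finally:
            fcntl.flock(lock_fd, fcntl.LOCK_UN)
            os.close(lock_fd)
        state.raw_bytes = new_bytes

    # -- snapshot/restore (used by the engine's all-or-nothing rollback) ----

    def snapshot_table(self, table: str) -> tuple[bytes, int]:
        """Capture (loc bytes, entry count) of *table* for later restore."""
        state = self._state(table)
        return state.raw_bytes, len(state.entries)

    def restore_table(self, table: str, snapshot: tuple[bytes, int]) -> None:
        """Atomically rewind *table* to a previously captured snapshot."""
        state = self._state(table)
        raw, count = snapshot
        if state.raw_bytes != raw:
            self._commit_bytes(state, raw)
        del state.entries[count:]


def load_registry(config_doc, registry_root: Path | str,
                  data_root: Path | str) -> Registry:
    """Build a :class:`Registry` from a parsed config document.

    Absent loc files are treated as empty tables and created on first commit;
    present ones are parsed eagerly, so a malformed loc file fails the whole
    load rather than yielding a partially usable registry.
    """
    specs = parse_registry_config(config_doc)
    return Registry(Path(registry_root), Path(data_root), specs)
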