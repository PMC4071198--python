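"""Recipe execution engine.

One run walks the whole pipeline that an administrator used to perform by
hand: build a parameter bundle, execute the recipe in a private staging
directory, collect the entries it declares, finalize their values, install
the produced files into the permanent data store, and commit the new rows to
the live registry — atomically, with full rollback on any failure.

The engine and the recipe executable communicate only through two JSON
documents with fixed names inside the staging directory:

``params.json`` (engine -> tool)
    ``{"params": {...normalized bindings...}, "staging_dir": "...",
    "settings": {"data_root": "..."}}``. For subprocess recipes the file's
    path is also appended as the command's final token.

``entries.json`` (tool -> engine)
    ``{"data_tables": {table: [ {column: value, ...}, ... ]}}`` — raw entries
    for any number of declared output tables. The executable never touches a
    location file itself; this document is the only channel.

Recipes are either subprocess commands (token lists, substituted per token)
or *builtin actions*: in-process callables registered by name that honor the
identical bundle contract, so the test suite and offline installs need no
external binaries.

All-or-nothing: files are installed *before* the registry append (a registry
row pointing at missing files would silently poison downstream analyses,
whereas an orphaned directory is caught by the collision check); if the
append then fails, the installed directories are deleted and the loc files
rewound to their pre-run bytes. A terminal run record (succeeded / failed /
rolled_back) is persisted in every case.
"""

from __future__ import annotations

import contextlib
import hashlib
import io
import json
import os
import re
import shutil
import subprocess
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from . import provenance as _prov
from .errors import (
    BundleError,
    InjectedFailure,
    InstallCollisionError,
    RecipeError,
    RunFailure,
)
from .recipes import RecipeSpec, RecipeStore, finalize_entry, validate_bindings
from .registry import Registry, TableEntry

PARAMS_FILENAME = "params.json"
ENTRIES_FILENAME = "entries.json"

_PLACEHOLDER_RE = re.compile(r"\$\{([^}]*)\}")
_HEX64_RE = re.compile(r"^[0-9a-f]{64}$")


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamBundle:
    """The JSON parameter/settings dictionary handed to a recipe executable."""

    params: Mapping[str, object]
    staging_dir: str
    settings: Mapping[str, str]

    def to_json(self) -> str:
        doc = {
            "params": dict(self.params),
            "staging_dir": self.staging_dir,
            "settings": dict(self.settings),
        }
        return json.dumps(doc, sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ParamBundle":
        doc = json.loads(text)
        return cls(params=doc["params"], staging_dir=doc["staging_dir"],
                   settings=doc["settings"])


@dataclass(frozen=True)
class EntryBundle:
    """Raw entries a recipe emitted, grouped by target data table."""

    data_tables: Mapping[str, tuple[Mapping[str, str], ...]]

    def total_entries(self) -> int:
        return sum(len(v) for v in self.data_tables.values())


@dataclass(frozen=True)
class FileManifestItem:
    """One installed file: path (relative, no '..'), size and sha256 digest."""

    relpath: str
    size: int
    sha256: str

    def __post_init__(self):
        parts = Path(self.relpath).parts
        if ".." in parts or Path(self.relpath).is_absolute():
            raise BundleError(f"manifest path {self.relpath!r} escapes its root")
        if not _HEX64_RE.match(self.sha256):
            raise BundleError(f"manifest digest {self.sha256!r} is not 64 lowercase hex chars")


def sha256_file(path: Path, chunk: int = 1 << 16) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        while block := fh.read(chunk):
            h.update(block)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# builtin actions
# ---------------------------------------------------------------------------

#: in-process actions registered by name; each takes a ParamBundle, writes
#: entries.json into the staging dir, and returns an exit status (None == 0)
BUILTINS: dict[str, Callable[[ParamBundle], int | None]] = {}


def register_builtin(name: str):
    """Decorator registering a callable as a builtin recipe action.

    Re-registration replaces the previous callable (the fixtures module is
    imported both as a package module and as a script in subprocess runs).
    """

    def deco(fn):
        BUILTINS[name] = fn
        return fn

    return deco


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def build_param_bundle(recipe: RecipeSpec, bindings: Mapping[str, object],
                       staging_dir: Path, settings: Mapping[str, str]) -> ParamBundle:
    """Create the staging directory (must be fresh) and write ``params.json``."""
    staging_dir = Path(staging_dir)
    staging_dir.mkdir(parents=True, exist_ok=True)
    if any(staging_dir.iterdir()):
        raise BundleError(f"staging dir {staging_dir} is not empty")
    bundle = ParamBundle(
        params=dict(bindings),
        staging_dir=str(staging_dir),
        settings=dict(settings),
    )
    (staging_dir / PARAMS_FILENAME).write_text(bundle.to_json(), encoding="utf-8")
    return bundle


def invoke(recipe: RecipeSpec, bundle: ParamBundle) -> tuple[int, str]:
    """Run the recipe's command or builtin; return (exit status, captured log).

    Subprocess commands run with the staging directory as working directory,
    stdout and stderr merged into the log, and the params.json path appended
    as the final token. Builtins run in-process with their stdout/stderr
    captured the same way; an exception becomes exit status 1 with the
    traceback in the log.
    """
    staging = Path(bundle.staging_dir)
    params_path = staging / PARAMS_FILENAME
    if recipe.builtin is not None:
        fn = BUILTINS.get(recipe.builtin)
        if fn is None:
            return 127, f"builtin action {recipe.builtin!r} is not registered\n"
        buf = io.StringIO()
        cwd = os.getcwd()
        try:
            os.chdir(staging)
            with contextlib.redirect_stdout(buf), contextlib.redirect_stderr(buf):
                status = fn(bundle)
        except Exception:
            buf.write(traceback.format_exc())
            status = 1
        finally:
            os.chdir(cwd)
        return (0 if status is None else int(status)), buf.getvalue()

    tokens = [_substitute_token(tok, bundle.params, recipe) for tok in recipe.command]
    tokens.append(str(params_path))
    try:
        proc = subprocess.run(
            tokens, cwd=staging, stdout=subprocess.PIPE,
            stderr=subprocess.STDOUT, text=True,
        )
    except FileNotFoundError as exc:
        return 127, f"executable not found: {exc}\n"
    return proc.returncode, proc.stdout


def _substitute_token(token: str, params: Mapping[str, object],
                      recipe: RecipeSpec) -> str:
    def _sub(match: re.Match) -> str:
        name = match.group(1)
        if name not in params:  # parse_recipe already guarantees this
            raise RecipeError(
                f"recipe {recipe.id!r}: command placeholder ${{{name}}} unbound"
            )
        val = params[name]
        if isinstance(val, bool):
            return "true" if val else "false"
        return str(val)

    return _PLACEHOLDER_RE.sub(_sub, token)


def parse_entry_bundle(text: str, recipe: RecipeSpec) -> EntryBundle:
    """Validate the tool's ``entries.json`` against the recipe's declarations."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BundleError(f"entries.json is not valid JSON: {exc}") from None
    if not isinstance(doc, Mapping) or not isinstance(doc.get("data_tables"), Mapping):
        raise BundleError("entries.json must be {'data_tables': {table: [entry, ...]}}")
    declared = {o.table for o in recipe.outputs}
    tables: dict[str, tuple[Mapping[str, str], ...]] = {}
    for table, raw_entries in doc["data_tables"].items():
        if table not in declared:
            raise BundleError(
                f"entries.json names table {table!r} not declared by recipe {recipe.id!r}"
            )
        if not isinstance(raw_entries, Sequence) or isinstance(raw_entries, (str, bytes)):
            raise BundleError(f"entries for table {table!r} must be a list")
        cleaned = []
        for i, raw in enumerate(raw_entries):
            if not isinstance(raw, Mapping):
                raise BundleError(f"table {table!r} entry {i}: not a mapping")
            for k, v in raw.items():
                if not isinstance(k, str) or not isinstance(v, str):
                    raise BundleError(
                        f"table {table!r} entry {i}: non-string key or value ({k!r})"
                    )
            cleaned.append(dict(raw))
        tables[table] = tuple(cleaned)
    return EntryBundle(data_tables=tables)


def install_files(staging_dir: Path, asset_dir: Path, policy: str,
                  files: Sequence[str] = ()) -> list[FileManifestItem]:
    """Install staged files into *asset_dir* and return their manifest.

    ``copy_dir`` copies every staging file except the two bundle documents,
    preserving relative layout; ``copy_file`` copies only the named staging
    files; ``none`` moves nothing. The manifest (relative path, size, sha256)
    is computed *after* the copy from the installed bytes, so it attests to
    what actually landed on disk. A populated target directory is a collision
    error; a failed copy removes the partially installed directory.
    """
    staging_dir = Path(staging_dir)
    asset_dir = Path(asset_dir)
    if policy == "none":
        return []
    if asset_dir.exists() and any(asset_dir.iterdir()):
        raise InstallCollisionError(f"asset dir {asset_dir} already populated")
    created = not asset_dir.exists()
    asset_dir.mkdir(parents=True, exist_ok=True)
    try:
        if policy == "copy_dir":
            for src in sorted(staging_dir.rglob("*")):
                rel = src.relative_to(staging_dir)
                if str(rel) in (PARAMS_FILENAME, ENTRIES_FILENAME):
                    continue
                dst = asset_dir / rel
                if src.is_dir():
                    dst.mkdir(parents=True, exist_ok=True)
                else:
                    dst.parent.mkdir(parents=True, exist_ok=True)
                    shutil.copy2(src, dst)
        elif policy == "copy_file":
            for name in files:
                src = staging_dir / name
                if not src.is_file():
                    raise BundleError(f"copy_file: staged file {name!r} not found")
                dst = asset_dir / name
                dst.parent.mkdir(parents=True, exist_ok=True)
                shutil.copy2(src, dst)
        else:
            raise BundleError(f"unknown move policy {policy!r}")
    except BaseException:
        shutil.rmtree(asset_dir, ignore_errors=True)
        raise
    manifest = [
        FileManifestItem(
            relpath=str(p.relative_to(asset_dir)),
            size=p.stat().st_size,
            sha256=sha256_file(p),
        )
        for p in sorted(asset_dir.rglob("*"))
        if p.is_file()
    ]
    return manifest


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_recipe(registry: Registry, recipe_store: RecipeStore, recipe_id: str,
               bindings: Mapping[str, str], *, scratch_root: Path,
               provenance_store=None, recipe_version: str | None = None,
               failpoint: Callable[[str], None] | None = None):
    """Execute one recipe end-to-end and return its :class:`~refstash.provenance.RunRecord`.

    On any failure the registry and data root are left exactly as before the
    run (installed asset directories deleted, loc files rewound), a terminal
    record with status ``failed`` or ``rolled_back`` is persisted, and
    :class:`RunFailure` is raised carrying that record.

    *failpoint*, if given, is called with a stage name at each defined point
    (``before_invoke``, ``after_invoke``, ``after_parse``, ``after_install``,
    ``mid_append``) and may raise to simulate a crash there — this is the
    hook the crash-safety tests drive.
    """
    recipe = recipe_store.get(recipe_id, recipe_version)
    normalized = validate_bindings(recipe, bindings)
    run_id = _prov.new_run_id()
    started = _prov.utc_now()
    scratch_root = Path(scratch_root)
    staging = scratch_root / run_id
    data_root = registry.data_root

    log_parts: list[str] = []
    raw_bundle: EntryBundle | None = None
    installed_dirs: list[Path] = []
    snapshots: dict[str, tuple[bytes, int]] = {}
    final_entries: dict[str, list[TableEntry]] = {}
    added_counts: dict[str, int] = {}
    manifest: list[FileManifestItem] = []

    def _checkpoint(stage: str) -> None:
        if failpoint is not None:
            failpoint(stage)

    def _fail(message: str) -> RunFailure:
        # undo installs, rewind any committed appends, persist a terminal record
        for d in installed_dirs:
            shutil.rmtree(d, ignore_errors=True)
            parent = d.parent
            while parent != data_root and parent.is_dir() and not any(parent.iterdir()):
                parent.rmdir()
                parent = parent.parent
        for table, snap in snapshots.items():
            registry.restore_table(table, snap)
        status = "rolled_back" if (installed_dirs or snapshots) else "failed"
        log_parts.append(f"run aborted: {message}\n")
        record = _prov.RunRecord(
            run_id=run_id, recipe_id=recipe.id, recipe_version=recipe.version,
            bindings=dict(normalized), started=started, finished=_prov.utc_now(),
            status=status, data_root=str(data_root),
            raw_bundle=raw_bundle, final_entries={}, added_counts={},
            manifest=(), log="".join(log_parts),
        )
        if provenance_store is not None:
            provenance_store.save_record(record)
        return RunFailure(f"run {run_id} ({recipe.id}) {status}: {message}", record)

    try:
        bundle = build_param_bundle(
            recipe, normalized, staging, {"data_root": str(data_root)}
        )
        _checkpoint("before_invoke")
        status_code, log = invoke(recipe, bundle)
        log_parts.append(log)
        if status_code != 0:
            raise _fail(f"recipe executable exited with status {status_code}")
        _checkpoint("after_invoke")

        entries_path = staging / ENTRIES_FILENAME
        if not entries_path.is_file():
            raise _fail(f"recipe produced no {ENTRIES_FILENAME}")
        raw_bundle = parse_entry_bundle(
            entries_path.read_text(encoding="utf-8"), recipe
        )
        _checkpoint("after_parse")

        # finalize every entry up front: validation failures must precede installs
        plan = []  # (out decl, raw entry, finalized entry)
        for out in recipe.outputs:
            tspec = registry.table_spec(out.table)
            for raw in raw_bundle.data_tables.get(out.table, ()):
                entry = finalize_entry(
                    raw, out, {"data_root": str(data_root)}, tspec
                )
                # idempotent rerun: a full-row duplicate of an existing
                # registry row neither reinstalls nor recommits; a key
                # conflict fails here, before any file moves
                prior = registry.query_entries(
                    out.table, {tspec.key_column: entry.key(tspec)}
                )
                if prior and not tspec.allow_duplicates:
                    if prior[0].values == dict(entry.values):
                        log_parts.append(
                            f"table {out.table}: entry "
                            f"{entry.key(tspec)!r} already registered, skipping\n"
                        )
                        continue
                    raise _fail(
                        f"table {out.table}: key {entry.key(tspec)!r} already "
                        f"present with different values"
                    )
                plan.append((out, raw, entry))

        # install files, one asset directory per entry: data_root/table/<key>
        for out, raw, entry in plan:
            if out.move_policy == "none":
                continue
            tspec = registry.table_spec(out.table)
            asset_dir = data_root / out.table / entry.key(tspec)
            # under copy_file only the files named by translated columns move
            raw_names = [raw[t.column] for t in out.translations if t.column in raw]
            items = install_files(staging, asset_dir, out.move_policy, files=raw_names)
            installed_dirs.append(asset_dir)
            base = asset_dir.relative_to(data_root)
            manifest.extend(
                FileManifestItem(
                    relpath=str(base / it.relpath), size=it.size, sha256=it.sha256
                )
                for it in items
            )
        _checkpoint("after_install")

        # commit rows table by table, snapshotting for rollback
        by_table: dict[str, list[TableEntry]] = {}
        for out, _, entry in plan:
            by_table.setdefault(out.table, []).append(entry)
        first = True
        for table, entries in by_table.items():
            snapshots[table] = registry.snapshot_table(table)
            added_counts[table] = registry.append_entries(table, entries)
            final_entries[table] = entries
            if first:
                _checkpoint("mid_append")
                first = False
        total = sum(added_counts.values())
        log_parts.append(f"committed {total} new entr{'y' if total == 1 else 'ies'}\n")

    except RunFailure:
        raise
    except Exception as exc:
        if isinstance(exc, InjectedFailure):
            raise _fail(f"injected failure: {exc}") from exc
        raise _fail(str(exc)) from exc

    record = _prov.RunRecord(
        run_id=run_id, recipe_id=recipe.id, recipe_version=recipe.version,
        bindings=dict(normalized), started=started, finished=_prov.utc_now(),
        status="succeeded", data_root=str(data_root),
        raw_bundle=raw_bundle, final_entries=final_entries,
        added_counts=added_counts, manifest=tuple(manifest),
        log="".join(log_parts),
    )
    if provenance_store is not None:
        provenance_store.save_record(record)
    return record
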