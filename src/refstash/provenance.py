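"""Run records: persistence, verification and replay.

Every recipe execution — successful or not — leaves a *run record*: who ran
which recipe version with which normalized parameters, when, what the tool
emitted, which rows were committed, and a sha256 manifest of every installed
file. Records are one JSON document each under ``<root>/runs/``, append-only
(a terminal record is never rewritten), with lexicographically sortable
time-prefixed ids so history order needs no extra index.

Because the manifest digests the bytes that actually landed in the data
store, a record supports two operations the original manual workflow never
could:

verification
    recompute every manifest digest and re-query every committed row; any
    corrupted, truncated or deleted index file — and any manually deleted
    loc line — is pinpointed exactly.

replay
    re-execute the recorded recipe version with the recorded bindings
    against a fresh registry/data root and compare: for deterministic
    builders the installed files are digest-identical and the committed
    rows identical once the (legitimately host-specific) data-root prefix
    is factored out.
"""

from __future__ import annotations

import itertools
import json
import os
import threading
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence, TYPE_CHECKING

from .errors import ProvenanceError, ReplayError
from .registry import Registry, TableEntry

if TYPE_CHECKING:  # engine imports this module; avoid the cycle at runtime
    from .engine import EntryBundle, FileManifestItem

RUN_STATUSES = ("succeeded", "failed", "rolled_back")

_counter = itertools.count()
_counter_lock = threading.Lock()


def utc_now() -> str:
    """Current time as an RFC-3339 UTC timestamp with microseconds."""
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S.%fZ")


def new_run_id() -> str:
    """A unique, lexicographically time-sortable run id."""
    now = datetime.now(timezone.utc)
    with _counter_lock:
        seq = next(_counter) % 10000
    return (
        now.strftime("%Y%m%dT%H%M%S.%f")
        + f"-{seq:04d}-{os.urandom(3).hex()}"
    )


# ---------------------------------------------------------------------------
# the run record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunRecord:
    """Complete provenance for one recipe execution."""

    run_id: str
    recipe_id: str
    recipe_version: str
    bindings: Mapping[str, object]
    started: str
    finished: str
    status: str
    data_root: str
    raw_bundle: "EntryBundle | None"
    final_entries: Mapping[str, Sequence[TableEntry]]
    added_counts: Mapping[str, int]
    manifest: "tuple[FileManifestItem, ...]"
    log: str

    def __post_init__(self):
        if self.status not in RUN_STATUSES:
            raise ProvenanceError(f"invalid run status {self.status!r}")
        if self.status != "succeeded" and self.manifest:
            raise ProvenanceError("manifest only allowed on succeeded runs")

    def entries_added(self) -> int:
        return sum(self.added_counts.values())

    def to_doc(self) -> dict:
        return {
            "run_id": self.run_id,
            "recipe_id": self.recipe_id,
            "recipe_version": self.recipe_version,
            "bindings": dict(self.bindings),
            "started": self.started,
            "finished": self.finished,
            "status": self.status,
            "data_root": self.data_root,
            "raw_bundle": (
                None if self.raw_bundle is None
                else {"data_tables": {
                    t: [dict(e) for e in es]
                    for t, es in self.raw_bundle.data_tables.items()
                }}
            ),
            "final_entries": {
                t: [dict(e.values) for e in es]
                for t, es in self.final_entries.items()
            },
            "added_counts": dict(self.added_counts),
            "manifest": [
                {"relpath": m.relpath, "size": m.size, "sha256": m.sha256}
                for m in self.manifest
            ],
            "log": self.log,
        }

    @classmethod
    def from_doc(cls, doc: Mapping) -> "RunRecord":
        from .engine import EntryBundle, FileManifestItem

        raw = doc.get("raw_bundle")
        return cls(
            run_id=doc["run_id"],
            recipe_id=doc["recipe_id"],
            recipe_version=doc["recipe_version"],
            bindings=dict(doc["bindings"]),
            started=doc["started"],
            finished=doc["finished"],
            status=doc["status"],
            data_root=doc["data_root"],
            raw_bundle=(
                None if raw is None
                else EntryBundle(data_tables={
                    t: tuple(dict(e) for e in es)
                    for t, es in raw["data_tables"].items()
                })
            ),
            final_entries={
                t: [TableEntry(e) for e in es]
                for t, es in doc["final_entries"].items()
            },
            added_counts=dict(doc["added_counts"]),
            manifest=tuple(
                FileManifestItem(**m) for m in doc["manifest"]
            ),
            log=doc["log"],
        )


# ---------------------------------------------------------------------------
# the store
# ---------------------------------------------------------------------------

class ProvenanceStore:
    """Append-only collection of run records, one JSON document per run."""

    def __init__(self, root: Path | str):
        self.root = Path(root)
        self.runs_dir = self.root / "runs"
        self.runs_dir.mkdir(parents=True, exist_ok=True)

    def _path(self, run_id: str) -> Path:
        return self.runs_dir / f"{run_id}.json"

    def save_record(self, record: RunRecord) -> Path:
        path = self._path(record.run_id)
        if path.exists():
            raise ProvenanceError(f"run {record.run_id!r} already recorded")
        tmp = path.with_suffix(".json.tmp")
        tmp.write_text(
            json.dumps(record.to_doc(), sort_keys=True, indent=2) + "\n",
            encoding="utf-8",
        )
        os.replace(tmp, path)
        return path

    def load_record(self, run_id: str) -> RunRecord:
        path = self._path(run_id)
        if not path.is_file():
            raise ProvenanceError(f"unknown run {run_id!r}")
        return RunRecord.from_doc(json.loads(path.read_text(encoding="utf-8")))

    def run_ids(self) -> list[str]:
        return sorted(p.stem for p in self.runs_dir.glob("*.json"))


def save_record(store: ProvenanceStore, record: RunRecord) -> Path:
    return store.save_record(record)


def history(store: ProvenanceStore, recipe_id: str | None = None) -> list[dict]:
    """Run summaries in execution (run-id) order, optionally filtered by recipe."""
    out = []
    for rid in store.run_ids():
        rec = store.load_record(rid)
        if recipe_id is not None and rec.recipe_id != recipe_id:
            continue
        out.append({
            "run_id": rec.run_id,
            "recipe_id": rec.recipe_id,
            "recipe_version": rec.recipe_version,
            "status": rec.status,
            "entries_added": rec.entries_added(),
            "added_counts": dict(rec.added_counts),
        })
    return out


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VerificationReport:
    """Per-file and per-entry outcome of verifying one committed run."""

    run_id: str
    files: tuple[tuple[str, str], ...]    # (relpath under data_root, ok|mismatch|missing)
    entries: tuple[tuple[str, str, str], ...]  # (table, key, present|absent)
    passed: bool

    def failures(self) -> list[str]:
        out = [f"file {p}: {s}" for p, s in self.files if s != "ok"]
        out += [f"entry {t}/{k}: {s}" for t, k, s in self.entries if s != "present"]
        return out


def verify_run(store: ProvenanceStore, registry: Registry,
               run_id: str) -> VerificationReport:
    """Check a succeeded run's installed files and committed rows, today.

    Every manifest file's digest is recomputed from disk and every committed
    entry re-queried from the live registry; the report names each mismatch
    or absence individually.
    """
    from .engine import sha256_file

    record = store.load_record(run_id)
    if record.status != "succeeded":
        raise ProvenanceError(
            f"run {run_id!r} has status {record.status!r}; only succeeded runs "
            f"are verifiable"
        )
    data_root = registry.data_root
    file_results = []
    for item in record.manifest:
        path = data_root / item.relpath
        if not path.is_file():
            file_results.append((item.relpath, "missing"))
        elif sha256_file(path) != item.sha256 or path.stat().st_size != item.size:
            file_results.append((item.relpath, "mismatch"))
        else:
            file_results.append((item.relpath, "ok"))
    entry_results = []
    for table, entries in record.final_entries.items():
        spec = registry.table_spec(table)
        current = {tuple(sorted(e.values.items())) for e in registry.query_entries(table)}
        for entry in entries:
            present = tuple(sorted(entry.values.items())) in current
            entry_results.append(
                (table, entry.key(spec), "present" if present else "absent")
            )
    passed = all(s == "ok" for _, s in file_results) and \
        all(s == "present" for _, _, s in entry_results)
    return VerificationReport(
        run_id=run_id, files=tuple(file_results),
        entries=tuple(entry_results), passed=passed,
    )


# ---------------------------------------------------------------------------
# replay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplayComparison:
    """How a replayed run compares with its original record."""

    entries_match: bool        # committed rows identical modulo data_root prefix
    digests_match: bool        # installed-file manifests identical (relpath+sha256)
    replay_added: int          # rows the replay actually added (0 == duplicate-consistent)
    mismatches: tuple[str, ...]

    @property
    def fidelity(self) -> bool:
        return self.entries_match and self.digests_match


def _normalize_entry(entry: TableEntry, data_root: str) -> tuple:
    prefix = data_root.rstrip("/") + "/"
    vals = {
        c: ("${data_root}/" + v[len(prefix):] if v.startswith(prefix) else v)
        for c, v in entry.values.items()
    }
    return tuple(sorted(vals.items()))


def compare_replay(original: RunRecord, replayed: RunRecord) -> ReplayComparison:
    """Compare two runs of the same recipe modulo their data-root prefixes."""
    mismatches: list[str] = []
    orig = {
        t: [_normalize_entry(e, original.data_root) for e in es]
        for t, es in original.final_entries.items()
    }
    new = {
        t: [_normalize_entry(e, replayed.data_root) for e in es]
        for t, es in replayed.final_entries.items()
    }
    entries_match = orig == new
    if not entries_match:
        mismatches.append("final entries differ (modulo data_root)")
    orig_digests = {m.relpath: m.sha256 for m in original.manifest}
    new_digests = {m.relpath: m.sha256 for m in replayed.manifest}
    digests_match = orig_digests == new_digests
    for rel in sorted(set(orig_digests) | set(new_digests)):
        a, b = orig_digests.get(rel), new_digests.get(rel)
        if a != b:
            mismatches.append(f"digest differs for {rel}: {a} vs {b}")
    return ReplayComparison(
        entries_match=entries_match, digests_match=digests_match,
        replay_added=replayed.entries_added(), mismatches=tuple(mismatches),
    )


def replay_run(store: ProvenanceStore, run_id: str, recipe_store,
               fresh_registry: Registry, *, scratch_root: Path,
               provenance_store: ProvenanceStore | None = None) -> RunRecord:
    """Re-execute a recorded run against a fresh registry and data root.

    The exact recorded recipe version must be available; a different version
    is never silently substituted. The returned record can be compared with
    the original via :func:`compare_replay`.
    """
    from .engine import run_recipe

    record = store.load_record(run_id)
    try:
        recipe_store.get(record.recipe_id, record.recipe_version)
    except Exception:
        raise ReplayError(
            f"recipe {record.recipe_id!r} version {record.recipe_version!r} "
            f"not available in the recipe store"
        ) from None
    return run_recipe(
        fresh_registry, recipe_store, record.recipe_id,
        {k: str(v) for k, v in record.bindings.items()},
        scratch_root=scratch_root,
        provenance_store=provenance_store,
        recipe_version=record.recipe_version,
    )
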