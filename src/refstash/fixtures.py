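"""Synthetic data and toy recipes: a complete, download-free demo pipeline.

Real deployments of a reference-data manager fetch genomes from mirrors and
run aligner binaries; everything here stands in for that with deterministic,
content-checkable substitutes so the whole pipeline — recipe, staging, JSON
contracts, installation, registry commit, provenance verify/replay — runs
offline in milliseconds:

* :func:`make_fasta` writes a seeded pseudo-random FASTA "genome";
* the ``fetch_local_fasta`` builtin registers a FASTA into ``all_fasta``
  (the local analogue of downloading a reference genome);
* the ``toy_index`` builtin is a miniature indexer: instead of a BWT it
  derives per-sequence lengths (``.sizes``) and a sha256 of the input
  (``.sum``) — real, independently recomputable content, so tamper-evidence
  and replay tests have teeth;
* the ``toy_multi`` builtin emits entries into two tables at once.

Every builtin is a deterministic function of its parameters, which is what
makes provenance replay exactly reproducible. Each is also runnable as a
subprocess (``python -m refstash.fixtures <action> <params.json>``), proving
that the in-process and subprocess invocation paths honor one contract.

``toy_index`` mimics an indexer that picks its algorithm automatically from
genome size: with ``algorithm=auto`` it chooses ``small`` below
:data:`TOY_AUTO_THRESHOLD_BASES` total bases and ``large`` at or above it.
The threshold is a fixture constant chosen to exercise the branch, not a
claim about any real aligner's cutoff.
"""

from __future__ import annotations

import hashlib
import json
import random
import shutil
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .engine import ENTRIES_FILENAME, ParamBundle, register_builtin
from .errors import ConfigError
from .recipes import DEFAULT_PATH_TEMPLATE

#: total-base cutoff for toy_index's algorithm=auto branch (fixture-only)
TOY_AUTO_THRESHOLD_BASES = 100_000


# ---------------------------------------------------------------------------
# synthetic genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a deterministic random genome: same seed, same bytes."""

    seed: int
    n_sequences: int = 2
    length: int = 120
    alphabet: str = "ACGT"

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ConfigError("n_sequences must be >= 1")
        if self.length < 1:
            raise ConfigError("length must be >= 1")
        if not self.alphabet:
            raise ConfigError("alphabet must be non-empty")


def make_fasta(spec: SyntheticGenomeSpec, out_path: Path | str) -> Path:
    """Write a synthetic FASTA (60-column wrap, headers ``>synth_<i>``)."""
    rng = random.Random(spec.seed)
    records = [
        SeqRecord(
            Seq("".join(rng.choice(spec.alphabet) for _ in range(spec.length))),
            id=f"synth_{i}",
            description="",
        )
        for i in range(1, spec.n_sequences + 1)
    ]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", encoding="ascii") as fh:
        SeqIO.write(records, fh, "fasta")
    return out_path


# ---------------------------------------------------------------------------
# builtin actions
# ---------------------------------------------------------------------------

def _emit_entries(staging: Path, data_tables: dict) -> None:
    (staging / ENTRIES_FILENAME).write_text(
        json.dumps({"data_tables": data_tables}, sort_keys=True, indent=2) + "\n",
        encoding="utf-8",
    )


@register_builtin("fetch_local_fasta")
def fetch_local_fasta(bundle: ParamBundle) -> int:
    """Stage a local FASTA and register it into ``all_fasta``.

    Emits one raw entry whose path is the FASTA *basename*; the declared
    path translation finalizes it to the installed absolute path.
    """
    staging = Path(bundle.staging_dir)
    dbkey = str(bundle.params["dbkey"])
    name = str(bundle.params["name"])
    src = Path(str(bundle.params["fasta"]))
    if not src.is_file():
        print(f"error: FASTA {src} not readable", file=sys.stderr)
        return 1
    if src.stat().st_size == 0:
        print(f"error: FASTA {src} is empty", file=sys.stderr)
        return 1
    dest = staging / src.name
    shutil.copy2(src, dest)
    print(f"staged {src.name} ({dest.stat().st_size} bytes)")
    _emit_entries(staging, {
        "all_fasta": [
            {"value": dbkey, "dbkey": dbkey, "name": name, "path": src.name}
        ]
    })
    return 0


@register_builtin("toy_index")
def toy_index(bundle: ParamBundle) -> int:
    """Build a toy "index" of a FASTA: per-sequence lengths plus a digest.

    Writes ``<basename>.sizes`` (one ``header<TAB>length`` line per sequence)
    and ``<basename>.sum`` (sha256 of the FASTA bytes) next to a staged copy
    of the FASTA, then emits one raw ``toy_indexes`` entry. With
    ``algorithm=auto`` the resolved choice (by total bases against
    :data:`TOY_AUTO_THRESHOLD_BASES`) is appended to the display name.
    """
    staging = Path(bundle.staging_dir)
    dbkey = str(bundle.params["dbkey"])
    algorithm = str(bundle.params.get("algorithm", "auto"))
    src = Path(str(bundle.params["fasta"]))
    if not src.is_file():
        print(f"error: FASTA {src} not readable", file=sys.stderr)
        return 1
    text = src.read_text(encoding="utf-8", errors="replace")
    if not text.strip() or not text.lstrip().startswith(">"):
        print(f"error: {src} is not FASTA (no '>' record)", file=sys.stderr)
        return 1

    records = list(SeqIO.parse(str(src), "fasta"))
    if not records:
        print(f"error: {src} contains no sequences", file=sys.stderr)
        return 1

    dest = staging / src.name
    shutil.copy2(src, dest)
    sizes_lines = [f"{rec.id}\t{len(rec.seq)}" for rec in records]
    (staging / (src.name + ".sizes")).write_text(
        "".join(line + "\n" for line in sizes_lines), encoding="utf-8"
    )
    digest = hashlib.sha256(src.read_bytes()).hexdigest()
    (staging / (src.name + ".sum")).write_text(digest + "\n", encoding="utf-8")

    total = sum(len(rec.seq) for rec in records)
    name = f"{dbkey} toy index"
    if algorithm == "auto":
        resolved = "small" if total < TOY_AUTO_THRESHOLD_BASES else "large"
        name += f" ({resolved})"
        print(f"auto algorithm: {total} bases -> {resolved}")
    else:
        resolved = algorithm
    print(f"indexed {len(records)} sequences, {total} bases, algorithm={resolved}")

    _emit_entries(staging, {
        "toy_indexes": [
            {"value": dbkey, "dbkey": dbkey, "name": name, "path": src.name}
        ]
    })
    return 0


@register_builtin("toy_multi")
def toy_multi(bundle: ParamBundle) -> int:
    """Emit entries into two tables at once (2 k-mer rows + 3 stat rows)."""
    staging = Path(bundle.staging_dir)
    dbkey = str(bundle.params["dbkey"])
    _emit_entries(staging, {
        "toy_kmers": [
            {"value": f"{dbkey}_k{k}", "dbkey": dbkey,
             "name": f"{dbkey} {k}-mers", "path": f"{dbkey}.k{k}"}
            for k in (11, 31)
        ],
        "toy_stats": [
            {"value": f"{dbkey}_{stat}", "dbkey": dbkey,
             "name": f"{dbkey} {stat}", "path": f"{dbkey}.{stat}"}
            for stat in ("gc", "n50", "len")
        ],
    })
    return 0


# ---------------------------------------------------------------------------
# fixture documents
# ---------------------------------------------------------------------------

def fixture_registry_config() -> dict:
    """Registry config declaring the four demo tables."""
    def table(name):
        return {
            "name": name,
            "columns": ["value", "dbkey", "name", "path"],
            "loc_path": f"{name}.loc",
        }

    return {"tables": [table(n) for n in
                       ("all_fasta", "toy_indexes", "toy_kmers", "toy_stats")]}


def fixture_recipe_docs(python: str | None = None) -> dict[str, dict]:
    """The demo recipe documents, keyed by recipe id.

    ``toy_index_cmd`` is the subprocess twin of the ``toy_index`` builtin; it
    invokes this module as a script with *python* (default: the current
    interpreter).
    """
    python = python or sys.executable
    path_tr = [{"column": "path", "kind": "template",
                "template": DEFAULT_PATH_TEMPLATE}]
    docs = {
        "fetch_local_fasta": {
            "id": "fetch_local_fasta",
            "version": "1.0.0",
            "name": "Fetch local FASTA",
            "description": "Register a local FASTA file as a reference genome.",
            "builtin": "fetch_local_fasta",
            "params": [
                {"name": "dbkey", "kind": "text"},
                {"name": "name", "kind": "text"},
                {"name": "fasta", "kind": "input_path"},
            ],
            "outputs": [
                {"table": "all_fasta", "translations": path_tr,
                 "move_policy": "copy_dir"},
            ],
        },
        "toy_index": {
            "id": "toy_index",
            "version": "1.0.0",
            "name": "Toy indexer",
            "description": "Derive per-sequence lengths and a digest from a FASTA.",
            "builtin": "toy_index",
            "params": [
                {"name": "dbkey", "kind": "text"},
                {"name": "fasta", "kind": "input_path"},
                {"name": "algorithm", "kind": "choice", "default": "auto",
                 "choices": ["auto", "small", "large"]},
            ],
            "outputs": [
                {"table": "toy_indexes", "translations": path_tr,
                 "move_policy": "copy_dir"},
            ],
        },
        "toy_multi": {
            "id": "toy_multi",
            "version": "1.0.0",
            "name": "Toy multi-table writer",
            "description": "Emit entries into two tables in one run.",
            "builtin": "toy_multi",
            "params": [{"name": "dbkey", "kind": "text"}],
            "outputs": [
                {"table": "toy_kmers", "move_policy": "none"},
                {"table": "toy_stats", "move_policy": "none"},
            ],
        },
    }
    cmd_twin = json.loads(json.dumps(docs["toy_index"]))
    cmd_twin["id"] = "toy_index_cmd"
    cmd_twin["name"] = "Toy indexer (subprocess)"
    del cmd_twin["builtin"]
    cmd_twin["command"] = [python, "-m", "refstash.fixtures", "toy_index"]
    docs["toy_index_cmd"] = cmd_twin
    return docs


def write_fixture_workspace(root: Path | str) -> dict[str, Path]:
    """Materialize a ready-to-use workspace under *root*.

    Writes the registry config, recipe documents and CLI config, and creates
    the registry/data/scratch/provenance directories. Returns the key paths.
    """
    root = Path(root).resolve()
    paths = {
        "root": root,
        "registry_config": root / "registry.yaml",
        "registry_root": root / "registry",
        "data_root": root / "data",
        "scratch_root": root / "scratch",
        "provenance_root": root / "provenance",
        "recipes_dir": root / "recipes",
        "cli_config": root / "refstash.yaml",
    }
    for key in ("registry_root", "data_root", "scratch_root",
                "provenance_root", "recipes_dir"):
        paths[key].mkdir(parents=True, exist_ok=True)
    paths["registry_config"].write_text(
        yaml.safe_dump(fixture_registry_config(), sort_keys=False),
        encoding="utf-8",
    )
    for rid, doc in fixture_recipe_docs().items():
        (paths["recipes_dir"] / f"{rid}.yaml").write_text(
            yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
        )
    paths["cli_config"].write_text(
        yaml.safe_dump({
            "registry_config": str(paths["registry_config"]),
            "registry_root": str(paths["registry_root"]),
            "data_root": str(paths["data_root"]),
            "scratch_root": str(paths["scratch_root"]),
            "provenance_root": str(paths["provenance_root"]),
            "recipes_dir": str(paths["recipes_dir"]),
        }, sort_keys=False),
        encoding="utf-8",
    )
    return paths


# ---------------------------------------------------------------------------
# subprocess entry point
# ---------------------------------------------------------------------------

def main(argv: list[str] | None = None) -> int:
    """``python -m refstash.fixtures <action> <params.json>``.

    Reads the parameter bundle, dispatches to the named builtin, and exits
    with its status — the subprocess side of the engine's JSON contract.
    """
    from .engine import BUILTINS

    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 2:
        print("usage: python -m refstash.fixtures <action> <params.json>",
              file=sys.stderr)
        return 2
    action, params_path = argv
    fn = BUILTINS.get(action)
    if fn is None:
        print(f"error: unknown action {action!r}", file=sys.stderr)
        return 2
    bundle = ParamBundle.from_json(Path(params_path).read_text(encoding="utf-8"))
    status = fn(bundle)
    return 0 if status is None else int(status)


if __name__ == "__main__":
    sys.exit(main())
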