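# Methods

## The data model

A **data table** is a named registry with an ordered, fixed column set; one
row ("entry") per reference asset. By convention the columns are `value`
(the entry ID and identity key), `dbkey` (genome-build key, e.g. `hg19`),
`name` (display text) and `path` (installed location), but any identifier
columns are allowed and the key column is configurable per table.

Each table persists as a **location file**: UTF-8, TAB-separated, one row
per line, `#` full-line comments, `\n` terminators, no quoting or escaping.
This is the historical dialect that existing servers and shell pipelines
(`grep`, `cut`) already understand; values containing TAB, CR or LF are
rejected outright rather than escaped, deliberately keeping the format
trivially greppable. Comment and blank lines that humans left in a loc file
are preserved verbatim because persistence only ever appends to the
original bytes.

A **recipe** merges what older systems split across a tool description and
a separate framework configuration into one document with distinct
sections: `params`/`command` describe the builder, `outputs`/`translations`
describe how its results become registry rows. Nothing is lost by the
merge — the two concerns remain separate sections — and a recipe is one
reviewable file.

## Commit semantics

* **Atomicity.** A commit renders the new rows, writes `old bytes + new
  bytes` to a temporary file in the loc file's own directory, fsyncs, and
  `rename(2)`s it over the original. POSIX rename atomicity guarantees a
  reader sees either the old or the new file, never a torn one. A sidecar
  `.lock` file with an exclusive `fcntl.flock` serializes concurrent
  commits from cooperating processes (advisory only — a non-cooperating
  writer can still corrupt a loc file, as it always could).
* **Identity and duplicates.** Entry identity is the key column. An
  incoming row whose key exists with *identical* columns is silently
  skipped (re-registration is idempotent); with *differing* columns it is a
  hard error and nothing commits. Silent overwrite was rejected because it
  would falsify previously recorded provenance. What a registry should do
  with a pre-existing duplicate-keyed loc file is genuinely open; here it
  is a load-time error unless the table opts into `allow_duplicates`.
* **Rollback.** The engine installs files *before* appending rows: a
  registry row pointing at missing files silently poisons downstream
  analyses, whereas an orphaned directory is caught by the collision check
  on the next install. If anything fails after installation, installed
  asset directories are deleted and every touched loc file is rewound to a
  byte snapshot taken just before its append. The snapshot/restore path
  exists only for this rollback; normal operation is append-only.
* **Idempotent reruns.** Before installing anything, each finalized entry
  is checked against the live registry; full-row duplicates skip both the
  install and the append, so rerunning a recipe with identical bindings
  succeeds, adds zero rows and leaves loc files byte-identical.

## The execution contract

The engine and the builder communicate exclusively through two JSON
documents with fixed names in the per-run staging directory: `params.json`
(engine → tool: normalized bindings plus `settings.data_root`) and
`entries.json` (tool → engine: `{"data_tables": {table: [entry, ...]}}`,
any number of entries for any number of declared tables). Fixed filenames
keep shell recipes trivial; schemas live in `docs/schemas/`. Subprocess
commands are token lists — substitution of `${param}` happens per token, so
a parameter value can never inject extra arguments or shell syntax — and
the `params.json` path is appended as the final token. Builtins are
in-process callables registered by name that receive the identical bundle;
the test suite proves the two paths produce identical registry rows and
file digests.

Value translations come in two kinds, `template` (substituting
`${data_root}`, `${table}`, `${value}`, `${dbkey}`, `${raw}`) and `abspath`
(idempotent join under the data root). The default layout
`${data_root}/${table}/${value}/<files>` keeps each build's assets in a
self-contained directory keyed by table and entry ID. Further kinds
(e.g. checksum-of-file) are extension points. Unknown placeholders are
parse-time errors, never silent empty strings.

## Provenance

A run record (schema in `docs/schemas/run_record.schema.json`) stores the
recipe id+version, normalized bindings, UTC RFC-3339 timestamps, status,
the raw entry bundle as received, the finalized rows as committed, per-table
added counts, the captured log, and a sha256 manifest of every installed
file. sha256 was chosen as ubiquitous and collision-resistant; manifest
paths are stored relative to the data root (so they include the
table/value segments and a single record suffices to relocate every file).
What a provenance record must minimally contain is a design decision of
this package; this field set is the smallest one that makes verification
and replay possible.

`verify` recomputes every digest and re-queries every committed row,
naming each mismatching/missing file and absent entry individually.
`replay` re-executes the recorded recipe *version* (never a substitute)
with the recorded bindings into a fresh registry and data root; the
comparison normalizes away the data-root prefix because absolute install
paths legitimately differ between hosts, then requires identical entry
values and identical file digests. Records are append-only: one JSON file
per run, never rewritten, with ids prefixed by a sortable UTC timestamp so
history order needs no index.

## Synthetic data and the toy recipes

The fixtures module emulates the real workflow's inputs without network or
binaries. `make_fasta` produces a seeded pseudo-random genome (default 2
sequences × 120 bases — large enough to wrap lines and exercise multi-record
parsing, small enough that a full pipeline run takes milliseconds); the same
seed yields byte-identical output, which is the foundation of the replay
tests. The `toy_index` builtin computes *checkable* derived data — a
`.sizes` file of per-sequence lengths and a `.sum` sha256 of the input —
rather than empty marker files, so tamper-evidence and replay tests compare
real content. Its `algorithm=auto` branch mimics indexers that pick an
algorithm from genome size; the cutoff (100 000 total bases,
`TOY_AUTO_THRESHOLD_BASES`) is a fixture constant chosen only to make both
branches reachable and is not a claim about any real aligner.

What the fixtures do **not** emulate: real aligner index formats (BWT,
suffix arrays), network retrieval and its failure modes, multi-gigabyte
assets, or concurrent multi-admin use. Passing tests therefore demonstrate
the management machinery — contracts, atomicity, provenance — not the
correctness of any real indexer, and wall-clock behaviour on huge genomes
is out of scope by design.

## Numerical and operational choices

* Loc parsing reports 1-based line numbers; a malformed loc file fails the
  whole registry load rather than yielding a partially usable registry.
* Problem sizes: the randomized loc round-trip suite uses 500 table/entry
  sets of up to 6 columns × 12 rows; crash-safety is exhaustive over the
  five defined injection stages (`before_invoke`, `after_invoke`,
  `after_parse`, `after_install`, `mid_append`).
* The CLI is single-admin by design: the historical framework restricted
  these operations to an administrator, and the command-line equivalent of
  that boundary is OS file permissions on the config file, data root and
  registry — no application-level authentication is implemented.
* Entry deletion/editing, loc re-sorting, multi-host shared registries,
  packaging/repository integration and remote execution are non-goals.

## Known limitations

* The advisory lock does not protect against external writers editing a
  loc file mid-commit.
* A rerun whose entry row is identical but whose *input file content*
  changed is treated as a duplicate (row-level identity); catching that
  case requires `verify` against the original record.
* `copy_file` installs flat by staged filename; builders needing nested
  layouts should use `copy_dir`.
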