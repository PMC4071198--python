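# refstash

A declarative reference-data asset manager for sequence-analysis servers.

Many bioinformatics tools depend on *built-in reference data* — reference
genome FASTA files, short-read aligner indexes, BLAST databases — located
through registry tables persisted as tab-separated **location (".loc")
files**. Keeping that cache correct has traditionally been a manual chore:
download a genome, run the indexer by hand, paste a line into
`bwa_indexes.loc`, restart the server, and hope nothing was mistyped — with
no record of what was done. Silent errors here corrupt every downstream
analysis that trusts the registry.

refstash replaces that workflow for a single-admin installation:

* **Recipes** declare, in one YAML document, a builder's parameters, its
  command (a subprocess token list or an in-process builtin), the data
  tables it may write, and how raw values are finalized.
* The **engine** runs a recipe in a private staging directory, talking to it
  only through a JSON contract: `params.json` in, `entries.json` out. The
  builder never touches a loc file.
* **Value translations** rewrite raw values (typically a file basename like
  `genome_build.fa`) into finalized ones — by default the installed path
  `${data_root}/${table}/${value}/${raw}` — while ID, dbkey and display
  text pass through verbatim.
* The **registry** commits new rows atomically (write-temp-then-rename under
  an advisory lock, strictly appending to the original bytes) and the rows
  are queryable the moment the run returns — no restart, yet persisted.
* **Provenance**: every run leaves an append-only JSON record with the
  normalized parameters, recipe version, captured log and a sha256 manifest
  of every installed file. Records support `verify` (pinpoint any corrupted
  file or deleted loc line) and `replay` (rebuild into a fresh data root and
  compare digests and entries, factoring out the host-specific prefix).
* Any failure at any stage rolls back completely: installed files deleted,
  loc files rewound byte-for-byte, and a terminal `failed`/`rolled_back`
  record persisted.

Everything is exercisable offline: the `fixtures` module generates seeded
synthetic FASTA genomes and ships toy recipes (a local-FASTA fetcher and a
deterministic toy indexer that derives per-sequence lengths and a digest),
available both as builtins and as equivalent subprocess scripts.

## Worked example

```sh
python - <<'EOF'
import refstash as rs
from pathlib import Path
rs.write_fixture_workspace(Path("ws"))
rs.make_fasta(rs.SyntheticGenomeSpec(seed=7, n_sequences=2, length=120), "hg19.fa")
EOF
export REFSTASH_CONFIG=ws/refstash.yaml

refstash run fetch_local_fasta --param dbkey=hg19 \
    --param "name=Human hg19" --param fasta=hg19.fa
refstash run toy_index --param dbkey=hg19 --param fasta=hg19.fa
```

which prints one line per run:

```
20260929T071021.679628-0000-701857: 1 entry added
20260929T071021.915070-0000-8bfa16: 1 entry added
```

Each run registered one entry — the first into `all_fasta` (the genome),
the second into `toy_indexes` (the index). The registry is live immediately:

```
$ refstash entries toy_indexes
hg19	hg19	hg19 toy index (small)	/tmp/demo/ws/data/toy_indexes/hg19/hg19.fa
```

The four columns are the entry ID (`value`), the genome-build key
(`dbkey`), the display text — `(small)` records that the indexer's `auto`
algorithm choice resolved to `small` for this 240-base genome — and the
finalized installed path. The same line is already persisted in
`ws/registry/toy_indexes.loc`. Verifying the index run recomputes every
installed file's sha256 and re-queries the committed row:

```
$ refstash verify 20260929T071021.915070-0000-8bfa16
file toy_indexes/hg19/hg19.fa: ok
file toy_indexes/hg19/hg19.fa.sizes: ok
file toy_indexes/hg19/hg19.fa.sum: ok
entry toy_indexes/hg19: present
PASS
```

and replaying it into a fresh data root rebuilds it and confirms fidelity:

```
$ refstash replay 20260929T071021.915070-0000-8bfa16 --data-root fresh_data
replayed as 20260929T071023.279869-0000-016e36
entries match: True
digests match: True
```

The same pipeline is available as a library (`rs.run_recipe`,
`rs.verify_run`, `rs.replay_run`, ...); see `docs/methods.md` for the data
model and design notes, and `docs/schemas/` for the JSON contracts.

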