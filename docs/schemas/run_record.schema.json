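{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "refstash run record",
  "description": "One provenance document per run, stored append-only under <provenance_root>/runs/<run_id>.json.",
  "type": "object",
  "required": ["run_id", "recipe_id", "recipe_version", "bindings", "started",
               "finished", "status", "data_root", "raw_bundle",
               "final_entries", "added_counts", "manifest", "log"],
  "properties": {
    "run_id": {"type": "string", "description": "Unique, lexicographically time-sortable id."},
    "recipe_id": {"type": "string"},
    "recipe_version": {"type": "string"},
    "bindings": {"type": "object", "description": "Normalized parameter bindings as executed."},
    "started": {"type": "string", "description": "RFC-3339 UTC timestamp."},
    "finished": {"type": "string", "description": "RFC-3339 UTC timestamp."},
    "status": {"enum": ["succeeded", "failed", "rolled_back"]},
    "data_root": {"type": "string", "description": "Data root the run committed into (host-specific; replay comparison factors it out)."},
    "raw_bundle": {
      "description": "The entries.json document as received from the tool, or null if the run failed before producing one.",
      "type": ["object", "null"]
    },
    "final_entries": {
      "type": "object",
      "description": "Table name -> finalized entries as committed (empty unless status is succeeded)."
    },
    "added_counts": {
      "type": "object",
      "description": "Table name -> number of rows actually added (full-row duplicates are skipped and not counted).",
      "additionalProperties": {"type": "integer"}
    },
    "manifest": {
      "type": "array",
      "description": "sha256 manifest of every installed file; present only on succeeded runs.",
      "items": {
        "type": "object",
        "required": ["relpath", "size", "sha256"],
        "properties": {
          "relpath": {"type": "string", "description": "Path relative to data_root; never contains '..'."},
          "size": {"type": "integer"},
          "sha256": {"type": "string", "pattern": "^[0-9a-f]{64}$"}
        }
      }
    },
    "log": {"type": "string", "description": "Captured stdout+stderr of the execution plus engine messages."}
  }
}
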