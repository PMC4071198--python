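{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "refstash params.json",
  "description": "The parameter/settings bundle the engine writes into the staging directory for the recipe executable (its path is also appended as the command's final token).",
  "type": "object",
  "required": ["params", "staging_dir", "settings"],
  "properties": {
    "params": {
      "type": "object",
      "description": "Normalized parameter bindings: text/choice as strings, integers as numbers, booleans as booleans, input paths as absolute path strings.",
      "additionalProperties": {"type": ["string", "integer", "boolean"]}
    },
    "staging_dir": {
      "type": "string",
      "description": "Absolute path of this run's private staging directory (also the working directory of subprocess recipes)."
    },
    "settings": {
      "type": "object",
      "required": ["data_root"],
      "properties": {
        "data_root": {
          "type": "string",
          "description": "Absolute path of the permanent managed data store."
        }
      }
    }
  },
  "additionalProperties": false
}
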