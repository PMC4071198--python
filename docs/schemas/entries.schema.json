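{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "refstash entries.json",
  "description": "The entry bundle a recipe executable writes into the staging directory: raw entries for any number of the recipe's declared output tables. Values are raw (typically file basenames); declared value translations finalize them.",
  "type": "object",
  "required": ["data_tables"],
  "properties": {
    "data_tables": {
      "type": "object",
      "description": "Table name -> list of raw entries. Every named table must be declared by the recipe's outputs; lists may be empty.",
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "object",
          "description": "One raw entry: flat mapping of column name to string value. The target table's key column (conventionally 'value') is required.",
          "additionalProperties": {"type": "string"}
        }
      }
    }
  },
  "additionalProperties": false
}
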