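{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "tieraudit panel file",
 "description": "A panel file is a JSON array of panel documents, one per (panel_id, version_tag) snapshot.",
 "type": "array",
 "items": {
  "type": "object",
  "required": ["panel_id", "version_tag", "entries"],
  "properties": {
   "panel_id": {"type": "string", "minLength": 1},
   "version_tag": {"enum": ["original", "updated"]},
   "entries": {
    "type": "array",
    "items": {
     "type": "object",
     "required": ["gene", "rating"],
     "properties": {
      "gene": {"type": "string", "minLength": 1},
      "rating": {"enum": ["green", "amber", "red"]},
      "moi": {"enum": ["monoallelic", "biallelic", "x_linked", "both"]}
     }
    }
   }
  }
 }
}
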