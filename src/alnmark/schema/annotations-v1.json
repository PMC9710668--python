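{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "alnmark/annotations-v1",
  "title": "alnmark annotation document, version 1",
  "description": "Variants, modifications and interval regions bound to the sequences of an alignment. Positions are 1-based UNGAPPED coordinates of the referenced sequence (the numbering HGVS-style tokens use); region start/end are alignment columns when no sequence is given.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "variants": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["sequence", "position"],
        "properties": {
          "sequence": {"description": "record index (0-based integer) or header label", "type": ["integer", "string"]},
          "position": {"description": "1-based ungapped residue/nucleotide position", "type": "integer", "minimum": 1},
          "token": {"description": "optional HGVS-like change token, e.g. p.C4957Y or c.88C>G", "type": "string"},
          "source": {"description": "provenance, e.g. ClinVar", "type": "string"},
          "note": {"description": "free text or HTML fragment shown in the pop-up", "type": "string"},
          "id": {"description": "variant identifier, e.g. rs121912606", "type": "string"},
          "url": {"description": "cross-reference link", "type": "string"}
        },
        "additionalProperties": {"description": "extra keys (allele frequency, clinical significance, ...) are preserved and shown in the pop-up"}
      }
    },
    "modifications": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["sequence", "position"],
        "properties": {
          "sequence": {"type": ["integer", "string"]},
          "position": {"type": "integer", "minimum": 1},
          "type": {"description": "modification kind, e.g. ubiquitination", "type": "string"},
          "note": {"type": "string"},
          "url": {"type": "string"}
        },
        "additionalProperties": true
      }
    },
    "regions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["start", "end"],
        "properties": {
          "sequence": {"description": "omit (or null) for a global region in alignment-column space", "type": ["integer", "string", "null"]},
          "start": {"type": "integer", "minimum": 1},
          "end": {"type": "integer", "minimum": 1},
          "label": {"type": "string"},
          "color": {"description": "CSS colour", "type": "string"},
          "url": {"type": "string"}
        },
        "additionalProperties": true
      }
    }
  }
}
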