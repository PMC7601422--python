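{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://fairsheet.readthedocs.io/schemas/isa-nanomaterial-extension.json",
  "title": "ISA-JSON nanomaterial material extension (synthetic reconstruction)",
  "description": "Synthetic reconstruction of a nanomaterial material-extension schema for ISA-JSON v1: a source material may carry a list of components, each with a role in the composition (core, coating, functionalisation, main constituent, impurity, additive) and linkages describing relations to other components (e.g. covalently bonded, embedded, encapsulated). Built from the published textual description only; not the original schema document.",
  "type": "object",
  "properties": {
    "@id": {"type": "string"},
    "name": {"type": "string"},
    "type": {"type": "string"},
    "characteristics": {
      "type": "array",
      "items": {
        "type": "object",
        "properties": {
          "category": {"$ref": "#/$defs/annotation"},
          "value": {"$ref": "#/$defs/annotation"}
        },
        "required": ["category", "value"]
      }
    },
    "components": {
      "type": "array",
      "items": {"$ref": "#/$defs/component"}
    }
  },
  "required": ["@id", "name"],
  "$defs": {
    "annotation": {
      "type": "object",
      "properties": {
        "annotationValue": {},
        "termSource": {"type": "string"},
        "termAccession": {"type": "string"}
      },
      "required": ["annotationValue"]
    },
    "component": {
      "type": "object",
      "properties": {
        "@id": {"type": "string"},
        "role": {
          "enum": [
            "main constituent",
            "impurity",
            "additive",
            "core",
            "coating",
            "functionalisation",
            "other"
          ]
        },
        "name": {"type": "string"},
        "structure": {"type": "string"},
        "linkages": {
          "type": "array",
          "items": {
            "type": "object",
            "properties": {
              "source": {"type": "string"},
              "target": {"type": "string"},
              "relation": {"type": "string"}
            },
            "required": ["source", "target", "relation"]
          }
        }
      },
      "required": ["@id", "role"]
    }
  }
}
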