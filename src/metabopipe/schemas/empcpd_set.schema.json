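{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Empirical compound set",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["interim_id", "charge_sign", "MS1_pseudo_Spectra", "MS2_Spectra", "annotations"],
    "properties": {
      "interim_id": {"type": "string"},
      "neutral_formula": {"type": ["string", "null"]},
      "neutral_formula_mass": {"type": ["number", "null"], "description": "Da"},
      "charge_sign": {"enum": [1, -1]},
      "MS1_pseudo_Spectra": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["feature_id", "isotope", "modification"],
          "properties": {
            "feature_id": {"type": "string"},
            "isotope": {"type": "string"},
            "modification": {"type": "string"},
            "mz": {"type": ["number", "null"]},
            "rtime": {"type": ["number", "null"], "description": "seconds"},
            "charge": {"type": "integer", "minimum": 1}
          }
        }
      },
      "MS2_Spectra": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["ms_level", "peaks"],
          "properties": {
            "ms_level": {"type": "integer", "minimum": 1},
            "precursor_mz": {"type": ["number", "null"]},
            "retention_time": {"type": ["number", "null"]},
            "source_acquisition": {"type": ["string", "null"]},
            "peaks": {
              "type": "array",
              "items": {
                "type": "array",
                "prefixItems": [{"type": "number"}, {"type": "number", "minimum": 0}],
                "minItems": 2,
                "maxItems": 2
              }
            }
          }
        }
      },
      "annotations": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["level", "compound_name", "source"],
          "properties": {
            "level": {"enum": ["1a", "1b", "2", "4"]},
            "compound_name": {"type": "string"},
            "identifiers": {"type": "object"},
            "score": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
            "source": {"type": "string"},
            "evidence": {"type": "object"}
          }
        }
      }
    }
  }
}
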