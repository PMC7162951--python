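{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "varsieve cascade report",
  "type": "object",
  "required": ["ledger", "candidates", "summary"],
  "properties": {
    "ledger": {
      "type": "object",
      "required": ["steps"],
      "properties": {
        "steps": {
          "type": "array",
          "items": {
            "type": "object",
            "required": [
              "name",
              "variants_in",
              "variants_removed",
              "variants_kept",
              "genes_in",
              "genes_kept"
            ],
            "properties": {
              "name": {"type": "string"},
              "variants_in": {"type": "integer", "minimum": 0},
              "variants_removed": {"type": "integer", "minimum": 0},
              "variants_kept": {"type": "integer", "minimum": 0},
              "genes_in": {"type": "integer", "minimum": 0},
              "genes_kept": {"type": "integer", "minimum": 0},
              "detail": {"type": "object"}
            }
          }
        }
      }
    },
    "candidates": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["key", "contig", "pos", "ref", "alt", "zygosity", "mode", "genes"],
        "properties": {
          "key": {"type": "string"},
          "contig": {"type": "string"},
          "pos": {"type": "integer", "minimum": 1},
          "ref": {"type": "string"},
          "alt": {"type": "string"},
          "zygosity": {"type": "string"},
          "mode": {"type": "string", "enum": ["homozygous", "compound_het"]},
          "phase": {"type": "string"},
          "genes": {"type": "array", "items": {"type": "string"}},
          "gene_symbols": {"type": "array", "items": {"type": "string"}},
          "hgvs_g": {"type": "string"},
          "hgvs_c": {"type": ["string", "null"]},
          "category": {"type": ["string", "null"]},
          "impact_tier": {"type": ["string", "null"]},
          "wt_protein_length": {"type": "integer", "minimum": 0},
          "mut_protein_length": {"type": "integer", "minimum": 0},
          "first_divergent_residue": {"type": "integer", "minimum": 0}
        }
      }
    },
    "summary": {
      "type": "object",
      "required": ["n_candidates"],
      "properties": {
        "n_candidates": {"type": "integer", "minimum": 0},
        "candidate_genes": {"type": "array", "items": {"type": "string"}},
        "compound_het_genes": {"type": "array", "items": {"type": "string"}}
      }
    }
  }
}
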