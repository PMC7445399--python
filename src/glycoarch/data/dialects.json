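{
  "comment": "Residue/atom naming dialects. resnames maps ensemble residue labels to the controlled monosaccharide vocabulary. The GLYCAM table is a representative subset of the linkage-coded three-character residue names; atom names are shared between dialects apart from the listed synonyms.",
  "dialects": {
    "pdb-ccd": {
      "resnames": {
        "NAG": "GlcNAc", "NDG": "GlcNAc",
        "MAN": "Man", "BMA": "Man",
        "GAL": "Gal", "GLA": "Gal",
        "FUC": "Fuc", "FUL": "Fuc",
        "XYS": "Xyl", "XYP": "Xyl",
        "GLC": "Glc", "BGC": "Glc",
        "SIA": "Sia"
      },
      "atom_synonyms": {}
    },
    "glycam": {
      "resnames": {
        "0YB": "GlcNAc", "2YB": "GlcNAc", "3YB": "GlcNAc", "4YB": "GlcNAc", "6YB": "GlcNAc", "WYB": "GlcNAc", "VYB": "GlcNAc",
        "0MA": "Man", "2MA": "Man", "3MA": "Man", "4MB": "Man", "6MA": "Man", "VMB": "Man", "WMB": "Man", "YMB": "Man", "0MB": "Man", "3MB": "Man",
        "0LB": "Gal", "3LB": "Gal", "4LB": "Gal",
        "0FA": "Fuc", "0fA": "Fuc",
        "0XB": "Xyl", "2XB": "Xyl",
        "0GB": "Glc", "4GB": "Glc",
        "0SA": "Sia"
      },
      "atom_synonyms": {"O2N": "O2", "C2N": "C2"}
    },
    "custom": {
      "resnames": {},
      "atom_synonyms": {}
    }
  }
}
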