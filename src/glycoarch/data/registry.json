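{
  "comment": "Shorthand glycoform registry. Sequences are condensed IUPAC-like text, child-to-parent left to right, root = reducing-end GlcNAc. reference_populations are annotation metadata from microsecond-scale MD characterisations of these glycoforms; they are carried for reporting only and are never recomputed by this package. ambiguity notes flag residue-level details that figure captions left open.",
  "glycoforms": [
    {
      "name": "ng",
      "description": "Plant-type biantennary core, arms terminating in GlcNAc-b(1-2); no Fuc, no Xyl, no Gal.",
      "sequence": "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
      "family": "plant",
      "reference_populations": {},
      "ambiguity": ""
    },
    {
      "name": "g",
      "description": "Plant-type biantennary, both arms terminating in Gal-b(1-3).",
      "sequence": "Gal(b1-3)GlcNAc(b1-2)Man(a1-3)[Gal(b1-3)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
      "family": "plant",
      "reference_populations": {},
      "ambiguity": ""
    },
    {
      "name": "ngf",
      "description": "ng plus core Fuc-a(1-3) on the reducing-end GlcNAc.",
      "sequence": "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-3)]GlcNAc",
      "family": "plant",
      "reference_populations": {"arm16_open_pct": 66.0, "arm16_folded_pct": 34.0},
      "ambiguity": ""
    },
    {
      "name": "gf",
      "description": "g plus core Fuc-a(1-3).",
      "sequence": "Gal(b1-3)GlcNAc(b1-2)Man(a1-3)[Gal(b1-3)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-3)]GlcNAc",
      "family": "plant",
      "reference_populations": {"arm16_open_pct": 72.0},
      "ambiguity": ""
    },
    {
      "name": "ngx",
      "description": "ng plus Xyl-b(1-2) on the central beta-Man.",
      "sequence": "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
      "family": "plant",
      "reference_populations": {"xyl_ring_1C4_pct": 76.0},
      "ambiguity": ""
    },
    {
      "name": "gx",
      "description": "g plus Xyl-b(1-2) on the central beta-Man.",
      "sequence": "Gal(b1-3)GlcNAc(b1-2)Man(a1-3)[Gal(b1-3)GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
      "family": "plant",
      "reference_populations": {},
      "ambiguity": ""
    },
    {
      "name": "ngfx",
      "description": "ng plus core Fuc-a(1-3) and Xyl-b(1-2): the doubly modified plant core.",
      "sequence": "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-3)]GlcNAc",
      "family": "plant",
      "reference_populations": {"rotated_trimannose_pct_lower_bound": 20.0},
      "ambiguity": ""
    },
    {
      "name": "gfx",
      "description": "g plus core Fuc-a(1-3) and Xyl-b(1-2); fully decorated plant glycoform.",
      "sequence": "Gal(b1-3)GlcNAc(b1-2)Man(a1-3)[Gal(b1-3)GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-3)]GlcNAc",
      "family": "plant",
      "reference_populations": {"arm16_open_pct": 87.0, "rotated_trimannose_pct": 5.0},
      "ambiguity": ""
    },
    {
      "name": "lea",
      "description": "Plant glycoform with Lewis A termini (Gal-b(1-3)[Fuc-a(1-4)]GlcNAc) on both arms, core Fuc-a(1-3) and Xyl-b(1-2).",
      "sequence": "Gal(b1-3)[Fuc(a1-4)]GlcNAc(b1-2)Man(a1-3)[Gal(b1-3)[Fuc(a1-4)]GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-3)]GlcNAc",
      "family": "plant",
      "reference_populations": {},
      "ambiguity": "Arm-terminus detail inferred from the Lewis A motif definition; the source figures do not print the full condensed sequence."
    },
    {
      "name": "lex",
      "description": "Same scaffold as lea but Lewis X termini (Gal-b(1-4)[Fuc-a(1-3)]GlcNAc); schistosome-type, built for arm-symmetry comparison.",
      "sequence": "Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-3)]GlcNAc",
      "family": "hybrid",
      "reference_populations": {"arm16_open_pct": 90.0},
      "ambiguity": "Arm-terminus detail inferred from the Lewis X motif definition."
    },
    {
      "name": "xA2G2",
      "description": "Mammalian A2G2 (arms Gal-b(1-4)GlcNAc-b(1-2)) plus Xyl-b(1-2); hybrid construct.",
      "sequence": "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
      "family": "hybrid",
      "reference_populations": {"arm16_closed_pct": 57.0, "arm16_closed_pct_without_xyl": 74.0},
      "ambiguity": ""
    },
    {
      "name": "xFA2G2",
      "description": "xA2G2 plus core Fuc-a(1-6); schistosome-type xylosylated FA2G2.",
      "sequence": "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc",
      "family": "hybrid",
      "reference_populations": {"arm16_closed_pct": 70.0},
      "ambiguity": ""
    },
    {
      "name": "xFA2",
      "description": "Xylosylated FA2: GlcNAc-terminated arms, Xyl-b(1-2), core Fuc-a(1-6).",
      "sequence": "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)][Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc",
      "family": "hybrid",
      "reference_populations": {},
      "ambiguity": "Narrative direction for this form is ambiguous in the source discussion (compared to xA2G2 despite lacking terminal Gal); the rule base reports the Xyl-driven open bias and flags the comparison in the trace."
    },
    {
      "name": "f3FA2G2",
      "description": "Double-core-fucose A2G2: Fuc-a(1-3) and Fuc-a(1-6) on the reducing-end GlcNAc, arms Gal-b(1-4)-terminated; worm/fly-type glycosylation.",
      "sequence": "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)][Fuc(a1-3)]GlcNAc",
      "family": "hybrid",
      "reference_populations": {"arm16_closed_pct": 85.0, "glcnac_ring_flip_pct": 18.0},
      "ambiguity": ""
    }
  ]
}
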