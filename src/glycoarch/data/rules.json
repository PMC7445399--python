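{
  "comment": "Sequence-to-propensity rule base over glycoblock decompositions. Each rule carries an evidence sentence (the package's summary of the structural finding it encodes) and reference_populations: percentages from microsecond-MD characterisations, carried as annotation metadata only and never recomputed at analysis time. priority resolves conflicts (highest fired rule that sets the arm state wins; conflicts are logged in the trace).",
  "rules": [
    {
      "id": "R1",
      "priority": 10,
      "requires": {"chitobiose_modifiers_include": ["Fuc_a1_3"]},
      "effects": {
        "arm_1_6": "open_dominant",
        "chitobiose_psi_shift_deg": -20.0,
        "notes": ["core a(1-3)-Fuc stacks onto the chitobiose b(1-4)-GlcNAc, rotating the GlcNAc-b(1-4)-GlcNAc psi by about 20 degrees from its unmodified mode near -127.8 (14.8) and biasing the (1-6) arm open"]
      },
      "evidence": "Core a(1-3)-fucose locks one chitobiose conformer and imposes a ~20 degree psi rotation of the GlcNAc-b(1-4)-GlcNAc linkage; with b(1-3)-Gal or GlcNAc arm termini this pushes the (1-6)-arm equilibrium towards the outstretched (open) conformation.",
      "reference_populations": {"arm16_open_pct_ngf": 66.0, "arm16_open_pct_gf": 72.0, "chitobiose_psi_unmodified_deg": -127.8, "chitobiose_psi_unmodified_sd_deg": 14.8}
    },
    {
      "id": "R2",
      "priority": 10,
      "requires": {"trimannose_modifiers_include": ["Xyl_b1_2"]},
      "effects": {
        "arm_1_6": "open_dominant",
        "front_fold_blocked": true,
        "arm_1_3_restrained": true,
        "notes": ["b(1-2)-Xyl sits in front of the two arms: steric hindrance blocks the front fold of the (1-6) arm and rigidifies the (1-3) arm, removing its two-conformer exchange"]
      },
      "evidence": "b(1-2)-xylose on the central mannose sterically blocks the front fold of the (1-6) arm and restrains the (1-3) arm, biasing the equilibrium open; its ring also exchanges into the all-axial inverted chair.",
      "reference_populations": {"xyl_ring_1C4_pct": 76.0}
    },
    {
      "id": "R3",
      "priority": 30,
      "requires": {"arm16_terminus": "Gal_1_4", "chitobiose_modifiers_include": ["Fuc_a1_6"]},
      "effects": {
        "arm_1_6": "closed_dominant",
        "notes": ["a(1-6)-Fuc stacks the terminal b(1-4)-Gal of the folded arm while Xyl (when present) hydrogen-bonds it: the closed (1-6) arm becomes the top conformer"]
      },
      "evidence": "With a b(1-4)-Gal-terminated (1-6) arm, core a(1-6)-fucose stabilises the folded arm by stacking the terminal galactose; the closed conformer dominates, overriding any open bias from a(1-3)-Fuc or Xyl.",
      "reference_populations": {"arm16_closed_pct_xylosylated": 70.0, "arm16_closed_pct_double_fucose": 85.0}
    },
    {
      "id": "R4",
      "priority": 20,
      "requires": {"arm16_terminus": "Gal_1_4", "chitobiose_modifiers_exclude": ["Fuc_a1_6"], "trimannose_modifiers_exclude": ["Xyl_b1_2"]},
      "effects": {
        "arm_1_6": "mixed",
        "notes": ["b(1-4)-Gal termini favour folding over the chitobiose by stacking; without a(1-6)-Fuc or Xyl the closed form leads but does not lock"]
      },
      "evidence": "A b(1-4)-Gal-terminated (1-6) arm folds over the chitobiose by stacking; without core a(1-6)-Fuc the equilibrium is closed-leaning mixed.",
      "reference_populations": {"arm16_closed_pct": 74.0}
    },
    {
      "id": "R4x",
      "priority": 20,
      "requires": {"arm16_terminus": "Gal_1_4", "chitobiose_modifiers_exclude": ["Fuc_a1_6"], "trimannose_modifiers_include": ["Xyl_b1_2"]},
      "effects": {
        "arm_1_6": "mixed",
        "notes": ["Xyl hinders but does not prevent folding of a b(1-4)-Gal arm; the folded mode is distorted about 20 degrees in psi and reduced, yet remains the leading form"]
      },
      "evidence": "b(1-2)-xylose hinders but does not prevent the b(1-4)-Gal (1-6) arm from folding; the closed form is distorted (median psi 103.5 vs 82.9 unxylosylated) and reduced from 74 to 57 percent, a closed-leaning mixed equilibrium.",
      "reference_populations": {"arm16_closed_pct": 57.0, "folded_psi_median_deg": 103.5, "folded_psi_unxylosylated_deg": 82.9}
    },
    {
      "id": "R5",
      "priority": 40,
      "requires": {"both_arms_terminus": "LeA"},
      "effects": {
        "arm_1_6": "restrained_interacting",
        "notes": ["LeA branching (a(1-4)-Fuc + b(1-3)-Gal on the arm GlcNAc) enables an inter-arm hydrogen-bond network, restraining the (1-6) arm in otherwise unpopulated conformations"]
      },
      "evidence": "Lewis A termini promote a stable interaction between the two arms through hydrogen-bond networks (possibly involving the central xylose); the (1-6) arm is restrained in conformations not significantly populated otherwise.",
      "reference_populations": {}
    },
    {
      "id": "R6",
      "priority": 40,
      "requires": {"both_arms_terminus": "LeX"},
      "effects": {
        "arm_1_6": "open_dominant",
        "notes": ["LeX termini cannot form the LeA-type inter-arm network (non-complementary fucose deoxy-C6): the arms do not interact and the (1-6) arm is predominantly extended"]
      },
      "evidence": "With Lewis X termini the arms do not interact and the (1-6) arm is predominantly extended (open); the residual closed form goes through rotation about the core Man-b(1-4)-GlcNAc.",
      "reference_populations": {"arm16_open_pct": 90.0}
    },
    {
      "id": "R7",
      "priority": 15,
      "requires": {"arm16_terminus": "Gal_1_3", "any_fired": ["R1", "R2"]},
      "effects": {
        "arm_1_6": "open_dominant",
        "notes": ["terminal b(1-3)-Gal adds to the a(1-3)-Fuc/Xyl open bias: the outstretched arm is reinforced"]
      },
      "evidence": "Terminal b(1-3)-Gal pushes the a(1-3)-fucosylated or xylosylated (1-6)-arm equilibrium further open; with both modifications the open form is strongest.",
      "reference_populations": {"arm16_open_pct_gf": 72.0, "arm16_open_pct_gfx": 87.0}
    },
    {
      "id": "R8",
      "priority": 25,
      "requires": {"chitobiose_modifiers_include": ["Fuc_a1_3"], "trimannose_modifiers_include": ["Xyl_b1_2"], "arm16_terminus": "GlcNAc"},
      "effects": {
        "rotated_core_enhanced": true,
        "notes": ["with both a(1-3)-Fuc and Xyl and bare GlcNAc arms, the core Man-b(1-4)-GlcNAc linkage loosens and the rotated-trimannose conformer becomes significantly populated (synergistic effect)"]
      },
      "evidence": "a(1-3)-Fuc and b(1-2)-Xyl together loosen the core Man-b(1-4)-GlcNAc linkage: the rotated-trimannose conformer, around 2 percent with either modification alone, exceeds 20 percent with both (about 5 percent when the arms carry b(1-3)-Gal).",
      "reference_populations": {"rotated_trimannose_pct_lower_bound": 20.0, "rotated_trimannose_pct_single_modification": 2.0, "rotated_trimannose_pct_galactosylated": 5.0}
    },
    {
      "id": "R0",
      "priority": 0,
      "requires": {},
      "effects": {
        "arm_1_6": "mixed",
        "notes": ["unmodified biantennary scaffold: the (1-6) arm exchanges between outstretched and folded conformers (open-leaning for bare or b(1-2)-GlcNAc-terminated arms)"]
      },
      "evidence": "Without core modifications the (1-6) arm of a biantennary scaffold exchanges between open and folded conformers; functionalisation of the arm progressively depopulates the open form.",
      "reference_populations": {"arm16_open_pct_man3": 85.0, "arm16_open_pct_a2": 52.0, "arm16_open_pct_gal_1_4_terminated": 24.0}
    }
  ]
}
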