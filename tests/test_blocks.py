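"""Glycoblock decomposition and the propensity rule engine."""

from collections import Counter

import pytest

from glycoarch import model
from glycoarch.blocks import (
    DecompositionError,
    Glycoblock,
    compare_decompositions,
    decompose,
    predict_propensity,
)

ALL_GLYCOFORMS = [
    "ng", "g", "ngf", "gf", "ngx", "gx", "ngfx", "gfx",
    "lea", "lex", "xA2G2", "xFA2G2", "xFA2", "f3FA2G2",
]


class TestDecomposition:
    @pytest.mark.parametrize("name", ALL_GLYCOFORMS)
    def test_partition_covers_all_residues_exactly_once(self, name):
        tree = model.parse_glycan(name)
        blocks = decompose(tree)
        members = [m for b in blocks for m in b.members]
        assert sorted(members) == sorted(tree.nodes)
        assert len(members) == len(set(members))

    def test_man3_core_decomposition(self):
        blocks = decompose("Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc")
        assert [b.signature for b in blocks] == ["chitobiose_core", "trimannose_core"]

    def test_gfx_block_multiset(self):
        sigs = Counter(b.signature for b in decompose(model.parse_glycan("gfx")))
        assert sigs == {
            "chitobiose_core{Fuc_a1_3}": 1,
            "trimannose_core{Xyl_b1_2}": 1,
            "arm_GlcNAc": 2,
            "terminal_Gal_1_3": 2,
        }

    def test_lea_has_two_lewis_a_termini(self):
        blocks = decompose(model.parse_glycan("lea"))
        lea = [b for b in blocks if b.block_type == "LeA_terminus"]
        assert len(lea) == 2
        assert all(len(b.members) == 3 for b in lea)
        assert {b.arm for b in lea} == {"1-3", "1-6"}

    def test_double_fucose_modifiers(self):
        blocks = decompose(model.parse_glycan("f3FA2G2"))
        chito = next(b for b in blocks if b.block_type == "chitobiose_core")
        assert chito.modifiers == ("Fuc_a1_3", "Fuc_a1_6")

    def test_tree_without_core_is_an_error(self):
        with pytest.raises(DecompositionError, match="chitobiose|trimannose|rooted"):
            decompose("Gal(b1-4)Glc")

    def test_unassignable_residue_named_in_error(self):
        # Glc on an arm mannose fits no block rule
        text = "Glc(b1-2)Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"
        with pytest.raises(DecompositionError, match="Glc"):
            decompose(text)

    def test_illegal_modifier_attachment_rejected(self):
        with pytest.raises(ValueError, match="cannot attach"):
            Glycoblock(block_type="trimannose_core", members=(1,), modifiers=("Fuc_a1_3",))


EXPECTED_DIRECTION = {
    "ngf": "open_dominant",
    "gf": "open_dominant",
    "ngx": "open_dominant",
    "gx": "open_dominant",
    "ngfx": "open_dominant",
    "gfx": "open_dominant",
    "lex": "open_dominant",
    "xFA2G2": "closed_dominant",
    "f3FA2G2": "closed_dominant",
    "lea": "restrained_interacting",
    "ng": "mixed",
    "g": "mixed",
    "xA2G2": "mixed",
}


class TestPropensity:
    @pytest.mark.parametrize("name,direction", sorted(EXPECTED_DIRECTION.items()))
    def test_arm_direction_matches_narrative(self, name, direction):
        report = predict_propensity(decompose(model.parse_glycan(name)))
        assert report.arm_1_6 == direction

    def test_every_prediction_cites_a_fired_rule(self):
        for name in ALL_GLYCOFORMS:
            report = predict_propensity(decompose(model.parse_glycan(name)))
            assert report.trace, name
            for entry in report.trace:
                assert entry["evidence"].strip()

    def test_core_fucose_shifts_chitobiose_psi(self):
        shifted = predict_propensity(decompose(model.parse_glycan("ngf")))
        assert shifted.chitobiose_psi_shift == pytest.approx(-20.0)
        plain = predict_propensity(decompose(model.parse_glycan("ng")))
        assert plain.chitobiose_psi_shift == pytest.approx(0.0)

    def test_gfx_fires_fucose_xylose_and_galactose_rules(self):
        report = predict_propensity(decompose(model.parse_glycan("gfx")))
        assert report.fired() == ["R1", "R2", "R7"]
        assert report.reference_populations["arm16_open_pct_gfx"] == 87.0

    def test_closed_rule_overrides_open_bias(self):
        """Xylosylated FA2G2: the Gal_1_4 + core Fuc_a1_6 rule wins over Xyl."""
        report = predict_propensity(decompose(model.parse_glycan("xFA2G2")))
        assert "R2" in report.fired() and "R3" in report.fired()
        overridden = [t for t in report.trace if t.get("overridden_by")]
        assert any(t["id"] == "R2" for t in overridden)
        assert report.reference_populations["arm16_closed_pct_xylosylated"] == 70.0

    def test_rotated_core_synergy_flagged_for_ngfx_only(self):
        assert "R8" in predict_propensity(decompose(model.parse_glycan("ngfx"))).fired()
        assert "R8" not in predict_propensity(decompose(model.parse_glycan("ngf"))).fired()

    def test_default_rule_for_unmodified_scaffold(self):
        report = predict_propensity(decompose(model.parse_glycan("ng")))
        assert report.fired() == ["R0"]

    def test_reports_are_reproducible(self):
        a = predict_propensity(decompose(model.parse_glycan("lea")))
        b = predict_propensity(decompose(model.parse_glycan("lea")))
        assert a.trace == b.trace and a.arm_1_6 == b.arm_1_6

    def test_reference_populations_are_metadata_only(self):
        """Reference percentages come from the rule base verbatim, not computation."""
        report = predict_propensity(decompose(model.parse_glycan("lex"))
        )
        assert report.reference_populations.get("arm16_open_pct") == 90.0


class TestComparison:
    def test_xylose_shows_as_modifier_diff(self):
        diff = compare_decompositions(
            model.parse_glycan("ng"), model.parse_glycan("ngx")
        )
        assert diff["modified"] == [
            {
                "block_type": "trimannose_core",
                "modifiers_removed": [],
                "modifiers_added": ["Xyl_b1_2"],
            }
        ]

    def test_self_comparison_is_identical(self):
        tree = model.parse_glycan("gfx")
        assert compare_decompositions(tree, tree)["identical"]

    def test_galactosylation_adds_terminal_blocks(self):
        diff = compare_decompositions(
            model.parse_glycan("ngf"), model.parse_glycan("gf")
        )
        assert {"block_type": "terminal_Gal_1_3", "count": 2} in diff["added"]
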