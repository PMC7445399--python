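"""Synthetic generators: determinism, ground truth, construction precision."""

import numpy as np
import pytest

from glycoarch import io, model, synth, torsions
from glycoarch.circular import wrap_degrees
from glycoarch.synth import EnsembleSpec, sample_state_sequence, sample_torsion_mixture


def spec_of(components, n=1000, seed=0, dims=None, fragment=""):
    dims = dims or ["phi"] * 0 or [f"d{i}" for i in range(len(components[0]["mean"]))]
    return EnsembleSpec(
        dimensions=dims, components=components, n_frames=n, seed=seed, fragment=fragment
    )


class TestMixtureSampler:
    def test_identical_seeds_are_byte_identical(self):
        s = spec_of([{"mean": [30.0, -30.0], "kappa": 20.0, "weight": 1.0}], seed=5)
        a, b = sample_torsion_mixture(s), sample_torsion_mixture(s)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_changes_data(self):
        comps = [{"mean": [30.0], "kappa": 20.0, "weight": 1.0}]
        a = sample_torsion_mixture(spec_of(comps, seed=1))
        b = sample_torsion_mixture(spec_of(comps, seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_large_kappa_limit(self):
        """kappa -> infinity collapses the distribution onto the mean: at
        kappa = 1e6 the angular SD is 1/sqrt(kappa) rad (~0.057 deg), so the
        sample SD stays below 0.1 deg and every draw lies within 0.5 deg."""
        s = spec_of([{"mean": [-120.0], "kappa": 1e6, "weight": 1.0}], n=2000)
        out = sample_torsion_mixture(s)
        dev = np.abs(wrap_degrees(out.values - (-120.0)))
        assert dev.max() < 0.5
        assert dev.std() < 0.1

    def test_empirical_weights_within_binomial_error(self):
        comps = [
            {"mean": [0.0], "kappa": 30.0, "weight": 0.6},
            {"mean": [120.0], "kappa": 30.0, "weight": 0.4},
        ]
        out = sample_torsion_mixture(spec_of(comps, n=10_000, seed=3))
        se = np.sqrt(0.6 * 0.4 / 10_000)
        assert abs(out.true_weights()[0] - 0.6) <= 3 * se

    @pytest.mark.parametrize(
        "bad",
        [
            dict(components=[{"mean": [0.0], "kappa": 10.0, "weight": 0.5}]),
            dict(components=[{"mean": [0.0], "kappa": -1.0, "weight": 1.0}]),
            dict(components=[{"mean": [0.0, 1.0], "kappa": 10.0, "weight": 1.0}]),
            dict(n=0, components=[{"mean": [0.0], "kappa": 10.0, "weight": 1.0}]),
        ],
    )
    def test_invalid_specs_enumerated(self, bad):
        n = bad.pop("n", 10)
        with pytest.raises(ValueError, match="invalid ensemble spec"):
            EnsembleSpec(
                dimensions=["d0"], components=bad["components"], n_frames=n, seed=0
            ).validate()

    def test_spec_json_round_trip(self, tmp_path):
        s = spec_of(
            [{"mean": [10.0], "kappa": 5.0, "weight": 1.0}], fragment="Gal(b1-3)GlcNAc"
        )
        path = tmp_path / "spec.json"
        s.to_json(path)
        back = EnsembleSpec.from_json(path)
        assert back == s


class TestStateSequence:
    def test_deterministic(self):
        a = sample_state_sequence(500, seed=7)
        assert np.array_equal(a, sample_state_sequence(500, seed=7))

    def test_stationary_fraction_tracks_dwell_ratio(self):
        s = sample_state_sequence(10_000, mean_dwells=(9.0, 3.0), seed=0)
        assert (s == 0).mean() == pytest.approx(0.75, abs=0.02)

    def test_dwell_validation(self):
        with pytest.raises(ValueError):
            sample_state_sequence(10, mean_dwells=(0.5, 3.0))


class TestPyranoseBuilder:
    def test_amplitude_bounds(self):
        with pytest.raises(ValueError, match="amplitude"):
            synth.build_pyranose("4C1", amplitude=1.5)
        with pytest.raises(ValueError, match="amplitude"):
            synth.build_pyranose("4C1", amplitude=0.0)

    def test_unknown_pucker_token(self):
        with pytest.raises(ValueError, match="unknown pucker"):
            synth.build_pyranose("boaty")

    def test_construction_record_matches_geometry(self):
        g = synth.build_pyranose("4C1")
        bonds = np.linalg.norm(g.xyz - np.roll(g.xyz, -1, axis=0), axis=1)
        assert bonds == pytest.approx(g.record["bond_lengths_A"], abs=1e-9)


class TestLinkedBuilder:
    def test_constant_torsions_round_trip(self, disaccharide_tree):
        ens, truth = synth.build_linked_ensemble(
            disaccharide_tree, {"phi": [60.0] * 10, "psi": [-120.0] * 10}
        )
        series = torsions.torsion_series(
            ens,
            io.map_atoms(disaccharide_tree, ens, "custom"),
            model.torsion_definitions(disaccharide_tree),
        )
        by_name = {s.torsion_name: s.values for s in series}
        assert by_name["phi"] == pytest.approx(np.full(10, 60.0), abs=1e-6)
        assert by_name["psi"] == pytest.approx(np.full(10, -120.0), abs=1e-6)

    def test_psi_ramp_recovered_exactly(self, disaccharide_tree):
        ramp = np.arange(-170.0, 180.0, 10.0)
        ens, _ = synth.build_linked_ensemble(
            disaccharide_tree, {"psi": ramp, "phi": np.full(len(ramp), 60.0)}
        )
        series = torsions.torsion_series(
            ens,
            io.map_atoms(disaccharide_tree, ens, "custom"),
            model.torsion_definitions(disaccharide_tree),
        )
        psi = next(s for s in series if s.torsion_name == "psi")
        assert np.abs(wrap_degrees(psi.values - ramp)).max() < 1e-6

    def test_omega_realized_on_1_6_linkage(self):
        tree = model.parse_glycan("Man(a1-6)Man")
        ens, _ = synth.build_linked_ensemble(
            tree, {"phi": [-60.0], "psi": [100.0], "omega": [60.0]}
        )
        series = torsions.torsion_series(
            ens, io.map_atoms(tree, ens, "custom"), model.torsion_definitions(tree)
        )
        assert {s.torsion_name: s.values[0] for s in series} == pytest.approx(
            {"phi": -60.0, "psi": 100.0, "omega": 60.0}, abs=1e-6
        )

    def test_single_residue_has_no_torsions(self):
        ens, truth = synth.build_linked_ensemble("GlcNAc", {})
        assert ens.n_atoms == 6
        assert list(truth.columns) == ["frame"]

    def test_size_limit(self):
        with pytest.raises(ValueError, match="at most 4"):
            synth.build_linked_ensemble("ng", {})

    def test_clash_frames_recorded(self):
        tree = model.parse_glycan("Man(a1-3)[Man(a1-6)]Man")
        _, truth = synth.build_linked_ensemble(
            tree, {(3, "phi"): [70.0], (3, "psi"): [-100.0]}
        )
        assert isinstance(truth.attrs["clash_frames"], list)


class TestArmGeometryBuilder:
    def test_invalid_state_token(self):
        with pytest.raises(ValueError, match="invalid arm state"):
            synth.build_arm_geometry("sideways", 10.0)

    def test_distance_floor(self):
        with pytest.raises(ValueError, match="exceed 2"):
            synth.build_arm_geometry("open", 1.0)

    def test_requested_distance_realized(self):
        ens, ci, ai = synth.build_arm_geometry("back_fold", 7.0)
        d = np.linalg.norm(
            ens.xyz[0, ai].mean(axis=0) - ens.xyz[0, ci].mean(axis=0)
        )
        assert d == pytest.approx(7.0, abs=1e-9)
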