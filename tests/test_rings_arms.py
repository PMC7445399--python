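"""Ring pucker classification and (1-6)-arm state classification."""

import numpy as np
import pytest

from glycoarch import model, synth
from glycoarch.arms import (
    ArmParams,
    classify_arm_frames,
    classify_arm_state,
    find_arm_terminus,
)
from glycoarch.geometry import random_rigid_transform
from glycoarch.rings import (
    classify_pucker,
    cremer_pople,
    projection_state,
    pucker_populations,
)


class TestPucker:
    @pytest.mark.parametrize(
        "request_,expected", [("4C1", "4C1"), ("1C4", "1C4"), (90.0, "other")]
    )
    def test_built_ring_round_trip(self, request_, expected):
        ring = synth.build_pyranose(request_)
        assert classify_pucker(ring.xyz).states[0] == expected

    def test_round_trip_under_rigid_motion(self, rng):
        """100 built instances with random poses classify correctly."""
        for request_, expected in (("4C1", "4C1"), ("1C4", "1C4"), (90.0, "other")):
            base = synth.build_pyranose(request_).xyz
            frames = np.empty((100, 6, 3))
            for f in range(100):
                rot, trans = random_rigid_transform(rng)
                frames[f] = base @ rot.T + trans
            assert (classify_pucker(frames).states == expected).all()

    def test_cp_coordinates_exact(self):
        for theta, phase in ((0.0, 0.0), (55.0, 77.0), (90.0, 200.0), (180.0, 0.0)):
            g = synth.build_pyranose(theta, phase=phase)
            Q, th, ph = cremer_pople(g.xyz)
            assert Q == pytest.approx(0.57, abs=1e-9)
            assert th == pytest.approx(theta, abs=1e-9)
            if 0.0 < theta < 180.0:
                assert ph % 360.0 == pytest.approx(phase % 360.0, abs=1e-6)

    def test_mirror_swaps_chairs(self):
        ring = synth.build_pyranose("4C1").xyz
        mirrored = ring * np.array([1.0, 1.0, -1.0])
        assert classify_pucker(mirrored).states[0] == "1C4"

    def test_planar_hexagon_is_other(self):
        ring = synth.build_pyranose("4C1").xyz.copy()
        ring[:, 2] = 0.0
        assert classify_pucker(ring).states[0] == "other"

    def test_even_cyclic_relabelling_invariance(self):
        """Shifting the ring origin by two positions (parity-consistent
        relabelling) leaves the chair classification unchanged; an odd shift
        inverts the alternating mode, i.e. swaps the chair labels."""
        ring = synth.build_pyranose("4C1").xyz
        for shift in (2, 4):
            assert classify_pucker(np.roll(ring, shift, axis=0)).states[0] == "4C1"
        for shift in (1, 3, 5):
            assert classify_pucker(np.roll(ring, shift, axis=0)).states[0] == "1C4"

    def test_projection_heuristic_agrees_on_flip_ensembles(self):
        xyz, labels = synth.build_flip_ring_ensemble(3000, seed=5)
        series = classify_pucker(xyz)
        assert (series.states == labels).all()
        heuristic = projection_state(series.t1, series.t2)
        assert (heuristic == series.states).mean() >= 0.99

    def test_flip_populations_match_dwell_ratio(self):
        """3:1 dwell-structured flips give fractions near 0.75/0.25."""
        xyz, labels = synth.build_flip_ring_ensemble(10_000, mean_dwells=(9.0, 3.0), seed=0)
        pops = pucker_populations(classify_pucker(xyz))
        truth = (labels == "1C4").mean()
        assert pops["1C4"] == pytest.approx(truth, abs=1e-12)  # classification exact
        assert pops["1C4"] == pytest.approx(0.75, abs=0.02)

    def test_fractions_sum_to_one(self):
        xyz, _ = synth.build_flip_ring_ensemble(500, seed=2)
        pops = pucker_populations(classify_pucker(xyz))
        assert sum(pops.values()) == pytest.approx(1.0, abs=1e-12)


class TestArmStates:
    @pytest.mark.parametrize(
        "state,distance",
        [("open", 14.0), ("front_fold", 5.0), ("back_fold", 5.0)],
    )
    def test_constructed_geometry_recovers_label(self, state, distance):
        ens, core_idx, arm_idx = synth.build_arm_geometry(
            state, distance, n_frames=30, seed=4, jitter=0.05
        )
        out = classify_arm_frames(ens.xyz[:, core_idx], ens.xyz[:, arm_idx])
        assert out.fractions() == {state: 1.0}

    def test_fractions_partition_frames(self):
        parts = []
        for state, dist in (("open", 12.0), ("front_fold", 5.0), ("back_fold", 4.0)):
            ens, ci, ai = synth.build_arm_geometry(state, dist, n_frames=10, seed=1)
            parts.append((ens.xyz[:, ci], ens.xyz[:, ai]))
        core = np.concatenate([c for c, _ in parts])
        arm = np.concatenate([a for _, a in parts])
        out = classify_arm_frames(core, arm)
        assert sum(out.fractions().values()) == pytest.approx(1.0)
        assert len(out) == 30

    def test_classifier_is_deterministic(self):
        ens, ci, ai = synth.build_arm_geometry("front_fold", 6.0, n_frames=20, seed=9, jitter=0.1)
        a = classify_arm_frames(ens.xyz[:, ci], ens.xyz[:, ai])
        b = classify_arm_frames(ens.xyz[:, ci], ens.xyz[:, ai])
        assert (a.states == b.states).all()

    def test_d_open_band_property(self, rng):
        """Shifting d_open by 0.5 A relabels only frames inside the band."""
        cores, arms = [], []
        for dist in rng.uniform(6.0, 10.0, size=60):
            ens, ci, ai = synth.build_arm_geometry("front_fold", float(dist), n_frames=1)
            cores.append(ens.xyz[0, ci])
            arms.append(ens.xyz[0, ai])
        core, arm = np.stack(cores), np.stack(arms)
        lo = classify_arm_frames(core, arm, ArmParams(d_open=8.0))
        hi = classify_arm_frames(core, arm, ArmParams(d_open=8.5))
        changed = lo.states != hi.states
        assert np.all((lo.distance[changed] > 8.0) & (lo.distance[changed] <= 8.5))

    def test_rotated_core_takes_precedence(self):
        ens, ci, ai = synth.build_arm_geometry("open", 14.0, n_frames=4)
        psi = np.array([-127.0, -130.0, 60.0, 100.0])  # last two rotated
        out = classify_arm_frames(
            ens.xyz[:, ci],
            ens.xyz[:, ai],
            ArmParams(psi_reference=-127.8),
            core_psi=psi,
        )
        assert list(out.states) == ["open", "open", "rotated_core", "rotated_core"]

    def test_find_arm_terminus(self):
        tree = model.parse_glycan("gfx")
        terminus = find_arm_terminus(tree)
        assert tree.nodes[terminus].name == "Gal"
        with pytest.raises(ValueError, match="no .1-6. arm"):
            find_arm_terminus(model.parse_glycan("Gal(b1-3)GlcNAc"))

    def test_high_level_classification_on_built_fragment(self):
        """End-to-end arm labelling on a 4-residue core fragment."""
        from glycoarch import io

        tree = model.parse_glycan("Man(a1-6)Man(b1-4)GlcNAc(b1-4)GlcNAc")
        ens, _ = synth.build_linked_ensemble(
            tree,
            {
                (3, "omega"): np.array([-60.0, 60.0, 180.0, -60.0]),
                (3, "psi"): np.full(4, 100.0),
            },
        )
        amap = io.map_atoms(tree, ens, "custom")
        out = classify_arm_state(ens, amap, tree)
        assert len(out) == 4
        assert set(out.states) <= {"open", "front_fold", "back_fold"}
        assert sum(out.fractions().values()) == pytest.approx(1.0)
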