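"""Toroidal density clustering, wrapped KDE, convergence rule."""

import numpy as np
import pytest

from glycoarch import landscape, synth
from glycoarch.circular import circular_mean, wrap_degrees
from glycoarch.landscape import (
    ConformerLandscape,
    TorsionCluster,
    assess_convergence,
    cluster_torsions,
    kde_landscape,
    population_of_state,
)


def mixture(components, n, seed, dims=2):
    spec = synth.EnsembleSpec(
        dimensions=["phi", "psi"][:dims], components=components, n_frames=n, seed=seed
    )
    return synth.sample_torsion_mixture(spec)


class TestClustering:
    def test_single_tight_mode(self):
        st = mixture([{"mean": [10.0, -40.0], "kappa": 100.0, "weight": 1.0}], 10_000, 3)
        ls = cluster_torsions([st.values[:, 0], st.values[:, 1]])
        assert len(ls.clusters) == 1
        assert ls.clusters[0].population > 0.99
        assert ls.noise_fraction < 0.01

    def test_two_component_recovery(self):
        comps = [
            {"mean": [60.0, 180.0], "kappa": 50.0, "weight": 0.7},
            {"mean": [-60.0, -120.0], "kappa": 50.0, "weight": 0.3},
        ]
        st = mixture(comps, 30_000, 7)
        ls = cluster_torsions([st.values[:, 0], st.values[:, 1]])
        assert len(ls.clusters) == 2
        true = sorted(st.true_weights(), reverse=True)
        for cl, w in zip(ls.clusters, true):
            assert cl.population == pytest.approx(w, abs=0.02)
        # nearest-mean oracle agrees with the density assignment
        means = np.array([c["mean"] for c in comps])
        d0 = np.abs(wrap_degrees(st.values - means[0]))
        d1 = np.abs(wrap_degrees(st.values - means[1]))
        oracle = (np.hypot(*d1.T) < np.hypot(*d0.T)).astype(int)
        assigned = ls.assignments - 1  # cluster 1 = heavier = component 0
        mask = ls.assignments > 0
        assert (oracle[mask] == assigned[mask]).mean() > 0.999

    def test_mode_straddling_180_not_split(self):
        st = mixture([{"mean": [179.0], "kappa": 50.0, "weight": 1.0}], 10_000, 1, dims=1)
        ls = cluster_torsions(st.values[:, 0])
        assert len(ls.clusters) == 1
        assert abs(wrap_degrees(ls.clusters[0].means[0] - 179.0)) < 2.0

    def test_rotation_invariance(self):
        """Rotating all angles by +137 degrees leaves the clustering unchanged."""
        comps = [
            {"mean": [0.0, 0.0], "kappa": 50.0, "weight": 0.6},
            {"mean": [150.0, -150.0], "kappa": 50.0, "weight": 0.4},
        ]
        st = mixture(comps, 12_000, 5)
        base = cluster_torsions([st.values[:, 0], st.values[:, 1]])
        rot = wrap_degrees(st.values + 137.0)
        moved = cluster_torsions([rot[:, 0], rot[:, 1]])
        assert len(base.clusters) == len(moved.clusters)
        for a, b in zip(base.clusters, moved.clusters):
            assert a.member_count == b.member_count
            for ma, mb in zip(a.means, b.means):
                assert abs(wrap_degrees(mb - ma - 137.0)) < 1e-6

    def test_populations_plus_noise_sum_to_one(self):
        st = mixture(
            [
                {"mean": [0.0, 0.0], "kappa": 8.0, "weight": 0.5},
                {"mean": [120.0, 120.0], "kappa": 8.0, "weight": 0.5},
            ],
            8_000,
            2,
        )
        ls = cluster_torsions([st.values[:, 0], st.values[:, 1]])
        total = sum(c.population for c in ls.clusters) + ls.noise_fraction
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_weight_recovery_across_seeds(self):
        """Well-separated mixtures recover weights to 3 binomial SEs, 20 seeds."""
        comps = [
            {"mean": [-90.0, 30.0], "kappa": 50.0, "weight": 0.55},
            {"mean": [30.0, 150.0], "kappa": 50.0, "weight": 0.45},
        ]
        n = 30_000
        for seed in range(20):
            st = mixture(comps, n, seed)
            ls = cluster_torsions([st.values[:, 0], st.values[:, 1]])
            assert len(ls.clusters) == 2
            true = sorted(st.true_weights(), reverse=True)
            for cl, w in zip(ls.clusters, true):
                assert abs(cl.population - w) <= 3 * np.sqrt(w * (1 - w) / n)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            cluster_torsions(np.array([]))

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            cluster_torsions(np.array([0.0, 1.0]), eps=0.0)


class TestKDE:
    def test_torus_integral_is_one(self, rng):
        vals = np.degrees(rng.vonmises(0.5, 5.0, size=5000))
        grid = kde_landscape(vals)
        assert grid.integral() == pytest.approx(1.0, abs=1e-6)
        grid2 = kde_landscape(
            [vals, np.degrees(rng.vonmises(-1.0, 5.0, size=5000))]
        )
        assert grid2.integral() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_sample_is_flat(self, rng):
        n, cells = 90_000, 90
        vals = rng.uniform(-180.0, 180.0, size=n)
        grid = kde_landscape(vals, bandwidth=10.0, grid_size=cells)
        p = 1.0 / cells
        sd = np.sqrt(p * (1 - p) / n)  # binomial SD per cell, pre-smoothing
        cell_mass = grid.density * grid.cell_volume
        assert np.abs(cell_mass - p).max() < 3 * sd

    def test_argmax_tracks_circular_mean(self, rng):
        vals = np.degrees(rng.vonmises(np.radians(-120.0), 50.0, size=20_000))
        grid = kde_landscape(vals)
        cell = grid.cell_volume  # 1D: cell width in degrees
        assert abs(wrap_degrees(grid.argmax_center()[0] - circular_mean(vals))) <= cell

    def test_wrap_mode_peaks_at_180(self, rng):
        vals = wrap_degrees(np.degrees(rng.vonmises(np.pi, 50.0, size=20_000)))
        grid = kde_landscape(vals)
        assert abs(abs(grid.argmax_center()[0]) - 178.0) <= 4.0

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            kde_landscape(np.array([0.0]), bandwidth=0.0)


def landscape_with_sds(sds):
    clusters = [
        TorsionCluster(label=i + 1, means=(0.0,), sds=(sd,), population=1.0, member_count=10)
        for i, sd in enumerate(sds)
    ]
    return ConformerLandscape(
        dimension_names=("psi",),
        clusters=clusters,
        noise_fraction=0.0,
        noise_count=0,
        n_frames=10,
    )


class TestConvergence:
    @pytest.mark.parametrize(
        "sd,expected",
        [(10.0, "converged"), (14.0, "converged"), (15.0, "converged"), (16.0, "extend")],
    )
    def test_threshold_is_strict(self, sd, expected):
        """The 15-degree rule flags only SDs strictly above the threshold."""
        report = assess_convergence({"traj1": landscape_with_sds([sd])})
        assert report.flag == expected

    def test_any_cluster_triggers_extension(self):
        report = assess_convergence(
            {"a": landscape_with_sds([10.0, 12.0]), "b": landscape_with_sds([10.0, 15.1])}
        )
        assert report.flag == "extend"
        flags = report.rows.set_index(["trajectory", "cluster"])["flag"]
        assert flags[("a", 1)] == "converged"
        assert flags[("b", 2)] == "extend"

    def test_no_trajectories_rejected(self):
        with pytest.raises(ValueError):
            assess_convergence({})


class TestPopulationOfState:
    def test_all_clusters_one_state(self):
        ls = landscape_with_sds([5.0, 5.0])
        for c, p in zip(ls.clusters, (0.7, 0.3)):
            c.population = p
        out = population_of_state(ls, lambda c: "open")
        assert out["open"] == pytest.approx(1.0)

    def test_select_one_cluster(self):
        ls = landscape_with_sds([5.0, 5.0])
        ls.clusters[0].population, ls.clusters[1].population = 0.7, 0.3
        out = population_of_state(
            ls, lambda c: "open" if c.label == 1 else "folded"
        )
        assert out["open"] == pytest.approx(0.7)
        assert out["folded"] == pytest.approx(0.3)

    def test_unassigned_cluster_is_error(self):
        ls = landscape_with_sds([5.0])
        with pytest.raises(ValueError, match="unassigned"):
            population_of_state(ls, lambda c: None)

    def test_three_state_arm_mixture_recovery(self):
        """0.5/0.3/0.2 omega-rotamer mixture mapped to named states."""
        comps = [
            {"mean": [-60.0], "kappa": 50.0, "weight": 0.5},  # gg -> open
            {"mean": [60.0], "kappa": 50.0, "weight": 0.3},  # gt -> front
            {"mean": [180.0], "kappa": 50.0, "weight": 0.2},  # tg -> back
        ]
        st = mixture(comps, 30_000, 11, dims=1)
        ls = cluster_torsions(st.values[:, 0])
        assert len(ls.clusters) == 3

        def predicate(cl):
            m = cl.means[0]
            if abs(wrap_degrees(m + 60.0)) < 45.0:
                return "open"
            if abs(wrap_degrees(m - 60.0)) < 45.0:
                return "front"
            return "back"

        out = population_of_state(ls, predicate)
        true = st.true_weights()
        assert out["open"] == pytest.approx(true[0], abs=0.02)
        assert out["front"] == pytest.approx(true[1], abs=0.02)
        assert out["back"] == pytest.approx(true[2], abs=0.02)
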