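"""Morphometric statistics, distributions, Sholl profiles and motifs."""

import numpy as np
import pytest

from morphorep.geometry import geometry_tables
from morphorep.morphometrics import (STATISTIC_NAMES, average_maximal_distance,
                                     compute_statistics, distribution_1d,
                                     distribution_2d, fit_dataset_edges,
                                     sholl_profile, star_motifs,
                                     tree_asymmetry)
from morphorep.swc import parse_swc


@pytest.fixture(scope="module")
def y_stats(toys):
    return compute_statistics(geometry_tables(toys["y_tree"]))


class TestStatistics:
    def test_cone_surface_and_volume(self, toys):
        s = compute_statistics(geometry_tables(toys["cone"]))
        assert s["surface"] == pytest.approx(2 * np.pi, rel=1e-12)
        assert s["volume"] == pytest.approx(np.pi, rel=1e-12)

    def test_y_tree_hand_counts(self, y_stats):
        assert y_stats["n_branch_points"] == 1
        assert y_stats["n_tips"] == 2
        assert y_stats["n_stems"] == 1
        assert y_stats["total_length"] == pytest.approx(4.0)
        assert y_stats["max_neurite_length"] == pytest.approx(3.0)
        assert y_stats["max_branch_order"] == 1
        assert y_stats["max_segment"] == pytest.approx(2.0)

    def test_straight_neurite_angles_and_tortuosity(self, toys):
        s = compute_statistics(geometry_tables(toys["straight"]))
        assert s["median_path_angle"] == 0.0
        assert s["median_log_tortuosity"] == 0.0

    def test_all_24_statistics_present_and_finite(self, toys, random_trees):
        for m in [toys["y_tree"]] + random_trees[:5]:
            s = compute_statistics(geometry_tables(m))
            assert list(s.index) == STATISTIC_NAMES and len(s) == 24
            assert np.isfinite(s.to_numpy()).all()

    def test_translation_invariance(self, random_trees):
        m = random_trees[0]
        shifted = m.copy()
        shifted.xyz = m.xyz + np.array([10.0, -4.0, 7.0])
        a = compute_statistics(geometry_tables(m))
        b = compute_statistics(geometry_tables(shifted))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_percentile_at_least_median(self, random_trees):
        for m in random_trees[:8]:
            s = compute_statistics(geometry_tables(m))
            assert s["max_path_angle"] >= s["median_path_angle"] - 1e-12
            assert s["max_log_tortuosity"] >= s["median_log_tortuosity"] - 1e-12


class TestAsymmetry:
    def test_caterpillar_psad_one(self, toys):
        assert tree_asymmetry(toys["caterpillar4"]) == pytest.approx(1.0)

    def test_balanced_zero(self, toys):
        assert tree_asymmetry(toys["balanced4"]) == pytest.approx(0.0)

    def test_small_subtrees_unweighted(self, toys):
        # single branch point with 2 leaves: no subtree with > 3 leaves
        assert tree_asymmetry(toys["y_tree"]) == 0.0

    def test_non_negative(self, random_trees):
        for m in random_trees[:10]:
            assert tree_asymmetry(m) >= 0


class TestDistributions:
    def test_branch_angle_bin_placement(self):
        # single 90-degree branch angle lands in bin floor(90/9) = 10 of 20
        m = parse_swc("1 1 0 0 0 1 -1\n2 2 1 0 0 .5 1\n"
                      "3 2 1 1 0 .5 2\n4 2 2 0 0 .5 2\n")
        g = geometry_tables(m)
        edges = fit_dataset_edges([g])
        h = distribution_1d(g, "branch_angles", edges)
        assert len(h) == 20 and h.sum() == 1 and h[10] == 1

    def test_path_graph_branch_orders_all_zero(self, toys):
        g = geometry_tables(toys["straight"])
        edges = fit_dataset_edges([g])
        h = distribution_1d(g, "branch_orders", edges)
        assert h.sum() == 0  # no branch points at all

    def test_known_lengths(self, toys):
        g = geometry_tables(toys["y_tree"])
        edges = fit_dataset_edges([g])
        for name, n in [("branch_angles", 20), ("path_angles", 20),
                        ("root_angles", 20), ("segment_lengths", 20),
                        ("thickness", 30), ("path_dist_to_soma", 20),
                        ("radial_dist_to_soma", 20), ("sholl_xy", 36),
                        ("star_motifs", 10)]:
            assert len(distribution_1d(g, name, edges)) == n, name

    def test_unknown_name_raises(self, toys):
        g = geometry_tables(toys["y_tree"])
        with pytest.raises(ValueError, match="unknown"):
            distribution_1d(g, "nope", {})

    def test_2d_value_marginal_matches_1d(self, random_trees):
        for m in random_trees[:6]:
            g = geometry_tables(m)
            edges = fit_dataset_edges([g])
            pairs = [("path_angles_x_path_dist", "path_angles", 20),
                     ("path_angles_x_branch_orders", "path_angles", 20),
                     ("branch_angles_x_path_dist", "branch_angles", 20),
                     ("thickness_x_path_dist", "thickness", 30)]
            for name2d, name1d, nb in pairs:
                h2 = distribution_2d(g, name2d, edges).reshape(nb, 20)
                h1 = distribution_1d(g, name1d, edges)
                assert np.array_equal(h2.sum(axis=1), h1), (name2d,)

    def test_2d_mass_equals_contributors(self, toys):
        g = geometry_tables(toys["y_tree"])
        edges = fit_dataset_edges([g])
        h = distribution_2d(g, "path_angles_x_path_dist", edges)
        assert h.sum() == g.nodes["path_angle"].notna().sum()

    def test_straight_neurite_first_angle_bin(self, toys):
        g = geometry_tables(toys["straight"])
        edges = fit_dataset_edges([g])
        h = distribution_2d(g, "path_angles_x_path_dist", edges).reshape(20, 20)
        assert h.sum() == h[0].sum() > 0  # all mass at path angle ~ 0


class TestSholl:
    def test_straight_radial_all_ones(self, toys):
        g = geometry_tables(toys["straight"])  # radial along z
        prof = sholl_profile(g, "xz")
        assert (prof == 1).all()

    def test_y_profile_steps_up(self):
        # stem along +x then both daughters continue further out in x
        m = parse_swc("1 1 0 0 0 1 -1\n2 2 4 0 0 .5 1\n"
                      "3 2 8 3 0 .5 2\n4 2 8 -3 0 .5 2\n")
        prof = sholl_profile(geometry_tables(m), "xy")
        assert prof[0] == 1 and prof[-1] == 2
        assert set(np.unique(prof)) == {1, 2}

    def test_last_circle_crossed(self, random_trees):
        for m in random_trees[:10]:
            prof = sholl_profile(geometry_tables(m), "xy")
            assert len(prof) == 36 and prof[-1] >= 1


class TestStarMotifs:
    def test_bifurcation_and_trifurcation_counts(self, toys):
        assert star_motifs(toys["y_tree"])[-1] == 1
        assert star_motifs(toys["trifurcation"])[-1] == 2

    def test_monotone_in_decile(self, random_trees):
        for m in random_trees[:8]:
            v = star_motifs(m)
            assert (np.diff(v) >= 0).all()

    def test_random_centers_deterministic_given_seed(self, toys):
        m = toys["caterpillar4"]
        a = star_motifs(m, centers="random", n_repeats=20, seed=5)
        b = star_motifs(m, centers="random", n_repeats=20, seed=5)
        assert np.array_equal(a, b)
        d1 = average_maximal_distance(m, n_repeats=20, seed=5)
        d2 = average_maximal_distance(m, n_repeats=20, seed=5)
        assert np.array_equal(d1, d2)
        assert (np.diff(d1) >= -1e-12).all()
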