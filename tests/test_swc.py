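"""SWC parsing, validation and the preprocessing chain."""

import numpy as np
import pytest

from morphorep.swc import (SWCError, center, consolidate_soma,
                           harmonize_branch_types, parse_swc, preprocess,
                           resample, segments, smooth_depth_axis, write_swc)

MINIMAL = """# comment line
1 1 0 0 0 1.0 -1
2 2 1 0 0 0.5 1
3 2 2 0 0 0.5 2
"""


class TestParse:
    def test_minimal_tree(self):
        m = parse_swc(MINIMAL)
        assert m.n_nodes == 3
        assert m.root == 0
        assert list(m.tips()) == [2]

    def test_round_trip_identity(self, toys):
        for name, m in toys.items():
            m2 = parse_swc(write_swc(m))
            assert np.allclose(m2.xyz, m.xyz, atol=1e-8), name
            assert (m2.kind == m.kind).all()
            assert (m2.parent == m.parent).all()
            assert np.allclose(m2.radius, m.radius)

    def test_tab_delimited_and_unordered_ids(self):
        text = "10\t1\t0\t0\t0\t1\t-1\n5\t2\t1\t0\t0\t0.5\t10\n"
        m = parse_swc(text)
        assert m.n_nodes == 2 and m.ids[0] == 10

    @pytest.mark.parametrize("bad,msg", [
        ("1 1 0 0 0 1 -1\n2 2 1 0 0 0.5 99\n", "missing parent id 99"),
        ("1 1 0 0 0 1 -1\n2 1 1 0 0 1 -1\n", "root"),
        ("1 1 0 0 0 1 2\n2 2 1 0 0 0.5 1\n", "root"),  # cycle, no root
        ("1 1 0 0 0 1 -1\n2 7 1 0 0 0.5 1\n", "type"),
        ("1 1 0 0 0 1\n", "7 columns"),
    ])
    def test_malformed_input(self, bad, msg):
        with pytest.raises(SWCError, match=msg):
            parse_swc(bad)


class TestConsolidateSoma:
    def test_two_somas_merge_to_midpoint(self):
        text = ("1 1 0 0 0 1 -1\n2 1 2 0 0 1 1\n"
                "3 2 2 1 0 0.5 2\n4 2 0 -1 0 0.5 1\n")
        m = consolidate_soma(parse_swc(text))
        assert (m.kind == 1).sum() == 1
        assert np.allclose(m.xyz[0], [1, 0, 0])  # hull of 2 points -> midpoint
        # both neurite children re-parented to the new soma
        assert (m.parent[1:] == 0).all()

    def test_radius_threshold_relabels(self):
        # an 'axon' node thicker than 1 um is somatic
        text = "1 2 0 0 0 1.5 -1\n2 2 1 0 0 0.5 1\n"
        m = consolidate_soma(parse_swc(text), radius_threshold=1.0)
        assert m.kind[0] == 1 and m.n_nodes == 2

    def test_idempotent_on_single_soma(self, toys):
        y = toys["y_tree"]
        m = consolidate_soma(y)
        assert np.allclose(m.xyz, y.xyz) and (m.parent == y.parent).all()

    def test_no_soma_errors(self):
        with pytest.raises(SWCError, match="no soma"):
            consolidate_soma(parse_swc("1 2 0 0 0 0.5 -1\n2 2 1 0 0 0.5 1\n"))


class TestHarmonize:
    def test_majority_vote_within_branch(self):
        # branch of 3 sub-segments typed axon/axon/dendrite -> all axon
        text = ("1 1 0 0 0 1 -1\n2 2 1 0 0 .5 1\n"
                "3 2 2 0 0 .5 2\n4 3 3 0 0 .5 3\n")
        m = harmonize_branch_types(parse_swc(text))
        assert (m.kind[1:] == 2).all()

    def test_tie_resolves_to_axon(self):
        text = "1 1 0 0 0 1 -1\n2 2 1 0 0 .5 1\n3 3 2 0 0 .5 2\n"
        m = harmonize_branch_types(parse_swc(text))
        assert (m.kind[1:] == 2).all()

    def test_uniform_branch_unchanged(self, toys):
        y = toys["y_tree"]
        assert (harmonize_branch_types(y).kind == y.kind).all()


class TestResample:
    def test_straight_segment(self, toys):
        r = resample(toys["straight"], 1.0)
        assert r.n_nodes == 6
        assert r.total_length() == pytest.approx(5.0, abs=1e-12)
        # collinear
        assert np.allclose(r.xyz[:, :2], 0)

    def test_right_angle_polyline_bounds(self):
        text = "1 1 0 0 0 1 -1\n2 2 1 0 0 .5 1\n3 2 1 1 0 .5 2\n"
        r = resample(parse_swc(text), 0.3)
        total = r.total_length()
        assert np.sqrt(2) - 1e-12 <= total <= 2 + 1e-12

    def test_spacing_bound_and_topology_retained(self, toys, random_trees):
        for m in [toys["y_tree"], toys["semicircle"]] + random_trees[:5]:
            r = resample(m, 1.0)
            assert (r.edge_lengths()[1:] <= 1.0 + 1e-9).all()
            assert len(r.tips()) == len(m.tips())
            assert len(r.branch_points()) == len(m.branch_points())
            assert r.total_length() <= m.total_length() + 1e-9

    def test_fixed_point(self, toys, random_trees):
        for m in [toys["semicircle"]] + random_trees[:5]:
            r1 = resample(m, 1.0)
            r2 = resample(r1, 1.0)
            assert r1.n_nodes == r2.n_nodes
            assert np.abs(r1.xyz - r2.xyz).max() < 1e-9

    def test_coarse_spacing_keeps_topology_nodes_only(self, toys):
        y = toys["y_tree"]
        r = resample(y, 100.0)
        # spacing exceeds every sub-segment: all original nodes, nothing added
        assert r.n_nodes == y.n_nodes
        assert (r.parent == y.parent).all()
        assert len(r.tips()) == 2

    def test_invalid_spacing(self, toys):
        with pytest.raises(ValueError):
            resample(toys["y_tree"], 0.0)


class TestSavgol:
    def _straight_run(self, y_values):
        rows = ["1 1 0 0 0 1 -1"]
        for k, y in enumerate(y_values, start=1):
            rows.append(f"{k+1} 2 {float(k)} {y} 0 0.5 {k}")
        return parse_swc("\n".join(rows))

    def test_cubic_is_reproduced(self):
        # cubic through the soma point too (f(0) = 0), so the whole
        # unbranched run including the soma lies on one cubic
        t = np.arange(1, 31, dtype=float)
        y = 0.01 * t**3 - 0.2 * t**2 + t
        m = self._straight_run(y)
        s = smooth_depth_axis(m, window=21, order=3)
        assert np.allclose(s.xyz[1:, 1], y, atol=1e-8)
        assert np.allclose(s.xyz[:, [0, 2]], m.xyz[:, [0, 2]])

    def test_outlier_jump_attenuated(self):
        y = np.zeros(40)
        y[20] = 10.0
        m = self._straight_run(y)
        s = smooth_depth_axis(m, window=21, order=3)
        assert np.abs(s.xyz[1:, 1]).max() < 10.0

    def test_short_run_unfiltered(self):
        y = np.array([0, 5, 0, 5, 0], dtype=float)
        m = self._straight_run(y)
        s = smooth_depth_axis(m, window=21, order=3)
        assert np.allclose(s.xyz[:, 1], m.xyz[:, 1])


class TestCenter:
    def test_soma_mode(self, toys):
        m = toys["y_tree"].copy()
        m.xyz = m.xyz + np.array([5.0, -3.0, 2.0])
        c = center(m, "soma")
        assert np.allclose(c.xyz[0], 0)
        c2 = center(c, "soma")
        assert np.allclose(c.xyz, c2.xyz)

    def test_bipolar_mode_z_offset(self, toys):
        m = toys["y_tree"].copy()
        m.xyz = m.xyz + np.array([0.0, 0.0, 12.0])
        c = center(m, "soma_xy_with_z_offset", z_offset=-12.0)
        assert np.allclose(c.xyz[0], [0, 0, 0])
        assert np.allclose(c.xyz[:, 2], m.xyz[:, 2] - 12.0)


class TestPreprocessChain:
    def test_tree_invariants_preserved(self, random_trees):
        for m in random_trees[:8]:
            out = preprocess(m, mode="cortical")
            assert (out.parent == -1).sum() == 1
            assert (out.parent < np.arange(out.n_nodes)).all()
            assert (out.kind[0] == 1)

    def test_segment_lengths_sum_to_total(self, toys, random_trees):
        for m in [toys["y_tree"]] + random_trees[:5]:
            seg_sum = sum(
                float(np.linalg.norm(np.diff(m.xyz[s], axis=0), axis=1).sum())
                for s in segments(m))
            assert seg_sum == pytest.approx(m.total_length(), rel=1e-9)
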