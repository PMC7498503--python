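"""Morphometric statistics and distributions of a neuron reconstruction.

Two families of features live here:

* 24 single-valued summary statistics (counts, extents, lengths, angles,
  tortuosity, tree asymmetry), stacked into one "morphometric statistics"
  vector;
* 17 one-dimensional and 6 two-dimensional morphometric distributions
  (fixed-bin histograms, Sholl intersection profiles and 3-star motif
  vectors).

Statistics undefined for a degenerate topology (e.g. branch angles of an
unbranched cell) are recorded as 0 with a warning, never NaN, so feature
matrices stay finite.  Percentiles use linear interpolation between order
statistics; the "maximal" path angle and tortuosity are 99.5th percentiles,
which de-emphasizes single reconstruction artefacts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import GeometryTables
from .swc import Morphology, SOMA

STATISTIC_NAMES = [
    "n_branch_points", "n_tips", "height", "width", "depth", "n_stems",
    "avg_thickness", "total_length", "surface", "volume",
    "max_neurite_length", "max_branch_order", "max_segment",
    "median_intermediate_segment", "median_terminal_segment",
    "median_path_angle", "max_path_angle",
    "median_log_tortuosity", "max_log_tortuosity",
    "min_branch_angle", "avg_branch_angle", "max_branch_angle",
    "max_degree", "tree_asymmetry",
]

DISTRIBUTION_1D_NAMES = [
    "branch_angles", "branch_orders", "path_angles", "root_angles",
    "euler_root_angle_alpha", "euler_root_angle_beta", "euler_root_angle_gamma",
    "segment_lengths", "thickness", "path_dist_to_soma", "radial_dist_to_soma",
    "sholl_xy", "sholl_xz", "sholl_yz",
    "star_motifs", "avg_star_motifs", "avg_max_distance",
]

DISTRIBUTION_2D_NAMES = [
    "branch_angles_x_branch_orders", "branch_angles_x_path_dist",
    "path_angles_x_branch_orders", "path_angles_x_path_dist",
    "thickness_x_branch_orders", "thickness_x_path_dist",
]

N_SHOLL_STEPS = 36


def _zero_if_empty(values, name: str, reducer) -> float:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        warnings.warn(f"statistic {name!r} undefined for this topology; recorded as 0")
        return 0.0
    return float(reducer(values))


def _cone_surface(r, R, h):
    return np.pi * (r + R) * np.sqrt((R - r) ** 2 + h ** 2)


def _cone_volume(r, R, h):
    return np.pi * h * (r ** 2 + r * R + R ** 2) / 3.0


def compute_statistics(g: GeometryTables) -> pd.Series:
    """The 24 single-valued summary statistics, in a fixed order.

    Extents are max-min per axis (z = height, x = width, y = depth).  Surface
    and volume model each sub-segment as a truncated cone with the node radii
    at both ends; the soma is excluded from thickness and, its radius being
    incommensurate with neurites, soma-adjacent sub-segments use the child
    radius at both ends.
    """
    m = g.morphology
    nodes = g.nodes
    segs = g.segments_table

    neurite = nodes.index[nodes["kind"] != SOMA].to_numpy()
    lens = m.edge_lengths()

    # truncated-cone surface and volume per sub-segment (soma radius bypassed)
    par = m.parent[1:]
    r_child = m.radius[1:]
    r_parent = np.where(m.kind[par] == SOMA, r_child, m.radius[par])
    h = lens[1:]
    surface = float(_cone_surface(np.minimum(r_parent, r_child),
                                  np.maximum(r_parent, r_child), h).sum())
    volume = float(_cone_volume(np.minimum(r_parent, r_child),
                                np.maximum(r_parent, r_child), h).sum())

    tips = m.tips()
    path_dist = nodes["path_dist"].to_numpy()
    path_angles = nodes["path_angle"].to_numpy()
    with np.errstate(divide="ignore"):
        log_tort = np.log(segs["tortuosity"].to_numpy(dtype=float))
    inter = segs.loc[segs["kind"] == "intermediate", "path_length"].to_numpy()
    term = segs.loc[segs["kind"] == "terminal", "path_length"].to_numpy()
    stems = int((m.parent == 0).sum())

    out = {
        "n_branch_points": float(g.n_branch_points),
        "n_tips": float(len(tips)),
        "height": float(np.ptp(nodes["z"])) if len(nodes) else 0.0,
        "width": float(np.ptp(nodes["x"])),
        "depth": float(np.ptp(nodes["y"])),
        "n_stems": float(stems),
        "avg_thickness": _zero_if_empty(m.radius[neurite], "avg_thickness", np.mean),
        "total_length": float(lens.sum()),
        "surface": surface,
        "volume": volume,
        "max_neurite_length": _zero_if_empty(path_dist[tips], "max_neurite_length", np.max),
        "max_branch_order": float(nodes["branch_order"].max()),
        "max_segment": _zero_if_empty(segs["euclidean"], "max_segment", np.max),
        "median_intermediate_segment": _zero_if_empty(
            inter, "median_intermediate_segment", np.median),
        "median_terminal_segment": _zero_if_empty(
            term, "median_terminal_segment", np.median),
        "median_path_angle": _zero_if_empty(path_angles, "median_path_angle", np.median),
        "max_path_angle": _zero_if_empty(
            path_angles, "max_path_angle", lambda v: np.percentile(v, 99.5)),
        "median_log_tortuosity": _zero_if_empty(
            log_tort, "median_log_tortuosity", np.median),
        "max_log_tortuosity": _zero_if_empty(
            log_tort, "max_log_tortuosity", lambda v: np.percentile(v, 99.5)),
        "min_branch_angle": _zero_if_empty(g.branch_angles, "min_branch_angle", np.min),
        "avg_branch_angle": _zero_if_empty(g.branch_angles, "avg_branch_angle", np.mean),
        "max_branch_angle": _zero_if_empty(g.branch_angles, "max_branch_angle", np.max),
        "max_degree": _zero_if_empty(
            g.branch_points["out_degree"].to_numpy() + 1 if g.n_branch_points else [],
            "max_degree", np.max),
        "tree_asymmetry": tree_asymmetry(m),
    }
    return pd.Series(out, index=STATISTIC_NAMES, dtype=float)


def tree_asymmetry(m: Morphology) -> float:
    """Weighted sum of per-branch-point PSAD scores.

    PSAD(p) = m / (2 (m-1) (n-m)) * sum_i |r_i - n/m| for a branch point of
    out-degree m whose subtree has n leaves split r_1..r_m among the daughter
    subtrees; each PSAD lies in [0, 1].  A branch point contributes (weight 1)
    only when its subtree has more than 3 leaves; a perfectly balanced tree
    scores 0.
    """
    ch = m.children()
    deg = m.out_degree()
    # leaves below each node, computed bottom-up (reverse topological order)
    leaves = np.zeros(m.n_nodes, dtype=np.int64)
    for i in range(m.n_nodes - 1, -1, -1):
        if deg[i] == 0:
            leaves[i] = 1
        else:
            leaves[i] = sum(leaves[c] for c in ch[i])
    total = 0.0
    for p in range(m.n_nodes):
        mm = int(deg[p])
        if mm < 2:
            continue
        n_leaves = int(leaves[p])
        if n_leaves <= 3:
            continue
        r = np.array([leaves[c] for c in ch[p]], dtype=float)
        if n_leaves == mm:  # all daughters are leaves: perfectly balanced
            continue
        psad = mm / (2.0 * (mm - 1) * (n_leaves - mm)) * np.abs(r - n_leaves / mm).sum()
        total += psad
    return float(total)


# ---------------------------------------------------------------------------
# dataset-level bin edges
# ---------------------------------------------------------------------------

EDGE_KEYS = ("max_segment_length", "max_radius", "max_neurite_length",
             "max_path_dist", "max_branch_order")


def fit_dataset_edges(tables: list[GeometryTables]) -> dict:
    """Dataset-level histogram maxima shared by all cells of one dataset."""
    seg_max = rad_max = neur_max = path_max = 0.0
    order_max = 0
    for g in tables:
        if len(g.segments_table):
            seg_max = max(seg_max, float(g.segments_table["euclidean"].max()))
        neurite = g.nodes["kind"] != SOMA
        if neurite.any():
            rad_max = max(rad_max, float(g.nodes.loc[neurite, "radius"].max()))
        path_max = max(path_max, float(g.nodes["path_dist"].max()))
        tips = g.morphology.tips()
        if len(tips):
            neur_max = max(
                neur_max, float(g.nodes["path_dist"].to_numpy()[tips].max()))
        order_max = max(order_max, int(g.nodes["branch_order"].max()))
    return {
        "max_segment_length": seg_max, "max_radius": rad_max,
        "max_neurite_length": neur_max, "max_path_dist": path_max,
        "max_branch_order": order_max,
    }


def _hist(values, n_bins, vmax, vmin=0.0):
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if vmax <= vmin:
        vmax = vmin + 1.0
    counts, _ = np.histogram(np.clip(values, vmin, vmax), bins=n_bins,
                             range=(vmin, vmax))
    return counts.astype(float)


def _axis_values(g: GeometryTables, axis: str, edges: dict):
    """(values, n_bins, vmax) for one histogram axis; shared by 1D and 2D."""
    nodes = g.nodes
    if axis == "branch_angles":
        return g.branch_angles, 20, 180.0
    if axis == "path_angles":
        return nodes["path_angle"].dropna().to_numpy(), 20, 180.0
    if axis == "root_angles":
        return g.segments_table["root_angle"].dropna().to_numpy(), 20, 180.0
    if axis.startswith("euler_root_angle_"):
        col = "euler_" + axis.rsplit("_", 1)[1]
        return g.segments_table[col].dropna().to_numpy(), 20, 180.0
    if axis == "segment_lengths":
        return (g.segments_table["euclidean"].to_numpy(), 20,
                edges["max_segment_length"])
    if axis == "thickness":
        neurite = nodes["kind"] != SOMA
        return nodes.loc[neurite, "radius"].to_numpy(), 30, edges["max_radius"]
    if axis == "path_dist_to_soma":
        sel = _topology_nodes(g)
        return (nodes["path_dist"].to_numpy()[sel], 20,
                edges["max_neurite_length"])
    if axis == "radial_dist_to_soma":
        sel = _topology_nodes(g)
        return nodes["radial_dist"].to_numpy()[sel], 20, edges["max_path_dist"]
    raise ValueError(f"unknown distribution axis {axis!r}")


def _topology_nodes(g: GeometryTables) -> np.ndarray:
    """Branch points and tips (the nodes distance histograms run over)."""
    m = g.morphology
    return np.concatenate([m.branch_points(), m.tips()]).astype(int)


def distribution_1d(g: GeometryTables, name: str, edges: dict,
                    n_repeats: int = 100, seed: int = 0) -> np.ndarray:
    """One of the 17 one-dimensional morphometric distributions.

    ``edges`` carries the dataset-level maxima from
    :func:`fit_dataset_edges`; angle histograms always span [0, 180] with 20
    bins, thickness uses 30 bins, Sholl profiles have 36 steps, and the
    3-star-motif vectors are 10-dimensional (one entry per path-distance
    decile).
    """
    if name == "branch_orders":
        k_max = int(edges["max_branch_order"])
        orders = g.nodes["branch_order"].to_numpy()[g.branch_points["node"].to_numpy()] \
            if g.n_branch_points else np.array([], dtype=int)
        out = np.zeros(k_max + 1)
        for o in orders:
            out[min(int(o), k_max)] += 1
        return out
    if name.startswith("sholl_"):
        return sholl_profile(g, name.split("_")[1]).astype(float)
    if name == "star_motifs":
        return star_motifs(g.morphology, centers="soma").astype(float)
    if name == "avg_star_motifs":
        return star_motifs(g.morphology, centers="random",
                           n_repeats=n_repeats, seed=seed)
    if name == "avg_max_distance":
        return average_maximal_distance(g.morphology, n_repeats=n_repeats, seed=seed)
    values, n_bins, vmax = _axis_values(g, name, edges)
    return _hist(values, n_bins, vmax)


# ---------------------------------------------------------------------------
# Sholl profiles
# ---------------------------------------------------------------------------

_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def sholl_profile(g: GeometryTables, plane: str = "xy") -> np.ndarray:
    """Sholl intersection profile of a 2D projection.

    Counts crossings of the projected skeleton with 36 concentric circles,
    equally spaced from the soma out to the maximal projected radial
    distance.  Each sub-segment is counted once per circle whose radius
    falls between its endpoint distances.
    """
    if plane not in _PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    m = g.morphology
    cols = _PLANES[plane]
    proj = m.xyz[:, cols] - m.xyz[0, cols]
    dist = np.linalg.norm(proj, axis=1)
    r_max = dist.max()
    if r_max == 0:
        return np.zeros(N_SHOLL_STEPS, dtype=int)
    radii = r_max * np.arange(1, N_SHOLL_STEPS + 1) / N_SHOLL_STEPS
    child = np.arange(1, m.n_nodes)
    d_lo = np.minimum(dist[child], dist[m.parent[child]])
    d_hi = np.maximum(dist[child], dist[m.parent[child]])
    # circle r crossed by a sub-segment iff d_lo < r <= d_hi
    counts = (
        (d_lo[None, :] < radii[:, None]) & (radii[:, None] <= d_hi[None, :])
    ).sum(axis=1)
    return counts.astype(int)


# ---------------------------------------------------------------------------
# 3-star motifs
# ---------------------------------------------------------------------------

def _tree_distances_from(m: Morphology, center: int) -> np.ndarray:
    """Path distance from ``center`` to every node along the (undirected) tree."""
    lens = m.edge_lengths()
    adj: list[list[tuple[int, float]]] = [[] for _ in range(m.n_nodes)]
    for i in range(1, m.n_nodes):
        p = int(m.parent[i])
        adj[i].append((p, lens[i]))
        adj[p].append((i, lens[i]))
    dist = np.full(m.n_nodes, np.inf)
    dist[center] = 0.0
    stack = [center]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                stack.append(v)
    return dist


def _decile_motifs(m: Morphology, center: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-decile 3-star counts and maximal Euclidean distance from the center.

    Decile i keeps the ceil(i*10%) of nodes closest to the center by tree
    path distance.  A node of (undirected) degree d >= 3 in the induced
    subgraph contributes d - 2 motifs: a bifurcation is one 3-star, each
    further branch adds another.
    """
    dist = _tree_distances_from(m, center)
    n = m.n_nodes
    order = np.argsort(dist, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    motifs = np.zeros(10)
    max_dist = np.zeros(10)
    euclid = np.linalg.norm(m.xyz - m.xyz[center], axis=1)
    for i in range(1, 11):
        k = int(np.ceil(i * 0.1 * n))
        members = order[:k]
        in_set = np.zeros(n, dtype=bool)
        in_set[members] = True
        child = np.arange(1, n)
        both = in_set[child] & in_set[m.parent[child]]
        degree = np.zeros(n, dtype=np.int64)
        np.add.at(degree, child[both], 1)
        np.add.at(degree, m.parent[child[both]], 1)
        motifs[i - 1] = np.maximum(degree[members] - 2, 0).sum()
        max_dist[i - 1] = euclid[members].max() if k else 0.0
    return motifs, max_dist


def star_motifs(m: Morphology, centers: str = "soma", n_repeats: int = 100,
                seed: int = 0) -> np.ndarray:
    """10-vector of 3-star motif counts in nested path-distance deciles.

    ``centers="soma"`` uses the soma; ``centers="random"`` averages over
    ``n_repeats`` random center nodes drawn with a seeded generator.
    """
    if centers == "soma":
        return _decile_motifs(m, 0)[0]
    if centers != "random":
        raise ValueError(f"unknown centers {centers!r}")
    rng = np.random.default_rng(seed)
    acc = np.zeros(10)
    for _ in range(n_repeats):
        c = int(rng.integers(m.n_nodes))
        acc += _decile_motifs(m, c)[0]
    return acc / n_repeats


def average_maximal_distance(m: Morphology, n_repeats: int = 100,
                             seed: int = 0) -> np.ndarray:
    """Per-decile maximal Euclidean distance from random centers, averaged."""
    rng = np.random.default_rng(seed)
    acc = np.zeros(10)
    for _ in range(n_repeats):
        c = int(rng.integers(m.n_nodes))
        acc += _decile_motifs(m, c)[1]
    return acc / n_repeats


# ---------------------------------------------------------------------------
# 2D distributions
# ---------------------------------------------------------------------------

_2D_SPECS = {
    # name -> (value axis, conditioning axis, node set)
    "branch_angles_x_branch_orders": ("branch_angles", "branch_orders"),
    "branch_angles_x_path_dist": ("branch_angles", "path_dist"),
    "path_angles_x_branch_orders": ("path_angles", "branch_orders"),
    "path_angles_x_path_dist": ("path_angles", "path_dist"),
    "thickness_x_branch_orders": ("thickness", "branch_orders"),
    "thickness_x_path_dist": ("thickness", "path_dist"),
}


def _paired_values(g: GeometryTables, name: str, edges: dict):
    """Aligned (value, conditioner) samples for one 2D distribution."""
    nodes = g.nodes
    value_axis, cond_axis = _2D_SPECS[name]
    if value_axis == "branch_angles":
        # one sample per daughter pair, conditioned at the branch point
        vals, conds_order, conds_dist = [], [], []
        m = g.morphology
        ch = m.children()
        k = 0
        for bp in g.branch_points["node"]:
            n_pairs = len(ch[bp]) * (len(ch[bp]) - 1) // 2
            for _ in range(n_pairs):
                vals.append(g.branch_angles[k])
                conds_order.append(nodes["branch_order"].iloc[bp])
                conds_dist.append(nodes["path_dist"].iloc[bp])
                k += 1
        value = np.array(vals)
        cond = np.array(conds_order if cond_axis == "branch_orders" else conds_dist)
        vmax, n_bins = 180.0, 20
    elif value_axis == "path_angles":
        sel = nodes["path_angle"].notna().to_numpy()
        value = nodes["path_angle"].to_numpy()[sel]
        cond = nodes[
            "branch_order" if cond_axis == "branch_orders" else "path_dist"
        ].to_numpy()[sel]
        vmax, n_bins = 180.0, 20
    elif value_axis == "thickness":
        sel = (nodes["kind"] != SOMA).to_numpy()
        value = nodes["radius"].to_numpy()[sel]
        cond = nodes[
            "branch_order" if cond_axis == "branch_orders" else "path_dist"
        ].to_numpy()[sel]
        vmax, n_bins = edges["max_radius"], 30
    else:  # pragma: no cover
        raise ValueError(name)
    cond_max = (float(edges["max_branch_order"]) if cond_axis == "branch_orders"
                else edges["max_neurite_length"])
    return value, cond, n_bins, vmax, cond_max


def distribution_2d(g: GeometryTables, name: str, edges: dict) -> np.ndarray:
    """A 2D morphometric distribution, flattened row-major.

    Binning along each axis matches the corresponding 1D distribution
    (angles: 20 bins over [0, 180]; thickness: 30 bins; path distance /
    branch order: 20 bins to the dataset maximum), so the value-axis marginal
    of the 2D histogram reproduces the 1D histogram exactly.
    """
    if name not in _2D_SPECS:
        raise ValueError(f"unknown 2D distribution {name!r}")
    value, cond, n_bins, vmax, cond_max = _paired_values(g, name, edges)
    ok = np.isfinite(value) & np.isfinite(cond)
    value, cond = value[ok], cond[ok]
    if cond_max <= 0:
        cond_max = 1.0
    if vmax <= 0:
        vmax = 1.0
    h, _, _ = np.histogram2d(
        np.clip(value, 0, vmax), np.clip(cond, 0, cond_max),
        bins=(n_bins, 20), range=((0, vmax), (0, cond_max)),
    )
    return h.astype(float).ravel()
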