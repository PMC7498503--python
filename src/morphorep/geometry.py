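"""Per-node, per-branch-point and per-segment geometry of a reconstruction.

All angle quantities are reported in degrees within [0, 180].  Conventions:

* **Centrifugal branch order**: the number of branch points passed when
  tracing from a node back to the soma, the node itself excluded.  The soma
  has order 0, a branch point carries the order of its parent-side branch,
  and its daughters carry order + 1.  The soma is never counted as a branch
  point, even when several stems leave it.
* **Path angle**: the angle between two consecutive sub-segments at a
  pass-through node, measured between direction vectors — a straight
  continuation scores 0 degrees.  (The opposite convention, 180 for straight,
  exists in the literature; this module uses the direction-vector one.)
* **Branch angle**: for each pair of daughter sub-segments meeting at a
  branch point, the angle between their direction vectors.
* **Root angle**: per segment, the angle between the segment chord
  (end - start) and the outward radial direction (end - soma); a segment
  growing straight away from the soma scores 0.
* **Euler root angles**: the rotation taking the outward radial direction
  onto the segment chord, decomposed into extrinsic rotations about the
  fixed x, y, z axes; magnitudes reported in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .swc import AXON, DENDRITE, SOMA, Morphology, segments

MODALITIES = ("full", "axon", "dendrite")


class EmptyModalityError(ValueError):
    """The requested compartment has no nodes in this cell."""


def modality_subtree(m: Morphology, modality: str) -> Morphology:
    """Induced subtree of one compartment kind; the soma stays as root.

    Nodes are kept when their compartment matches and their path to the soma
    runs through matching nodes only.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if modality == "full":
        return m
    want = AXON if modality == "axon" else DENDRITE
    keep = np.zeros(m.n_nodes, dtype=bool)
    keep[0] = True  # soma root
    for i in range(1, m.n_nodes):
        p = int(m.parent[i])
        keep[i] = keep[p] and (m.kind[i] == want or m.kind[i] == SOMA)
    keep[0] = True
    idx = np.flatnonzero(keep)
    if len(idx) <= 1:
        raise EmptyModalityError(f"empty modality {modality!r}")
    new_of = {int(old): j for j, old in enumerate(idx)}
    parent = np.array(
        [-1 if m.parent[old] == -1 else new_of[int(m.parent[old])] for old in idx]
    )
    return Morphology(
        m.ids[idx], m.kind[idx], m.xyz[idx], m.radius[idx], parent,
        metadata=dict(m.metadata),
    )


def branch_orders(m: Morphology) -> np.ndarray:
    """Centrifugal branch order per node (soma = 0)."""
    deg = m.out_degree()
    is_bp = deg >= 2
    is_bp[0] = False
    order = np.zeros(m.n_nodes, dtype=np.int64)
    for i in range(1, m.n_nodes):
        p = int(m.parent[i])
        order[i] = order[p] + (1 if is_bp[p] else 0)
    return order


def _angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle in degrees between row vectors, safe against rounding."""
    un = u / np.linalg.norm(u, axis=-1, keepdims=True)
    vn = v / np.linalg.norm(v, axis=-1, keepdims=True)
    dots = np.clip(np.sum(un * vn, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


@dataclass
class GeometryTables:
    """Geometry queries the feature modules consume.

    nodes: one row per node — kind, x/y/z, radius, branch_order,
    path_dist (to soma, um), radial_dist (Euclidean to soma, um), path_angle
    (deg, NaN where undefined).
    branch_points: one row per branch point — node, out_degree;
    ``branch_angles`` holds all pairwise daughter angles flattened.
    segments_table: one row per segment — path_length, euclidean, tortuosity,
    kind (intermediate/terminal), root_angle, euler_alpha/beta/gamma.
    """

    morphology: Morphology
    nodes: pd.DataFrame
    branch_points: pd.DataFrame
    branch_angles: np.ndarray
    segments_table: pd.DataFrame

    @property
    def n_tips(self) -> int:
        return len(self.morphology.tips())

    @property
    def n_branch_points(self) -> int:
        return len(self.branch_points)


def geometry_tables(m: Morphology, modality: str = "full") -> GeometryTables:
    """Compute every per-node / per-branch-point / per-segment quantity."""
    sub = modality_subtree(m, modality)
    n = sub.n_nodes
    xyz = sub.xyz
    soma = xyz[0]
    ch = sub.children()
    deg = sub.out_degree()
    order = branch_orders(sub)
    path_dist = sub.path_distances()
    radial = np.linalg.norm(xyz - soma, axis=1)

    # path angles at pass-through nodes (exactly one child, non-root)
    path_angle = np.full(n, np.nan)
    mid = [i for i in range(1, n) if deg[i] == 1]
    if mid:
        mid_a = np.array(mid)
        par = sub.parent[mid_a]
        kid = np.array([ch[i][0] for i in mid])
        path_angle[mid_a] = _angles_deg(xyz[mid_a] - xyz[par], xyz[kid] - xyz[mid_a])

    # branch angles: pairwise between daughter sub-segments
    bp_rows, all_angles = [], []
    for i in range(1, n):
        if deg[i] >= 2:
            bp_rows.append((i, int(deg[i])))
            dirs = xyz[ch[i]] - xyz[i]
            for a in range(len(dirs)):
                for b in range(a + 1, len(dirs)):
                    all_angles.append(float(_angles_deg(dirs[a], dirs[b])))
    branch_points = pd.DataFrame(bp_rows, columns=["node", "out_degree"])
    branch_angles = np.array(all_angles)

    # per-segment table
    seg_rows = []
    for seg in segments(sub):
        pts = xyz[seg]
        plen = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        chord = pts[-1] - pts[0]
        euc = float(np.linalg.norm(chord))
        end = seg[-1]
        terminal = deg[end] == 0
        tort = plen / euc if euc > 0 else np.inf
        radial_dir = pts[-1] - soma
        if np.linalg.norm(radial_dir) > 0 and euc > 0:
            root_angle = float(_angles_deg(chord, radial_dir))
            alpha, beta, gamma = _euler_root_angles(radial_dir, chord)
        else:
            root_angle, alpha, beta, gamma = np.nan, np.nan, np.nan, np.nan
        seg_rows.append(
            dict(
                start=int(seg[0]), end=int(end),
                path_length=plen, euclidean=euc, tortuosity=tort,
                kind="terminal" if terminal else "intermediate",
                branch_order=int(order[end]),
                root_angle=root_angle,
                euler_alpha=alpha, euler_beta=beta, euler_gamma=gamma,
            )
        )
    segments_table = pd.DataFrame(
        seg_rows,
        columns=["start", "end", "path_length", "euclidean", "tortuosity",
                 "kind", "branch_order", "root_angle",
                 "euler_alpha", "euler_beta", "euler_gamma"],
    )

    nodes = pd.DataFrame(
        dict(
            kind=sub.kind, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2],
            radius=sub.radius, branch_order=order,
            path_dist=path_dist, radial_dist=radial, path_angle=path_angle,
        )
    )
    return GeometryTables(sub, nodes, branch_points, branch_angles, segments_table)


def _euler_root_angles(radial_dir: np.ndarray, chord: np.ndarray) -> tuple:
    """Extrinsic x/y/z Euler decomposition of the radial-to-chord rotation."""
    u = radial_dir / np.linalg.norm(radial_dir)
    v = chord / np.linalg.norm(chord)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    if s < 1e-12:
        if c > 0:
            return 0.0, 0.0, 0.0
        # antiparallel: rotate 180 deg about any axis orthogonal to u
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.pi * axis)
    else:
        rot = Rotation.from_rotvec(np.arctan2(s, c) * axis / s)
    angles = np.abs(rot.as_euler("xyz", degrees=True))
    return float(angles[0]), float(angles[1]), float(angles[2])
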