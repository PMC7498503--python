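"""SWC reconstructions: parsing, validation, and the preprocessing chain.

A reconstruction is a rooted tree of 3D points ("nodes"), each carrying a
compartment type (1 soma, 2 axon, 3 dendrite), a radius and a parent pointer.
The straight line between a node and its parent is a *sub-segment*; a neurite
path from one branch point (or the soma) to the next branch point or tip is a
*segment* (also called a branch).

Coordinates are micrometres throughout.  By convention x is the slice width,
y the slice depth (the microscope viewing axis) and z the cortical or retinal
depth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial import ConvexHull, QhullError

SOMA, AXON, DENDRITE = 1, 2, 3
_VALID_KINDS = (SOMA, AXON, DENDRITE)

KIND_NAMES = {"soma": SOMA, "axon": AXON, "dendrite": DENDRITE}


class SWCError(ValueError):
    """Malformed SWC content or an invalid tree structure."""


@dataclass
class Morphology:
    """A single neuron reconstruction as parallel node arrays.

    ``parent`` stores array *indices* (-1 for the root); original SWC ids are
    kept in ``ids`` so that files round-trip.  Nodes are stored in topological
    order: a parent always precedes its children.
    """

    ids: np.ndarray          # (n,) int
    kind: np.ndarray         # (n,) int in {1, 2, 3}
    xyz: np.ndarray          # (n, 3) float, micrometres
    radius: np.ndarray       # (n,) float, micrometres
    parent: np.ndarray       # (n,) int, index into arrays, -1 = root
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.kind = np.asarray(self.kind, dtype=np.int8)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        validate(self)

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def out_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.parent[self.parent >= 0], 1)
        return deg

    def tips(self) -> np.ndarray:
        """Indices of leaf nodes (no children), the root excluded."""
        deg = self.out_degree()
        mask = deg == 0
        mask[self.root] = False
        return np.flatnonzero(mask)

    def branch_points(self) -> np.ndarray:
        """Indices of non-root nodes with two or more children."""
        deg = self.out_degree()
        mask = deg >= 2
        mask[self.root] = False
        return np.flatnonzero(mask)

    def edge_lengths(self) -> np.ndarray:
        """Length of the sub-segment above each node (0 at the root)."""
        out = np.zeros(self.n_nodes)
        nz = self.parent >= 0
        out[nz] = np.linalg.norm(self.xyz[nz] - self.xyz[self.parent[nz]], axis=1)
        return out

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def path_distances(self) -> np.ndarray:
        """Cumulative path length from the root to every node."""
        lens = self.edge_lengths()
        dist = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):  # topological order
            p = self.parent[i]
            if p >= 0:
                dist[i] = dist[p] + lens[i]
        return dist

    def copy(self, **meta) -> "Morphology":
        m = replace(
            self,
            ids=self.ids.copy(),
            kind=self.kind.copy(),
            xyz=self.xyz.copy(),
            radius=self.radius.copy(),
            parent=self.parent.copy(),
            metadata={**self.metadata, **meta},
        )
        return m


def validate(m: Morphology) -> None:
    n = m.n_nodes
    if n == 0:
        raise SWCError("empty morphology")
    shapes = (len(m.kind), len(m.xyz), len(m.radius), len(m.parent))
    if any(s != n for s in shapes):
        raise SWCError("node arrays have inconsistent lengths")
    roots = np.flatnonzero(m.parent == -1)
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root, found {len(roots)}")
    if ((m.parent >= n) | (m.parent < -1)).any():
        raise SWCError("parent index out of range")
    bad = ~np.isin(m.kind, _VALID_KINDS)
    if bad.any():
        raise SWCError(
            f"unsupported node type {int(m.kind[bad][0])} at id {int(m.ids[bad][0])}"
            " (expected 1 soma, 2 axon or 3 dendrite)"
        )
    if (m.radius < 0).any():
        raise SWCError("negative radius")
    # topological order doubles as the acyclicity/connectivity check
    order_ok = m.parent < np.arange(n)
    if not order_ok.all():
        raise SWCError("nodes are not in topological order (cycle or forward reference)")


def parse_swc(text: str, **metadata) -> Morphology:
    """Parse 7-column SWC content (``#`` starts a comment line).

    Ids need not be consecutive; space- and tab-delimited files are both
    accepted; the root's parent is encoded as -1.  A row whose parent id does
    not occur in the file, more than one root, or a cycle raise
    :class:`SWCError`.
    """
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            kind = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            pid = int(parts[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from None
        rows.append((nid, kind, x, y, z, r, pid))
    if not rows:
        raise SWCError("no data rows in SWC content")

    id_to_row = {r[0]: i for i, r in enumerate(rows)}
    if len(id_to_row) != len(rows):
        raise SWCError("duplicate node ids")
    for nid, _, _, _, _, _, pid in rows:
        if pid != -1 and pid not in id_to_row:
            raise SWCError(f"node {nid} references missing parent id {pid}")

    # re-order topologically (children after parents); detects cycles
    children: dict[int, list[int]] = {i: [] for i in range(len(rows))}
    roots = []
    for i, (nid, *_rest, pid) in enumerate(rows):
        if pid == -1:
            roots.append(i)
        else:
            children[id_to_row[pid]].append(i)
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root (parent -1), found {len(roots)}")
    already_topological = all(
        r[6] == -1 or id_to_row[r[6]] < i for i, r in enumerate(rows)
    )
    if already_topological:
        order = list(range(len(rows)))
    else:
        order = []
        stack = [roots[0]]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(children[i]))
    if len(order) != len(rows):
        raise SWCError("cycle detected: some nodes are unreachable from the root")

    pos_of = {old: new for new, old in enumerate(order)}
    rows = [rows[i] for i in order]
    ids = np.array([r[0] for r in rows])
    kind = np.array([r[1] for r in rows])
    xyz = np.array([[r[2], r[3], r[4]] for r in rows])
    radius = np.array([r[5] for r in rows])
    parent = np.array(
        [-1 if r[6] == -1 else pos_of[id_to_row[r[6]]] for r in rows]
    )
    return Morphology(ids, kind, xyz, radius, parent, metadata=dict(metadata))


def write_swc(m: Morphology) -> str:
    """Serialize to 7-column SWC text."""
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for i in range(m.n_nodes):
        pid = -1 if m.parent[i] == -1 else int(m.ids[m.parent[i]])
        x, y, z = m.xyz[i]
        buf.write(
            f"{int(m.ids[i])} {int(m.kind[i])} {x:.10g} {y:.10g} {z:.10g} "
            f"{m.radius[i]:.10g} {pid}\n"
        )
    return buf.getvalue()


def load_swc(path, **metadata) -> Morphology:
    with open(path) as fh:
        return parse_swc(fh.read(), source=str(path), **metadata)


def save_swc(m: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_swc(m))


# ---------------------------------------------------------------------------
# preprocessing chain
# ---------------------------------------------------------------------------

def consolidate_soma(m: Morphology, radius_threshold: float | None = None) -> Morphology:
    """Collapse all somatic nodes into a single root node.

    If ``radius_threshold`` is given, every node with radius strictly larger
    than the threshold is first relabelled as somatic (used for reconstructions
    that lack explicit soma labels, where anything thicker than ~1 um is soma).
    The replacement node sits at the centroid of the convex hull of the
    original soma positions, with the mean soma radius; children of removed
    soma nodes are re-parented to it.
    """
    kind = m.kind.copy()
    if radius_threshold is not None:
        kind[m.radius > radius_threshold] = SOMA
    soma_idx = np.flatnonzero(kind == SOMA)
    if len(soma_idx) == 0:
        raise SWCError("no soma identifiable")
    if len(soma_idx) == 1 and m.parent[soma_idx[0]] == -1 and (kind == m.kind).all():
        return m.copy()

    pts = m.xyz[soma_idx]
    uniq = np.unique(pts, axis=0)
    try:
        hull = ConvexHull(uniq)
        verts = uniq[hull.vertices]
    except (QhullError, ValueError):
        verts = uniq  # degenerate (coincident / collinear / coplanar) somas
    centroid = verts.mean(axis=0)
    soma_radius = float(m.radius[soma_idx].mean())

    keep = np.flatnonzero(kind != SOMA)
    is_soma = kind == SOMA
    new_index = {old: i + 1 for i, old in enumerate(keep)}  # 0 = new soma
    ids = np.arange(1, len(keep) + 2)
    xyz = np.vstack([centroid, m.xyz[keep]])
    radius = np.concatenate([[soma_radius], m.radius[keep]])
    out_kind = np.concatenate([[SOMA], kind[keep]])
    parent = np.empty(len(keep) + 1, dtype=np.int64)
    parent[0] = -1
    for i, old in enumerate(keep):
        p = m.parent[old]
        if p == -1 or is_soma[p]:
            parent[i + 1] = 0
        else:
            parent[i + 1] = new_index[p]
    return Morphology(ids, out_kind, xyz, radius, parent, metadata=dict(m.metadata))


def segments(m: Morphology) -> list[np.ndarray]:
    """Decompose the tree into segments (branches).

    Each segment is the node-index path from a branch point (or the soma) down
    to the next branch point or tip, start node included.  The start node
    itself belongs to the parent-side branch.
    """
    ch = m.children()
    deg = m.out_degree()
    root = m.root
    starts = [root] if deg[root] else []
    starts += [i for i in range(m.n_nodes) if i != root and deg[i] >= 2]
    segs = []
    for s in starts:
        for c in ch[s]:
            path = [s, c]
            node = c
            while deg[node] == 1:
                node = ch[node][0]
                path.append(node)
            segs.append(np.array(path))
    return segs


def harmonize_branch_types(m: Morphology) -> Morphology:
    """Make compartment labels consistent within each branch.

    Each branch's nodes are set to the majority type over its sub-segments
    (ties resolve to axon); the soma root is exempt.
    """
    kind = m.kind.copy()
    root = m.root
    for seg in segments(m):
        votes = m.kind[seg[1:]]  # sub-segment type = type of the child node
        votes = votes[votes != SOMA]
        if len(votes) == 0:
            continue
        n_axon = int((votes == AXON).sum())
        n_dend = int((votes == DENDRITE).sum())
        winner = AXON if n_axon >= n_dend else DENDRITE
        targets = seg[1:]
        targets = targets[targets != root]
        kind[targets] = np.where(kind[targets] == SOMA, kind[targets], winner)
    out = m.copy()
    out.kind = kind
    return out


def resample(m: Morphology, spacing: float = 1.0) -> Morphology:
    """Resample the neurites to (at most) ``spacing``-spaced nodes.

    Every sub-segment of length L is subdivided into ceil(L / spacing) equal
    straight pieces by linear interpolation, so all original nodes (soma,
    branch points, tips and trace points) are retained exactly, consecutive
    nodes are at most ``spacing`` apart, path length is preserved, and the
    operation is an exact fixed point on already-resampled morphologies.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    new_xyz: list[np.ndarray] = [m.xyz[0]]
    new_kind = [int(m.kind[0])]
    new_radius = [float(m.radius[0])]
    new_parent = [-1]
    new_of = {0: 0}

    for i in range(1, m.n_nodes):
        p = int(m.parent[i])
        a, b = m.xyz[p], m.xyz[i]
        length = float(np.linalg.norm(b - a))
        n_iv = max(1, int(np.ceil(length / spacing - 1e-9)))
        prev = new_of[p]
        for j in range(1, n_iv + 1):
            t = j / n_iv
            new_xyz.append(b if j == n_iv else a + t * (b - a))
            new_kind.append(int(m.kind[i]))
            new_radius.append(float((1 - t) * m.radius[p] + t * m.radius[i]))
            new_parent.append(prev)
            prev = len(new_xyz) - 1
        new_of[i] = prev

    n = len(new_xyz)
    return Morphology(
        np.arange(1, n + 1),
        np.array(new_kind),
        np.array(new_xyz),
        np.array(new_radius),
        np.array(new_parent),
        metadata=dict(m.metadata),
    )


def smooth_depth_axis(m: Morphology, window: float = 21, order: int = 3) -> Morphology:
    """Savitzky-Golay smoothing of the slice-depth (y) coordinate.

    Biocytin tracings occasionally contain sudden jumps along the microscope
    viewing axis.  After resampling to 1 um spacing a window in micrometres
    equals a window in samples, so the filter is applied per unbranched run of
    nodes; runs shorter than the window are left untouched.  x and z are never
    modified.
    """
    win = int(round(window))
    if win <= order:
        raise ValueError("window must exceed the polynomial order")
    y = m.xyz[:, 1].copy()
    for seg in segments(m):
        if len(seg) < win:
            continue
        smoothed = savgol_filter(m.xyz[seg, 1], win, order)
        y[seg[1:]] = smoothed[1:]  # the start node belongs to the parent run
    out = m.copy()
    out.xyz = m.xyz.copy()
    out.xyz[:, 1] = y
    return out


def center(m: Morphology, mode: str = "soma", z_offset: float = 0.0) -> Morphology:
    """Translate the cell so the soma defines the origin.

    mode ``soma``: soma to (0, 0, 0).  mode ``soma_xy_with_z_offset``: soma to
    x = y = 0 and all z shifted by ``z_offset`` (used for retinal bipolar
    cells, where z = 0 is the onset of the inner plexiform layer rather than
    the soma).
    """
    soma = m.xyz[m.root]
    if mode == "soma":
        shift = -soma
    elif mode == "soma_xy_with_z_offset":
        shift = np.array([-soma[0], -soma[1], z_offset])
    else:
        raise ValueError(f"unknown centering mode {mode!r}")
    out = m.copy()
    out.xyz = m.xyz + shift
    return out


def preprocess(
    m: Morphology,
    mode: str = "cortical",
    spacing: float = 1.0,
    savgol_window: float = 21,
    soma_radius_threshold: float | None = None,
    z_offset: float = 0.0,
) -> Morphology:
    """The full preprocessing chain for one reconstruction.

    cortical: consolidate soma, harmonize branch types, soma-center, resample,
    smooth the slice-depth axis.  bipolar: threshold-relabel somas (1 um by
    default), consolidate, harmonize, center x/y on the soma with a z offset;
    no resampling or smoothing.
    """
    if mode == "cortical":
        m = consolidate_soma(m, soma_radius_threshold)
        m = harmonize_branch_types(m)
        m = center(m, "soma")
        m = resample(m, spacing)
        m = smooth_depth_axis(m, savgol_window)
    elif mode == "bipolar":
        thr = 1.0 if soma_radius_threshold is None else soma_radius_threshold
        m = consolidate_soma(m, thr)
        m = harmonize_branch_types(m)
        m = center(m, "soma_xy_with_z_offset", z_offset)
    else:
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    return m
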