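"""Topological persistence of neurite trees, and Gaussian persistence images.

A persistence diagram summarizes the branching structure of a rooted tree
under a *filter function* f mapping nodes to reals (f(soma) = 0 for all four
filters used here).  Starting from the tips and moving toward the soma, each
branch is born at its tip with birth = f(tip); at every branch point all
incoming branches except the one with the largest birth are killed, their
death being the branch point's filter value ("elder rule").  The overall
survivor dies at the soma with death 0, so the diagram holds exactly one
(birth, death) pair per tip.

Birth ties at a branch point are resolved deterministically: the branch
whose tip has the smaller node index survives.  At a multifurcation all
non-surviving branches die simultaneously.

Diagrams are rendered into fixed-shape features as Gaussian persistence
images: a 2D kernel density estimate of the (birth, death) points on a
100 x 100 grid over [0, max_birth] x [0, max_death] (dataset-level maxima),
or a 1D density of the lifetimes (birth - death) sampled at 100 points on
[0, max_birth].  scipy's gaussian_kde with Scott's bandwidth rule is used;
degenerate diagrams (too few points or singular covariance) fall back to a
sum of isotropic Gaussians with bandwidth 1% of max_birth, which is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .geometry import branch_orders, modality_subtree
from .swc import Morphology

logger = logging.getLogger(__name__)

FILTER_NAMES = ("radial_distance", "path_length", "branch_order", "z_projection")

IMAGE_SIZE = 100
FALLBACK_BANDWIDTH_FRACTION = 0.01


def filter_values(m: Morphology, filter_name: str) -> np.ndarray:
    """Evaluate one of the four filter functions at every node.

    radial_distance: Euclidean distance to the soma; path_length: path
    distance to the soma along the tree; branch_order: centrifugal branch
    order; z_projection: signed z difference to the soma.  All are 0 at the
    soma.
    """
    if filter_name == "radial_distance":
        return np.linalg.norm(m.xyz - m.xyz[0], axis=1)
    if filter_name == "path_length":
        return m.path_distances()
    if filter_name == "branch_order":
        return branch_orders(m).astype(float)
    if filter_name == "z_projection":
        return m.xyz[:, 2] - m.xyz[0, 2]
    raise ValueError(f"unknown filter {filter_name!r}")


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death) pairs, one per neurite tip."""

    pairs: np.ndarray        # (n_tips, 2)
    filter_name: str
    modality: str = "full"

    @property
    def births(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        return self.pairs[:, 1]

    def lifetimes(self) -> np.ndarray:
        return self.births - self.deaths

    def __len__(self) -> int:
        return len(self.pairs)


def compute_diagram(m: Morphology, filter_name: str,
                    modality: str = "full") -> PersistenceDiagram:
    """Persistence diagram of one cell under one filter (elder rule)."""
    sub = modality_subtree(m, modality)
    f = filter_values(sub, filter_name)
    ch = sub.children()
    deg = sub.out_degree()
    # (birth, tip index) of the branch surviving through each node
    surviving: list[tuple[float, int] | None] = [None] * sub.n_nodes
    pairs = []
    for i in range(sub.n_nodes - 1, -1, -1):  # reverse topological order
        if deg[i] == 0:
            surviving[i] = (float(f[i]), i)
            continue
        cands = [surviving[c] for c in ch[i]]
        # survivor: largest birth, ties to the smaller tip index
        winner = max(range(len(cands)),
                     key=lambda k: (cands[k][0], -cands[k][1]))
        for k, (birth, _tip) in enumerate(cands):
            if k != winner:
                pairs.append((birth, float(f[i])))
        surviving[i] = cands[winner]
    pairs.append((surviving[0][0], float(f[0])))  # overall survivor dies at the soma
    out = np.array(pairs, dtype=float)
    return PersistenceDiagram(out[np.lexsort((out[:, 1], -out[:, 0]))],
                              filter_name, modality)


def _fallback_density(points: np.ndarray, grid: np.ndarray,
                      bandwidth: float) -> np.ndarray:
    """Sum of isotropic Gaussians; used when a KDE cannot be fitted."""
    d2 = np.zeros((grid.shape[1],))
    out = np.zeros(grid.shape[1])
    for p in points.T:
        d2 = ((grid - p[:, None]) ** 2).sum(axis=0)
        out += np.exp(-0.5 * d2 / bandwidth ** 2)
    norm = len(points.T) * (2 * np.pi) ** (grid.shape[0] / 2) * bandwidth ** grid.shape[0]
    return out / norm


def image_2d(d: PersistenceDiagram, max_birth: float,
             max_death: float) -> np.ndarray:
    """2D Gaussian persistence image on a 100 x 100 grid.

    Grid rows index birth in [0, max_birth], columns death in [0, max_death];
    flatten row-major for a 10,000-feature vector.
    """
    if max_birth <= 0 or max_death <= 0:
        raise ValueError("image rectangle maxima must be positive")
    bx = np.linspace(0, max_birth, IMAGE_SIZE)
    dx = np.linspace(0, max_death, IMAGE_SIZE)
    bb, dd = np.meshgrid(bx, dx, indexing="ij")
    grid = np.vstack([bb.ravel(), dd.ravel()])
    pts = d.pairs.T  # (2, n)
    try:
        kde = gaussian_kde(pts)
        values = kde(grid)
    except (np.linalg.LinAlgError, ValueError):
        logger.info("image_2d: KDE not solvable for %d diagram point(s); "
                    "isotropic fallback used", len(d))
        values = _fallback_density(pts, grid,
                                   FALLBACK_BANDWIDTH_FRACTION * max_birth)
    return values.reshape(IMAGE_SIZE, IMAGE_SIZE)


def image_1d(d: PersistenceDiagram, max_birth: float) -> np.ndarray:
    """1D Gaussian density of branch lifetimes sampled at 100 points.

    Lifetimes can be negative under the radial-distance and z-projection
    filters; they are clipped to 0 (and logged) before estimation.
    """
    if max_birth <= 0:
        raise ValueError("max_birth must be positive")
    life = d.lifetimes()
    n_neg = int((life < 0).sum())
    if n_neg:
        logger.info("image_1d: %d negative lifetime(s) clipped to 0", n_neg)
        life = np.clip(life, 0, None)
    grid = np.linspace(0, max_birth, IMAGE_SIZE)
    if len(np.unique(life)) < 2:
        logger.info("image_1d: degenerate lifetimes; isotropic fallback used")
        return _fallback_density(life[None, :], grid[None, :],
                                 FALLBACK_BANDWIDTH_FRACTION * max_birth)
    kde = gaussian_kde(life)
    return kde(grid)


def fit_image_maxima(diagrams) -> tuple[float, float]:
    """Dataset-level (max_birth, max_death) over a collection of diagrams."""
    diagrams = list(diagrams)
    if not diagrams:
        raise ValueError("need at least one diagram")
    max_birth = max(float(d.births.max()) for d in diagrams)
    max_death = max(float(d.deaths.max()) for d in diagrams)
    return max_birth, max(max_death, 1e-9)
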