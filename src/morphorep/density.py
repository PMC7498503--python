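"""Neurite density maps: dense skeleton sampling, normalization, binning.

A density map is a histogram of points sampled every 25 nm along the
skeleton, after min-max normalization of the coordinates with dataset-level
ranges.  1D maps project onto a single axis (100 bins), 2D maps onto a
coordinate plane (100 x 100 bins); both span [-0.1, 1.1] per normalized axis
and are smoothed with an 11-bin (or 11 x 11) Gaussian kernel of sigma = 2
bins, truncated and renormalized to unit sum.  Normalized coordinates
falling outside the span (possible when fixed ranges narrower than the data
are supplied) are clipped into the boundary bins rather than dropped, so
total mass stays interpretable; the clipped count is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve

from .geometry import modality_subtree
from .swc import Morphology

logger = logging.getLogger(__name__)

AXIS_SPECS = ("x", "y", "z", "xy", "xz", "yz")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

N_BINS = 100
SPAN = (-0.1, 1.1)
KERNEL_SIZE = 11
KERNEL_SIGMA = 2.0


@dataclass
class PointCloud:
    """Densely sampled skeleton points of one cell (um)."""

    points: np.ndarray          # (n, 3)
    modality: str = "full"
    dataset: str = ""


def sample_points(m: Morphology, spacing: float = 0.025,
                  modality: str = "full") -> PointCloud:
    """Sample equidistant points along every neurite of one compartment.

    Each sub-segment of length L contributes ceil(L / spacing) interior steps
    (its far endpoint included); the soma contributes one point, so points
    cover the piecewise-linear skeleton with consecutive spacing <= 25 nm.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    sub = modality_subtree(m, modality)
    chunks = [sub.xyz[:1]]
    for i in range(1, sub.n_nodes):
        a = sub.xyz[sub.parent[i]]
        b = sub.xyz[i]
        length = float(np.linalg.norm(b - a))
        n_iv = max(1, int(np.ceil(length / spacing - 1e-12)))
        t = np.arange(1, n_iv + 1)[:, None] / n_iv
        chunks.append(a + t * (b - a))
    return PointCloud(np.vstack(chunks), modality=modality,
                      dataset=sub.metadata.get("dataset", ""))


@dataclass
class NormalizationRanges:
    """Per-axis min/max used to normalize point clouds of one dataset."""

    mins: np.ndarray  # (3,)
    maxs: np.ndarray  # (3,)

    def normalize(self, points: np.ndarray) -> np.ndarray:
        return (points - self.mins) / (self.maxs - self.mins)

    def to_dict(self) -> dict:
        return {"min": self.mins.tolist(), "max": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationRanges":
        return cls(np.asarray(d["min"], float), np.asarray(d["max"], float))


def fit_ranges(clouds) -> NormalizationRanges:
    """Per-axis min/max over a collection of point clouds (one dataset)."""
    clouds = list(clouds)
    if not clouds:
        raise ValueError("need at least one point cloud")
    pts = np.vstack([c.points for c in clouds])
    mins, maxs = pts.min(axis=0), pts.max(axis=0)
    for k, name in enumerate("xyz"):
        if maxs[k] <= mins[k]:
            raise ValueError(f"degenerate normalization axis {name!r} (max == min)")
    return NormalizationRanges(mins, maxs)


def save_ranges(ranges_by_key: dict, path) -> None:
    """Serialize a {dataset -> modality -> NormalizationRanges} config."""
    out = {ds: {mod: r.to_dict() for mod, r in mods.items()}
           for ds, mods in ranges_by_key.items()}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)


def load_ranges(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    return {ds: {mod: NormalizationRanges.from_dict(d) for mod, d in mods.items()}
            for ds, mods in raw.items()}


def gaussian_kernel_1d(size: int = KERNEL_SIZE,
                       sigma: float = KERNEL_SIGMA) -> np.ndarray:
    """Truncated unit-sum Gaussian kernel."""
    x = np.arange(size) - (size - 1) / 2
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def density_map(cloud: PointCloud, ranges: NormalizationRanges,
                axis_spec: str, smooth: bool = True) -> np.ndarray:
    """Binned (and by default Gaussian-smoothed) projected density.

    Returns a 100-vector for a single axis or a 100 x 100 array for a plane
    (first axis of the spec indexes rows).  The raw histogram is available
    with ``smooth=False``.
    """
    if axis_spec not in AXIS_SPECS:
        raise ValueError(f"unknown axis spec {axis_spec!r}")
    norm = ranges.normalize(cloud.points)
    cols = [_AXIS_INDEX[a] for a in axis_spec]
    vals = norm[:, cols]
    lo, hi = SPAN
    n_clip = int(((vals < lo) | (vals > hi)).any(axis=1).sum())
    if n_clip:
        logger.info("density_map: %d point(s) outside [-0.1, 1.1] clipped "
                    "into boundary bins", n_clip)
        vals = np.clip(vals, lo, np.nextafter(hi, lo))
    idx = _bin_indices(vals)
    if len(cols) == 1:
        hist = np.bincount(idx[:, 0], minlength=N_BINS).astype(float)
        if smooth:
            hist = convolve(hist, gaussian_kernel_1d(), mode="same",
                            method="direct")
        return hist
    flat = idx[:, 0] * N_BINS + idx[:, 1]
    hist = np.bincount(flat, minlength=N_BINS * N_BINS).astype(float)
    hist = hist.reshape(N_BINS, N_BINS)
    if smooth:
        k1 = gaussian_kernel_1d()
        hist = convolve(hist, np.outer(k1, k1), mode="same", method="direct")
    return hist


def _bin_indices(vals: np.ndarray) -> np.ndarray:
    """Half-open floor binning: index = floor((v - lo) / width).

    A tiny epsilon keeps values lying exactly on a bin edge in the upper
    bin despite floating-point division error.
    """
    lo, hi = SPAN
    width = (hi - lo) / N_BINS
    idx = np.floor((vals - lo) / width + 1e-9).astype(int)
    return np.clip(idx, 0, N_BINS - 1)


def featurize_density(m: Morphology, ranges: NormalizationRanges,
                      axis_spec: str, modality: str = "full",
                      spacing: float = 0.025) -> np.ndarray:
    """Density-map feature vector of one cell: the map flattened row-major
    (10,000 features for a plane, 100 for an axis)."""
    cloud = sample_points(m, spacing=spacing, modality=modality)
    return density_map(cloud, ranges, axis_spec).ravel()
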