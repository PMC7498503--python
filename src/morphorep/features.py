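"""Dataset-level featurization: turn a population of cells into a
FeatureMatrix under a named representation.

Representation names:

* ``density:<axes>`` — 1D or 2D neurite density map, axes in
  {x, y, z, xy, xz, yz} (normalization ranges fitted on the population
  unless supplied);
* ``morphometrics`` — the 24-statistic vector (z-scored downstream);
* ``dist:<name>`` — one of the 1D morphometric distributions;
* ``dist2d:<name>`` — one of the 2D morphometric distributions;
* ``persistence2d:<filter>`` / ``persistence1d:<filter>`` — Gaussian
  persistence images under one of the four filter functions.

Dataset-level quantities (normalization ranges, histogram maxima,
persistence-image rectangles) are fitted over the supplied population,
mirroring how per-dataset ranges are fixed before per-cell featurization.
"""

from __future__ import annotations

import numpy as np

from . import density, morphometrics, persistence
from .classify import FeatureMatrix
from .geometry import geometry_tables
from .swc import Morphology

REPRESENTATION_EXAMPLES = (
    "density:z", "density:xz", "morphometrics", "dist:branch_angles",
    "dist2d:path_angles_x_path_dist", "persistence2d:z_projection",
    "persistence1d:path_length",
)


def _labels(cells: list[Morphology], labels=None) -> np.ndarray:
    if labels is not None:
        return np.asarray(labels)
    return np.asarray([m.metadata.get("label", "") for m in cells])


def featurize_cells(cells: list[Morphology], rep: str, modality: str = "full",
                    labels=None, ranges: density.NormalizationRanges | None = None,
                    edges: dict | None = None, seed: int = 0,
                    density_spacing: float = 0.025) -> FeatureMatrix:
    """Feature matrix of one representation for a population of cells."""
    labels = _labels(cells, labels)
    kind = "pca"

    if rep.startswith("density:"):
        axes = rep.split(":", 1)[1]
        clouds = [density.sample_points(m, spacing=density_spacing,
                                        modality=modality) for m in cells]
        if ranges is None:
            ranges = density.fit_ranges(clouds)
        X = np.stack([density.density_map(c, ranges, axes).ravel()
                      for c in clouds])
    elif rep == "morphometrics":
        tables = [geometry_tables(m, modality) for m in cells]
        X = np.stack([morphometrics.compute_statistics(g).to_numpy()
                      for g in tables])
        kind = "zscore"
    elif rep.startswith("dist:") or rep.startswith("dist2d:"):
        name = rep.split(":", 1)[1]
        tables = [geometry_tables(m, modality) for m in cells]
        if edges is None:
            edges = morphometrics.fit_dataset_edges(tables)
        if rep.startswith("dist2d:"):
            X = np.stack([morphometrics.distribution_2d(g, name, edges)
                          for g in tables])
        else:
            X = np.stack([morphometrics.distribution_1d(g, name, edges, seed=seed)
                          for g in tables])
    elif rep.startswith("persistence1d:") or rep.startswith("persistence2d:"):
        filter_name = rep.split(":", 1)[1]
        diagrams = [persistence.compute_diagram(m, filter_name, modality)
                    for m in cells]
        max_birth, max_death = persistence.fit_image_maxima(diagrams)
        if rep.startswith("persistence2d:"):
            X = np.stack([persistence.image_2d(d, max_birth, max_death).ravel()
                          for d in diagrams])
        else:
            X = np.stack([persistence.image_1d(d, max_birth) for d in diagrams])
    else:
        raise ValueError(f"unknown representation {rep!r}")

    return FeatureMatrix(X, labels, representation=rep, modality=modality,
                         kind=kind)


def featurizer(rep: str, modality: str = "full", **kwargs):
    """A ``cells -> FeatureMatrix`` callable (used by the truncation
    experiment, which refits dataset-level ranges per truncation grade)."""
    def run(cells: list[Morphology]) -> FeatureMatrix:
        return featurize_cells(cells, rep, modality=modality, **kwargs)
    return run
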