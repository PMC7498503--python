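"""Comparing feature representations across cell-type pairs.

The primary statistic is the mean log-loss difference between two
representations A and B over a pool of type pairs P,

    delta(A, B) = (1 / |P|) * sum_p [ loss(B, p) - loss(A, p) ],

negative when B beats A.  Because pairs sharing a type are not independent,
the standard error of delta is estimated by a jackknife across *types*: each
type tau is left out entirely (with every pair containing it), giving n
leave-one-out estimates delta_-tau and

    SE = sqrt( (n - 1) / n * sum_tau (delta_-tau - mean)^2 ),

with n the number of types.  p-values come from a two-sided z-test
z = delta / SE; they are reported unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from sklearn.covariance import MinCovDet
from sklearn.manifold import TSNE


def _pair_losses(results: pd.DataFrame) -> pd.Series:
    """pair -> mean log-loss from a tidy results frame."""
    return results.set_index("pair")["log_loss"]


def mean_delta(results_a: pd.DataFrame, results_b: pd.DataFrame) -> float:
    """Mean over pairs of loss(B, p) - loss(A, p)."""
    la, lb = _pair_losses(results_a), _pair_losses(results_b)
    if set(la.index) != set(lb.index):
        raise ValueError("result sets cover different pairs")
    return float((lb - la.reindex(lb.index)).mean())


def _types_of(pair_key: str) -> tuple[str, str]:
    a, b = pair_key.split("|")
    return a, b


def jackknife_se(results_a: pd.DataFrame, results_b: pd.DataFrame
                 ) -> tuple[float, pd.Series]:
    """Leave-one-type-out jackknife SE of delta(A, B).

    Returns (SE, delta_-tau series indexed by the left-out type).
    """
    la, lb = _pair_losses(results_a), _pair_losses(results_b)
    if set(la.index) != set(lb.index):
        raise ValueError("result sets cover different pairs")
    diff = (lb - la.reindex(lb.index))
    types = sorted({t for p in diff.index for t in _types_of(p)})
    if len(types) < 3:
        raise ValueError("jackknife across types needs at least 3 types")
    loo = {}
    for tau in types:
        keep = [p for p in diff.index if tau not in _types_of(p)]
        if not keep:
            raise ValueError(f"removing type {tau!r} leaves no pairs")
        loo[tau] = float(diff.loc[keep].mean())
    loo = pd.Series(loo)
    n = len(types)
    se = float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
    return se, loo


def z_test(delta: float, se: float) -> tuple[float, float]:
    """Two-sided z-test of delta against 0."""
    if se == 0:
        if delta == 0:
            return 0.0, 1.0
        warnings.warn("zero jackknife SE with nonzero delta; p reported as 0")
        return float(np.sign(delta) * np.inf), 0.0
    z = delta / se
    return float(z), float(2 * (1 - norm.cdf(abs(z))))


@dataclass
class DeltaComparison:
    representation_a: str
    representation_b: str
    delta: float
    se: float
    z: float
    p: float
    loo: pd.Series


def compare_representations(results: pd.DataFrame, rep_a: str, rep_b: str,
                            modality: str | None = None) -> DeltaComparison:
    """delta, jackknife SE, z and p for two representations in one frame."""
    sel = results
    if modality is not None:
        sel = sel[sel["modality"] == modality]
    ra = sel[sel["representation"] == rep_a]
    rb = sel[sel["representation"] == rep_b]
    if ra.empty or rb.empty:
        raise ValueError("missing results for one of the representations")
    delta = mean_delta(ra, rb)
    se, loo = jackknife_se(ra, rb)
    z, p = z_test(delta, se)
    return DeltaComparison(rep_a, rep_b, delta, se, z, p, loo)


def rank_features(results: pd.DataFrame, top_k: int = 5,
                  distribution_prefix: str = "dist:") -> tuple[pd.DataFrame, list]:
    """Rank representations by mean pairwise log-loss; pick the top set.

    Within each modality, representations are ranked by their mean log-loss
    across all pairs; the selection is the union of every modality's top
    ``top_k`` plus the best-performing morphometric distribution (so at
    least one distribution is always represented).  Missing representation x
    modality x pair cells raise an error listing them.
    """
    needed = ["representation", "modality", "pair", "log_loss"]
    for col in needed:
        if col not in results.columns:
            raise ValueError(f"results frame lacks column {col!r}")
    counts = results.pivot_table(index="representation", columns="modality",
                                 values="pair", aggfunc="count")
    if counts.isna().any().any() or counts.nunique().max() > 1:
        missing = counts[counts.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete results grid (e.g. for {missing})")
    ranking = (
        results.groupby(["modality", "representation"])["log_loss"]
        .mean().reset_index()
        .sort_values(["modality", "log_loss"], kind="stable")
        .reset_index(drop=True)
    )
    selected: list = []
    for _, grp in ranking.groupby("modality"):
        for rep in grp["representation"].head(top_k):
            if rep not in selected:
                selected.append(rep)
    dists = ranking[ranking["representation"].str.startswith(distribution_prefix)]
    if not dists.empty:
        overall = dists.groupby("representation")["log_loss"].mean()
        best_dist = overall.idxmin()
        if best_dist not in selected:
            selected.append(best_dist)
    return ranking, selected


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

@dataclass
class CoverageEllipse:
    """95% coverage ellipse from a robust (MCD) location/scatter fit."""

    label: str
    center: np.ndarray      # (2,)
    semi_axes: np.ndarray   # (2,) major, minor
    angle_deg: float        # orientation of the major axis


def embed(X: np.ndarray, labels: np.ndarray, perplexity: float = 50,
          seed: int = 42):
    """Exact t-SNE embedding plus per-type robust coverage ellipses.

    ``X`` must already be PCA-reduced, PC1-SD-scaled and concatenated (the
    same rule the classifier uses for combined representations).  Perplexity
    is capped below the sample count as t-SNE requires.  Types with fewer
    than 3 cells get points but no ellipse.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    perplexity = min(perplexity, (len(X) - 1) / 3)
    ts = TSNE(n_components=2, perplexity=perplexity, method="exact",
              random_state=seed, init="random")
    coords = ts.fit_transform(X)
    ellipses = []
    r2 = chi2.ppf(0.95, df=2)
    for label in np.unique(labels):
        pts = coords[labels == label]
        if len(pts) < 3:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mcd = MinCovDet(random_state=seed).fit(pts)
        evals, evecs = np.linalg.eigh(mcd.covariance_)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        semi = np.sqrt(np.maximum(evals, 0) * r2)
        angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
        ellipses.append(CoverageEllipse(str(label), mcd.location_, semi, angle))
    return coords, ellipses
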