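"""Supervised cell-type discrimination benchmark.

The benchmark asks how well a feature representation separates two (or K)
cell types with a linear readout under honest cross-validation:

* preprocessing fitted strictly on each training fold — PCA keeping the
  smallest number of components that explain >= 90% of the training
  variance, all components then divided by the SD of the first training PC
  (so differently sized representations live on a common scale and can be
  concatenated); morphometric-statistics vectors are z-scored instead;
* elastic-net (regularized) logistic regression with the L1/L2 mixing
  parameter alpha fixed at 0.5, the penalty strength lambda chosen on an
  inner 3-fold CV by the one-standard-error rule (the largest lambda whose
  mean inner log-loss is within one SE of the minimum), over a path of 100
  log-spaced lambdas from the data-derived lambda_max down to 1e-3 of it;
* an outer 10-times-repeated stratified 5-fold CV (random_state 17), scored
  by test-set log-loss, accuracy, macro-F1 and Matthews correlation.

Chance level is ln 2 for a balanced pair and ln K for K balanced classes.
3-nearest-neighbour and decision-tree classifiers are available as
alternative schemes (log-loss is not meaningful for them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, matthews_corrcoef
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

PROB_CLIP = 1e-15
METRIC_NAMES = ("log_loss", "accuracy", "macro_f1", "mcc")


@dataclass
class FeatureMatrix:
    """n cells x p features under one representation and modality."""

    X: np.ndarray
    labels: np.ndarray
    representation: str = ""
    modality: str = "full"
    kind: str = "pca"  # preprocessing route: "pca" | "zscore" | "none"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or len(self.X) != len(self.labels):
            raise ValueError("X must be 2D with one label per row")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite entries")

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return replace(self, X=self.X[mask], labels=self.labels[mask])


@dataclass
class CVConfig:
    """Cross-validation and solver settings (defaults are the benchmark's)."""

    n_splits: int = 5
    n_repeats: int = 10
    inner_splits: int = 3
    alpha: float = 0.5
    variance_fraction: float = 0.90
    seed: int = 17
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.n_splits < 2 or self.inner_splits < 2:
            raise ValueError("need at least 2 folds")
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance fraction must lie in (0, 1]")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class FeatureTransform:
    """Train-fold preprocessing: PCA + PC1-SD scaling, or z-scoring.

    ``kind="pca"``: keep the smallest k with cumulative explained variance
    >= the configured fraction, then divide every retained component by the
    SD of the first training PC.  ``kind="zscore"``: per-feature z-scoring
    with training moments (used for the raw morphometric-statistics vector).
    ``kind="none"``: identity.
    """

    def __init__(self, kind: str = "pca", variance_fraction: float = 0.90):
        if kind not in ("pca", "zscore", "none"):
            raise ValueError(f"unknown preprocessing kind {kind!r}")
        self.kind = kind
        self.variance_fraction = variance_fraction

    def fit(self, X: np.ndarray) -> "FeatureTransform":
        X = np.asarray(X, dtype=float)
        if self.kind == "pca":
            if np.allclose(X.var(axis=0), 0):
                raise ValueError("zero-variance training matrix")
            n_max = min(X.shape[0], X.shape[1])
            pca = PCA(n_components=n_max, svd_solver="full").fit(X)
            cum = np.cumsum(pca.explained_variance_ratio_)
            k = int(np.searchsorted(cum, self.variance_fraction - 1e-12) + 1)
            k = min(k, n_max)
            self._pca = pca
            self._k = k
            scores = pca.transform(X)[:, :k]
            self._scale = float(scores[:, 0].std(ddof=1))
            if self._scale == 0:
                self._scale = 1.0
        elif self.kind == "zscore":
            self._mean = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            self._sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "pca":
            return self._pca.transform(X)[:, : self._k] / self._scale
        if self.kind == "zscore":
            return (X - self._mean) / self._sd
        return X

    @property
    def n_components(self) -> int:
        return self._k


def preprocess_features(train: FeatureMatrix, test: FeatureMatrix,
                        config: CVConfig | None = None):
    """Fit the representation's transform on train, apply to both."""
    config = config or CVConfig()
    tf = FeatureTransform(
        kind=train.kind, variance_fraction=config.variance_fraction
    ).fit(train.X)
    tr = replace(train, X=tf.transform(train.X), kind="none")
    te = replace(test, X=tf.transform(test.X), kind="none")
    return tr, te


def combine_representations(reps: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-concatenate already-preprocessed representations."""
    if not reps:
        raise ValueError("no representations to combine")
    n = len(reps[0].X)
    for r in reps[1:]:
        if len(r.X) != n or (r.labels != reps[0].labels).any():
            raise ValueError("representations cover different rows")
    return FeatureMatrix(
        np.hstack([r.X for r in reps]), reps[0].labels,
        representation="+".join(r.representation for r in reps),
        modality=reps[0].modality, kind="none",
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def metric(name: str, y_true: np.ndarray, y_pred_or_prob: np.ndarray,
           classes: np.ndarray | None = None) -> float:
    """One of log_loss / accuracy / macro_f1 / mcc.

    ``log_loss`` expects class probabilities (columns ordered like
    ``classes``, or like sorted unique labels), clipped away from {0, 1} by
    1e-15; the others expect hard predictions.  MCC on a single-class truth
    is defined as 0 (warned).
    """
    y_true = np.asarray(y_true)
    if name == "log_loss":
        prob = np.asarray(y_pred_or_prob, dtype=float)
        if prob.ndim == 1:
            prob = np.column_stack([1 - prob, prob])
        cls = np.asarray(classes) if classes is not None else np.unique(y_true)
        idx = {c: j for j, c in enumerate(cls)}
        p_true = prob[np.arange(len(y_true)), [idx[c] for c in y_true]]
        p_true = np.clip(p_true, PROB_CLIP, 1 - PROB_CLIP)
        return float(-np.mean(np.log(p_true)))
    y_pred = np.asarray(y_pred_or_prob)
    if name == "accuracy":
        return float(np.mean(y_true == y_pred))
    if name == "macro_f1":
        labels = np.asarray(classes) if classes is not None else None
        return float(f1_score(y_true, y_pred, labels=labels,
                              average="macro", zero_division=0))
    if name == "mcc":
        if len(np.unique(y_true)) < 2:
            warnings.warn("MCC undefined for single-class truth; recorded as 0")
            return 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(matthews_corrcoef(y_true, y_pred))
    raise ValueError(f"unknown metric {name!r}")


# ---------------------------------------------------------------------------
# elastic-net path with the one-standard-error rule
# ---------------------------------------------------------------------------

def _lambda_path(X: np.ndarray, y01: np.ndarray, config: CVConfig) -> np.ndarray:
    """Descending lambda path from the data-derived lambda_max.

    lambda_max = max_j |x_j . (y - ybar)| / (n alpha) is the smallest penalty
    that zeroes every coefficient of the lasso part (the usual path anchor);
    100 log-spaced values down to 1e-3 * lambda_max.
    """
    resid = y01 - y01.mean(axis=0)
    grad = X.T @ resid
    lam_max = float(np.max(np.abs(grad)) / (len(X) * config.alpha))
    if not np.isfinite(lam_max) or lam_max <= 0:
        raise ValueError("degenerate lambda path (no association with labels)")
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                        config.n_lambda)


def _new_solver(config: CVConfig) -> LogisticRegression:
    return LogisticRegression(
        solver="saga", l1_ratio=config.alpha, warm_start=True,
        max_iter=config.max_iter, tol=1e-4, random_state=config.seed,
    )


def _path_val_losses(X_tr, y_tr, X_va, y_va, lambdas, config, classes):
    est = _new_solver(config)
    losses = np.empty(len(lambdas))
    for j, lam in enumerate(lambdas):
        est.set_params(C=1.0 / (len(X_tr) * lam))
        est.fit(X_tr, y_tr)
        losses[j] = metric("log_loss", y_va, est.predict_proba(X_va),
                           classes=est.classes_)
    return losses


def select_lambda_1se(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                      config: CVConfig) -> float:
    """Inner-CV lambda selection by the one-standard-error rule.

    Runs a stratified inner K-fold over the descending lambda path, and
    returns the largest lambda whose mean validation log-loss is within one
    standard error of the smallest mean loss.
    """
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=config.inner_splits, shuffle=True,
                          random_state=config.seed)
    losses = np.vstack([
        _path_val_losses(X[tr], y[tr], X[va], y[va], lambdas, config, classes)
        for tr, va in skf.split(X, y)
    ])
    mean = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(losses.shape[0])
    j_min = int(np.argmin(mean))
    threshold = mean[j_min] + se[j_min]
    j_1se = int(np.flatnonzero(mean <= threshold)[0])  # path is descending
    return float(lambdas[j_1se])


def _fit_at_lambda(X, y, lam: float, config: CVConfig) -> LogisticRegression:
    est = _new_solver(config)
    est.set_params(C=1.0 / (len(X) * lam), warm_start=False)
    est.fit(X, y)
    return est


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PairResult:
    """Cross-validated performance for one type pair (or multiclass task)."""

    pair: tuple
    representation: str
    modality: str
    fold_metrics: pd.DataFrame  # one row per outer fold
    n_cells: int = 0
    extras: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(self.fold_metrics[name].mean())

    @property
    def log_loss(self) -> float:
        return self.mean("log_loss")

    def summary(self) -> dict:
        out = dict(pair="|".join(map(str, self.pair)),
                   representation=self.representation, modality=self.modality,
                   n_cells=self.n_cells)
        for name in self.fold_metrics.columns:
            out[name] = self.mean(name)
            out[name + "_sd"] = float(self.fold_metrics[name].std(ddof=1))
        return out


def _outer_cv(config: CVConfig):
    return RepeatedStratifiedKFold(n_splits=config.n_splits,
                                   n_repeats=config.n_repeats,
                                   random_state=config.seed)


def _check_counts(labels: np.ndarray, config: CVConfig) -> None:
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < config.n_splits:
        raise ValueError(
            f"class with {int(counts.min())} cells cannot be stratified into "
            f"{config.n_splits} folds (types with <= 5 cells are excluded "
            "upstream)")


def _run_nested(fm: FeatureMatrix, config: CVConfig,
                model_fitter, needs_proba: bool) -> pd.DataFrame:
    """Shared outer loop: per-fold preprocessing, fitting and scoring."""
    X, labels = fm.X, fm.labels
    classes = np.unique(labels)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for tr, te in _outer_cv(config).split(X, labels):
            tf = FeatureTransform(fm.kind, config.variance_fraction).fit(X[tr])
            X_tr, X_te = tf.transform(X[tr]), tf.transform(X[te])
            est = model_fitter(X_tr, labels[tr])
            y_pred = est.predict(X_te)
            row = {}
            if needs_proba:
                row["log_loss"] = metric("log_loss", labels[te],
                                         est.predict_proba(X_te),
                                         classes=est.classes_)
            row["accuracy"] = metric("accuracy", labels[te], y_pred)
            row["macro_f1"] = metric("macro_f1", labels[te], y_pred,
                                     classes=classes)
            row["mcc"] = metric("mcc", labels[te], y_pred)
            rows.append(row)
    return pd.DataFrame(rows)


def _elastic_net_fitter(config: CVConfig):
    def fit(X_tr, y_tr):
        lambdas = _lambda_path(X_tr, _one_hot(y_tr), config)
        lam = select_lambda_1se(X_tr, y_tr, lambdas, config)
        return _fit_at_lambda(X_tr, y_tr, lam, config)
    return fit


def _one_hot(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if len(classes) == 2:
        return (labels == classes[1]).astype(float)
    return (labels[:, None] == classes[None, :]).astype(float)


def fit_binary(fm: FeatureMatrix, pair: tuple, config: CVConfig | None = None
               ) -> PairResult:
    """Nested-CV elastic-net logistic regression for one type pair."""
    config = config or CVConfig()
    mask = np.isin(fm.labels, list(pair))
    sub = fm.subset(mask)
    if len(np.unique(sub.labels)) != 2:
        raise ValueError(f"pair {pair} not present in the labels")
    _check_counts(sub.labels, config)
    folds = _run_nested(sub, config, _elastic_net_fitter(config),
                        needs_proba=True)
    return PairResult(tuple(pair), fm.representation, fm.modality, folds,
                      n_cells=len(sub.X))


def fit_multiclass(fm: FeatureMatrix, config: CVConfig | None = None
                   ) -> PairResult:
    """Nested-CV multinomial elastic-net over all classes (chance = ln K)."""
    config = config or CVConfig()
    _check_counts(fm.labels, config)
    folds = _run_nested(fm, config, _elastic_net_fitter(config),
                        needs_proba=True)
    classes = tuple(np.unique(fm.labels))
    return PairResult(classes, fm.representation, fm.modality, folds,
                      n_cells=len(fm.X))


def fit_alternative(fm: FeatureMatrix, pair: tuple, scheme: str,
                    config: CVConfig | None = None) -> PairResult:
    """3-NN or decision-tree baseline under the identical outer CV.

    Log-loss is not meaningful for these classifiers; only accuracy,
    macro-F1 and MCC are reported.
    """
    config = config or CVConfig()
    if scheme == "knn3":
        def fitter(X_tr, y_tr):
            return KNeighborsClassifier(n_neighbors=3).fit(X_tr, y_tr)
    elif scheme == "tree":
        def fitter(X_tr, y_tr):
            return DecisionTreeClassifier(random_state=config.seed).fit(X_tr, y_tr)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    mask = np.isin(fm.labels, list(pair))
    sub = fm.subset(mask)
    _check_counts(sub.labels, config)
    folds = _run_nested(sub, config, fitter, needs_proba=False)
    return PairResult(tuple(pair), fm.representation, fm.modality, folds,
                      n_cells=len(sub.X))


def all_pairs(labels) -> list[tuple]:
    classes = list(np.unique(labels))
    return [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]


def benchmark_pairs(feature_matrices: list[FeatureMatrix],
                    config: CVConfig | None = None) -> pd.DataFrame:
    """All pairwise elastic-net results for several representations.

    Returns a tidy frame with one row per representation x modality x pair
    and columns for each mean metric (the layout ``compare`` consumes).
    """
    config = config or CVConfig()
    rows = []
    for fm in feature_matrices:
        for pair in all_pairs(fm.labels):
            rows.append(fit_binary(fm, pair, config).summary())
    return pd.DataFrame(rows)
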