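"""Shrunken centroid (SC) and uncorrelated shrunken centroid (USC)
classifiers.

For feature i and class k, the relative difference

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s_0)),   m_k = sqrt(1/n_k - 1/n)

standardizes the gap between the class centroid and the overall
centroid by the pooled within-class standard deviation s_i (offset by
s_0, the median of the s_i, to guard against near-zero denominators).
Soft thresholding by the shrinkage parameter delta,

    d'_ik = sign(d_ik) * max(|d_ik| - delta, 0),

zeroes small differences; features whose d' row is entirely zero are
dropped. USC additionally prunes correlated survivors: scanning
features by decreasing max_k |d_ik|, a feature is kept only while its
absolute Pearson correlation with every already-kept feature stays at
or below the threshold rho. At rho = 1 nothing is pruned and USC
coincides with SC. Prediction assigns a sample x* to the class
minimizing the discriminant score

    delta_k(x*) = sum_i (x*_i - xbar'_ik)^2 / (s_i + s_0)^2 - 2 log pi_k

with xbar'_ik = xbar_i + m_k (s_i + s_0) d'_ik the shrunken class
centroid and pi_k the class prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, UscModel

__all__ = [
    "CentroidStats",
    "EmptyFeatureSetError",
    "compute_centroids",
    "relative_difference",
    "shrink",
    "select_features",
    "decorrelate",
    "fit",
    "discriminant_score",
    "predict",
    "predict_matrix",
]


class EmptyFeatureSetError(ValueError):
    """Delta so large that no feature survives shrinkage."""


@dataclass
class CentroidStats:
    """Per-feature centroid statistics of a labeled training matrix."""

    feature_ids: list[str]
    class_labels: list[str]  # sorted
    overall_centroid: np.ndarray  # (p,)
    class_centroids: np.ndarray  # (p, K)
    s_i: np.ndarray  # (p,) pooled within-class sd
    s_0: float  # median of s_i
    n: int
    n_k: np.ndarray  # (K,)

    @property
    def K(self) -> int:
        return len(self.class_labels)


def compute_centroids(m: ExpressionMatrix) -> CentroidStats:
    """Overall and class centroids plus the pooled within-class sd.

    s_i^2 = (1/(n-K)) sum_k sum_{j in C_k} (x_ij - xbar_ik)^2. Every
    class needs at least two samples so the pooled variance is defined.
    """
    y = m.label_array()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n = m.n_samples
    n_k = np.array([(y == c).sum() for c in classes])
    small = [c for c, nk in zip(classes, n_k) if nk < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    X = m.values
    overall = X.mean(axis=1)
    cents = np.column_stack([X[:, y == c].mean(axis=1) for c in classes])
    ss = np.zeros(m.n_features)
    for j, c in enumerate(classes):
        resid = X[:, y == c] - cents[:, [j]]
        ss += (resid**2).sum(axis=1)
    s_i = np.sqrt(ss / (n - len(classes)))
    return CentroidStats(
        feature_ids=list(m.feature_ids),
        class_labels=classes,
        overall_centroid=overall,
        class_centroids=cents,
        s_i=s_i,
        s_0=float(np.median(s_i)),
        n=n,
        n_k=n_k,
    )


def _mk(stats: CentroidStats, mk_mode: str) -> np.ndarray:
    if mk_mode == "cv":
        inner = 1.0 / stats.n_k - 1.0 / stats.n
    elif mk_mode == "plus":
        inner = 1.0 / stats.n_k + 1.0 / stats.n
    else:
        raise ValueError(f"unknown mk_mode {mk_mode!r}")
    return np.sqrt(inner)


def relative_difference(stats: CentroidStats, mk_mode: str = "cv") -> np.ndarray:
    """Standardized centroid gaps d_ik, shape (features, classes)."""
    if np.any(stats.n_k >= stats.n):
        raise ValueError("a class holds every sample; relative difference undefined")
    denom = stats.s_i + stats.s_0
    if np.any(denom <= 0):
        raise ValueError("s_i + s_0 must be positive for every feature")
    mk = _mk(stats, mk_mode)
    return (stats.class_centroids - stats.overall_centroid[:, None]) / (mk[None, :] * denom[:, None])


def shrink(d: np.ndarray, delta: float) -> np.ndarray:
    """Soft-threshold: d'_ik = sign(d_ik) * max(|d_ik| - delta, 0)."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def select_features(dprime: np.ndarray) -> np.ndarray:
    """Indices of features with at least one nonzero shrunken difference."""
    keep = np.flatnonzero(np.abs(dprime).max(axis=1) > 0)
    if keep.size == 0:
        raise EmptyFeatureSetError("delta too large: no feature survives shrinkage")
    return keep


def decorrelate(
    selected: np.ndarray,
    m: ExpressionMatrix,
    d: np.ndarray,
    rho: float,
    *,
    corr: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy correlation pruning of the shrinkage-selected features.

    Features are scanned by decreasing max_k |d_ik| (ties by
    lexicographic feature ID); a feature is kept iff its absolute
    Pearson correlation across training samples with every already-kept
    feature is <= rho. ``corr`` may supply a precomputed full
    feature-by-feature correlation matrix.

    Returns kept indices in scan (rank) order.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    selected = np.asarray(selected)
    if selected.size == 0:
        raise ValueError("empty selected feature set")
    strength = np.abs(d[selected]).max(axis=1)
    ids = [m.feature_ids[i] for i in selected]
    order = sorted(range(len(ids)), key=lambda i: (-strength[i], ids[i]))
    if rho >= 1.0:
        return selected[order]
    if corr is None:
        sub = m.values[selected]
        sds = sub.std(axis=1)
        if np.any(np.isclose(sds, 0.0)):
            bad = [ids[i] for i in np.flatnonzero(np.isclose(sds, 0.0))]
            raise ValueError(f"zero-variance features have undefined correlation: {bad[:10]}")
        cmat = np.abs(np.corrcoef(sub))
    else:
        cmat = np.abs(corr[np.ix_(selected, selected)])
    kept: list[int] = []
    for i in order:
        if all(cmat[i, j] <= rho for j in kept):
            kept.append(i)
    return selected[kept]


def fit(
    m: ExpressionMatrix,
    delta: float,
    rho: float,
    prior_mode: str = "empirical",
    *,
    mk_mode: str = "cv",
    apply_decorrelation: bool = True,
    standardizer: dict | None = None,
) -> UscModel:
    """Fit a USC model on a labeled training matrix.

    ``apply_decorrelation=False`` gives the plain SC path (shrinkage
    only), regardless of rho. ``standardizer`` is stored verbatim for
    serialization so raw test samples can be brought onto the training
    scale at prediction time.
    """
    stats = compute_centroids(m)
    d = relative_difference(stats, mk_mode=mk_mode)
    dprime = shrink(d, delta)
    sel = select_features(dprime)
    if apply_decorrelation:
        sel = decorrelate(sel, m, d, rho)
    else:
        strength = np.abs(d[sel]).max(axis=1)
        ids = [m.feature_ids[i] for i in sel]
        sel = sel[sorted(range(len(ids)), key=lambda i: (-strength[i], ids[i]))]
    mk = _mk(stats, mk_mode)
    denom = stats.s_i[sel] + stats.s_0
    shrunken = stats.overall_centroid[sel, None] + mk[None, :] * denom[:, None] * dprime[sel]
    if prior_mode == "empirical":
        priors = stats.n_k / stats.n
    elif prior_mode == "uniform":
        priors = np.full(stats.K, 1.0 / stats.K)
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    feats = [m.feature_ids[i] for i in sel]
    std = None
    if standardizer is not None:
        std = {f: list(map(float, standardizer[f])) for f in feats}
    return UscModel(
        selected_features=feats,
        class_labels=stats.class_labels,
        shrunken_centroids=shrunken,
        overall_centroid=stats.overall_centroid[sel],
        s_i=stats.s_i[sel],
        s_0=stats.s_0,
        priors=priors,
        delta=delta,
        rho=rho,
        standardizer=std,
    )


def discriminant_score(x: np.ndarray, model: UscModel) -> np.ndarray:
    """Per-class discriminant scores for one sample vector.

    ``x`` holds values for the model's selected features, in order, on
    the training scale.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.selected_features),):
        raise ValueError(
            f"expected {len(model.selected_features)} feature values, got shape {x.shape}"
        )
    denom = model.s_i + model.s_0
    dist = (((x[:, None] - model.shrunken_centroids) / denom[:, None]) ** 2).sum(axis=0)
    return dist - 2.0 * np.log(model.priors)


def predict(x: np.ndarray, model: UscModel) -> tuple[str, np.ndarray, bool]:
    """Assign a sample to the class with minimal discriminant score.

    Returns (label, score vector, tie flag); exact ties go to the
    lexicographically first class label.
    """
    scores = discriminant_score(x, model)
    best = int(np.argmin(scores))  # class labels are sorted, so first min wins
    tie = bool((scores == scores[best]).sum() > 1)
    return model.class_labels[best], scores, tie


def predict_matrix(
    m: ExpressionMatrix, model: UscModel, *, apply_standardizer: bool = True
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Predict every sample of a matrix.

    Missing selected features raise; if the model carries a
    standardizer and the matrix is not already standardized, the stored
    training (mean, sd) are applied per feature first.

    Returns (labels, scores (samples x classes), tie flags).
    """
    missing = [f for f in model.selected_features if f not in set(m.feature_ids)]
    if missing:
        raise ValueError(f"test matrix lacks selected features: {missing[:10]}")
    idx = [m.feature_ids.index(f) for f in model.selected_features]
    X = m.values[idx, :].astype(float).copy()
    if apply_standardizer and model.standardizer is not None and not m.standardized:
        mu = np.array([model.standardizer[f][0] for f in model.selected_features])
        sd = np.array([model.standardizer[f][1] for f in model.selected_features])
        X = (X - mu[:, None]) / sd[:, None]
    denom = model.s_i + model.s_0
    # (samples x classes) squared standardized distances
    dist = (
        ((X[:, :, None] - model.shrunken_centroids[:, None, :]) / denom[:, None, None]) ** 2
    ).sum(axis=0)
    scores = dist - 2.0 * np.log(model.priors)[None, :]
    best = scores.argmin(axis=1)
    labels = [model.class_labels[b] for b in best]
    ties = (scores == scores[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    return labels, scores, ties
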