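"""Repeated stratified cross-validation over the (delta, rho) grid.

The tuning protocol is ten random fourfold cross-validations: in each
repeat samples are split into four stratified folds, the classifier is
fit on three folds for every (delta, rho) cell and scored on the held
-out fold, and the grid cell minimizing the mean error over all
repeats and folds wins. Ties prefer the more parsimonious model:
larger delta first, then smaller rho.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from . import usc
from .datatypes import CvResult, ExpressionMatrix
from .preprocess import feature_stats, standardize_features

__all__ = ["make_folds", "cross_validate", "select_params", "DEFAULT_DELTA_GRID", "DEFAULT_RHO_GRID"]

DEFAULT_DELTA_GRID: list[float] = [round(0.1 * i, 1) for i in range(21)]  # 0.0 .. 2.0
DEFAULT_RHO_GRID: list[float] = [round(0.5 + 0.1 * i, 1) for i in range(6)]  # 0.5 .. 1.0

#: fold id given to samples pinned to the training side of every split
PINNED = -1


def make_folds(
    labels: Mapping[str, str], n_folds: int = 4, seed: int = 0
) -> dict[str, int]:
    """Stratified fold assignment, deterministic given the seed.

    Within each class, shuffled samples are dealt to folds round-robin
    from a random starting fold, so per-class fold sizes differ by at
    most one and small classes land in a subset of folds. A singleton
    class cannot be split, so its sample is pinned to the training side
    (fold ``PINNED``) with a warning.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for s in sorted(labels):
        by_class.setdefault(labels[s], []).append(s)
    assignment: dict[str, int] = {}
    for c in sorted(by_class):
        members = by_class[c]
        if len(members) == 1:
            warnings.warn(
                f"class {c!r} has a single sample; pinning it to training in every split",
                stacklevel=2,
            )
            assignment[members[0]] = PINNED
            continue
        perm = rng.permutation(len(members))
        start = int(rng.integers(n_folds))
        for pos, idx in enumerate(perm):
            assignment[members[idx]] = (start + pos) % n_folds
    return assignment


def _split_standardize(train: ExpressionMatrix, test: ExpressionMatrix):
    """Standardize train and test with statistics fit on train only.

    A feature constant within the split carries no signal; its sd is
    replaced by 1 so the split is merely centred rather than aborted.
    """
    means, sds = feature_stats(train)
    sds = np.where(np.isclose(sds, 0.0), 1.0, sds)
    return (
        standardize_features(train, stats=(means, sds)),
        standardize_features(test, stats=(means, sds)),
    )


def cross_validate(
    m: ExpressionMatrix,
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    repeats: int = 10,
    n_folds: int = 4,
    seed: int = 0,
    *,
    prior_mode: str = "empirical",
    mk_mode: str = "cv",
    standardize_in_fold: bool = True,
) -> CvResult:
    """Mean classification error over the (delta, rho) grid.

    For repeat r the fold split uses ``seed + r``. A grid cell where a
    fold's fit fails (delta leaves no feature) contributes error 1.0 to
    that fold and is flagged. Raises if every cell fails everywhere.
    """
    delta_grid = [float(x) for x in delta_grid]
    rho_grid = [float(x) for x in rho_grid]
    if not delta_grid or not rho_grid:
        raise ValueError("empty parameter grid")
    if min(delta_grid) < 0 or min(rho_grid) < 0 or max(rho_grid) > 1:
        raise ValueError("delta must be >= 0 and rho in [0, 1]")
    labels = {s: c for s, c in (m.labels or {}).items()}
    if set(labels) != set(m.sample_ids):
        raise ValueError("cross_validate needs a fully labeled matrix")
    nd, nr = len(delta_grid), len(rho_grid)
    errs = np.zeros((repeats, n_folds, nd, nr))
    failed = np.zeros((nd, nr), dtype=bool)
    for r in range(repeats):
        folds = make_folds(labels, n_folds=n_folds, seed=seed + r)
        for f in range(n_folds):
            test_ids = [s for s in m.sample_ids if folds[s] == f]
            train_ids = [s for s in m.sample_ids if folds[s] != f]
            if not test_ids:
                raise ValueError(f"fold {f} of repeat {r} is empty; too few samples")
            train = m.subset(samples=train_ids)
            test = m.subset(samples=test_ids)
            if standardize_in_fold:
                train, test = _split_standardize(train, test)
            errs[r, f] = _fold_error_grid(
                train, test, labels, delta_grid, rho_grid, failed,
                prior_mode=prior_mode, mk_mode=mk_mode,
            )
    if failed.all():
        raise ValueError("every (delta, rho) cell failed to fit")
    return CvResult(
        delta_grid=delta_grid,
        rho_grid=rho_grid,
        mean_error=errs.mean(axis=(0, 1)),
        per_repeat_errors=errs,
        failed=failed,
        seed=seed,
    )


def _fold_error_grid(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    labels: Mapping[str, str],
    delta_grid: Sequence[float],
    rho_grid: Sequence[float],
    failed: np.ndarray,
    *,
    prior_mode: str,
    mk_mode: str,
) -> np.ndarray:
    """Error of one train/test split at every grid cell.

    Centroid statistics and the feature correlation matrix are computed
    once per split and shared across cells; each cell then reduces to a
    soft-threshold, a greedy correlation scan and a vectorized
    prediction, exactly as in :func:`sfssclass.usc.fit`.
    """
    out = np.ones((len(delta_grid), len(rho_grid)))
    stats = usc.compute_centroids(train)
    d = usc.relative_difference(stats, mk_mode=mk_mode)
    mk = usc._mk(stats, mk_mode)
    sds = train.values.std(axis=1)
    safe = ~np.isclose(sds, 0.0)
    corr = np.zeros((train.n_features, train.n_features))
    if safe.any():
        sub = np.corrcoef(train.values[safe])
        corr[np.ix_(safe, safe)] = np.atleast_2d(sub)
    if prior_mode == "empirical":
        priors = stats.n_k / stats.n
    else:
        priors = np.full(stats.K, 1.0 / stats.K)
    y_true = np.array([labels[s] for s in test.sample_ids])
    test_vals = {f: i for i, f in enumerate(test.feature_ids)}
    tidx = np.array([test_vals[f] for f in train.feature_ids])
    X_test = test.values[tidx]  # test rows in training feature order
    for di, delta in enumerate(delta_grid):
        dprime = usc.shrink(d, delta)
        try:
            sel = usc.select_features(dprime)
        except usc.EmptyFeatureSetError:
            failed[di, :] = True
            continue
        for ri, rho in enumerate(rho_grid):
            kept = usc.decorrelate(sel, train, d, rho, corr=corr)
            denom = stats.s_i[kept] + stats.s_0
            shrunken = (
                stats.overall_centroid[kept, None]
                + mk[None, :] * denom[:, None] * dprime[kept]
            )
            Xs = X_test[kept]
            dist = (
                ((Xs[:, :, None] - shrunken[:, None, :]) / denom[:, None, None]) ** 2
            ).sum(axis=0)
            scores = dist - 2.0 * np.log(priors)[None, :]
            pred = np.array([stats.class_labels[b] for b in scores.argmin(axis=1)])
            out[di, ri] = float((pred != y_true).mean())
    return out


def select_params(cv: CvResult) -> tuple[float, float]:
    """(delta*, rho*) minimizing mean error; ties prefer larger delta,
    then smaller rho."""
    ok = ~cv.failed
    if not ok.any():
        raise ValueError("no non-failed grid cell")
    best = np.min(cv.mean_error[ok])
    candidates = [
        (cv.delta_grid[i], cv.rho_grid[j])
        for i in range(len(cv.delta_grid))
        for j in range(len(cv.rho_grid))
        if ok[i, j] and cv.mean_error[i, j] == best
    ]
    candidates.sort(key=lambda dr: (-dr[0], dr[1]))
    return candidates[0]
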