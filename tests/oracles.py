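"""Brute-force reference implementations used to cross-check the package.

Everything here is deliberately naive (exhaustive enumeration, double
loops) and independent of the code paths it validates.
"""

import itertools

import numpy as np


def exhaustive_best_score(g, min_features: int = 2, min_samples: int = 2) -> float:
    """Exhaustive maximum bicluster score over all feature x sample
    submatrices of at least min_features x min_samples."""
    p, n = g.response.shape
    best = -np.inf
    for fs in range(min_features, p + 1):
        for fc in itertools.combinations(range(p), fs):
            sub = g.response[list(fc)]
            for ss in range(min_samples, n + 1):
                for sc in itertools.combinations(range(n), ss):
                    cnt = int(sub[:, list(sc)].sum())
                    total = g.w_present * cnt + g.w_absent * (fs * ss - cnt)
                    if total > best:
                        best = total
    return best


def recount_selected(dprime: np.ndarray) -> set[int]:
    """Features with at least one nonzero shrunken relative difference."""
    keep = set()
    for i in range(dprime.shape[0]):
        for k in range(dprime.shape[1]):
            if dprime[i, k] != 0:
                keep.add(i)
    return keep


def potential_by_double_loop(bicluster, net, labels) -> bool:
    for s in bicluster.samples:
        for m in bicluster.features:
            if net.has_edge(labels[s], m):
                return True
    return False


def relevant_samples_by_double_loop(bicluster, net, labels) -> set[str]:
    kept = set()
    for s in bicluster.samples:
        for m in bicluster.features:
            if net.has_edge(labels[s], m):
                kept.add(s)
                break
    return kept


def greedy_decorrelate_reference(values: np.ndarray, strengths: np.ndarray,
                                 ids: list[str], rho: float) -> list[int]:
    """Reference greedy correlation pruning in explicit double loops.

    values: (features x samples) for the candidate set; strengths the
    ranking statistic; returns kept indices (into the candidate set).
    """
    order = sorted(range(len(ids)), key=lambda i: (-strengths[i], ids[i]))
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            r = np.corrcoef(values[i], values[j])[0, 1]
            if abs(r) > rho:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept
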