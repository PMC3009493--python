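"""SAMBA-style biclustering of a standardized expression matrix.

The matrix is discretized to a trinary up/unchanged/down response
matrix, viewed as a bipartite feature-sample graph whose edges are the
nonzero responses. Each (feature, sample) pair carries a log
likelihood-ratio weight under a uniform-density null: present pairs are
rewarded with ``log(p_c / p_hat)`` and absent pairs penalized with
``log((1 - p_c) / (1 - p_hat))``, where ``p_hat`` is the observed edge
density and ``p_c > p_hat`` is the assumed within-bicluster response
probability. A bicluster's score is the summed weight of its induced
submatrix, so heavy subgraphs are coherent blocks of responses.

The search enumerates small feature-subset seeds from sample
neighborhoods, grows each seed by greedy single-element moves, and
emits the resulting biclusters in score order subject to a pairwise
overlap bound.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import Bicluster, ExpressionMatrix

__all__ = [
    "TrinaryMatrix",
    "WeightedBipartiteGraph",
    "discretize",
    "build_graph",
    "score",
    "find_biclusters",
]


@dataclass
class TrinaryMatrix:
    """Discretized responses: +1 (up), -1 (down), 0 (unchanged)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # int8, features x samples

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("trinary matrix shape mismatch")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("trinary values must be in {-1, 0, +1}")


@dataclass
class WeightedBipartiteGraph:
    """Bipartite response graph with likelihood-ratio pair weights."""

    feature_ids: list[str]
    sample_ids: list[str]
    response: np.ndarray  # bool, features x samples
    signs: np.ndarray  # int8, features x samples (sign of the response)
    w_present: float
    w_absent: float
    density: float
    p_c: float

    def weight(self, fi: int, si: int) -> float:
        return self.w_present if self.response[fi, si] else self.w_absent


def discretize(m: ExpressionMatrix, t: float = 1.0) -> TrinaryMatrix:
    """Threshold a standardized matrix at ±t standard deviations."""
    if t <= 0:
        raise ValueError("discretization threshold t must be > 0")
    if not m.standardized:
        raise ValueError("discretize expects a standardized matrix")
    vals = np.zeros(m.values.shape, dtype=np.int8)
    vals[m.values >= t] = 1
    vals[m.values <= -t] = -1
    return TrinaryMatrix(list(m.feature_ids), list(m.sample_ids), vals)


def build_graph(tm: TrinaryMatrix, p_c: float = 0.9) -> WeightedBipartiteGraph:
    """Attach likelihood-ratio weights to the response graph.

    ``p_c`` is the assumed probability that a within-bicluster pair
    responds; it must exceed the observed density ``p_hat``. With no
    responses at all the present-pair weight is computed against half a
    pseudo-count so the graph stays well-defined (the search then finds
    nothing).
    """
    if not 0.5 < p_c < 1:
        raise ValueError("p_c must lie in (0.5, 1)")
    response = tm.values != 0
    total = response.size
    p_hat = response.sum() / total
    if p_c <= p_hat:
        raise ValueError(
            f"degenerate model: p_c={p_c} must exceed observed density {p_hat:.4f}"
        )
    p_eff = max(p_hat, 0.5 / total)  # pseudo-density keeps weights finite
    return WeightedBipartiteGraph(
        feature_ids=list(tm.feature_ids),
        sample_ids=list(tm.sample_ids),
        response=response,
        signs=tm.values.copy(),
        w_present=math.log(p_c / p_eff),
        w_absent=math.log((1 - p_c) / (1 - p_eff)),
        density=p_hat,
        p_c=p_c,
    )


def score(b: Bicluster, g: WeightedBipartiteGraph) -> float:
    """Summed pair weight of the induced feature x sample submatrix."""
    fidx = [g.feature_ids.index(f) for f in sorted(b.features)]
    sidx = [g.sample_ids.index(s) for s in sorted(b.samples)]
    sub = g.response[np.ix_(fidx, sidx)]
    present = int(sub.sum())
    return g.w_present * present + g.w_absent * (sub.size - present)


def _submatrix_score(resp: np.ndarray, fmask: np.ndarray, smask: np.ndarray,
                     wp: float, wa: float) -> float:
    sub = resp[np.ix_(fmask, smask)]
    present = int(sub.sum())
    return wp * present + wa * (sub.size - present)


def _seed_candidates(resp_f32: np.ndarray, resp: np.ndarray, neigh: np.ndarray,
                     k: int, n_keep: int, wp: float, min_samples: int):
    """Top-scoring seed subsets (size 2..k) of one sample's neighbor features.

    A seed's sample set is every sample responding on all its features,
    so all pairs are present and the score is w_present * |F| * |S|.
    Returns (score, feature-index-tuple) pairs.
    """
    m = len(neigh)
    if m < 2:
        return []
    A = resp_f32[neigh]  # m x n
    out: list[tuple[float, tuple[int, ...]]] = []
    # pairs via the Gram matrix of the response rows
    counts = A @ A.T
    iu, ju = np.triu_indices(m, k=1)
    c = counts[iu, ju]
    ok = c >= min_samples
    for i, j, cc in zip(iu[ok], ju[ok], c[ok]):
        out.append((wp * 2.0 * cc, (int(neigh[i]), int(neigh[j]))))
    if k >= 3:
        for a in range(m):
            B = A * resp[neigh[a]]  # rows masked by feature a's responses
            tc = B @ B.T
            ti, tj = np.triu_indices(m, k=1)
            keep = (ti > a) & (tj > a)
            ti, tj = ti[keep], tj[keep]
            cc = tc[ti, tj]
            okk = cc >= min_samples
            for i, j, c3 in zip(ti[okk], tj[okk], cc[okk]):
                out.append((wp * 3.0 * c3, (int(neigh[a]), int(neigh[i]), int(neigh[j]))))
    if k >= 4:  # generic fall-back; intended for small graphs only
        for size in range(4, k + 1):
            for combo in itertools.combinations(range(m), size):
                sam = resp[neigh[list(combo)]].all(axis=0)
                ns = int(sam.sum())
                if ns >= min_samples:
                    out.append((wp * size * ns, tuple(int(neigh[i]) for i in combo)))
    out.sort(key=lambda sc: (-sc[0], sc[1]))
    return out[:n_keep]


def _best_axis_set(contrib: np.ndarray, min_keep: int) -> np.ndarray:
    """Optimal axis subset given independent per-element contributions:
    every positive contributor, topped up to ``min_keep`` if needed."""
    mask = contrib > 0
    if mask.sum() < min_keep:
        top = np.argsort(-contrib, kind="stable")[:min_keep]
        mask = np.zeros_like(mask)
        mask[top] = True
    return mask


def _improve(resp: np.ndarray, fmask: np.ndarray, smask: np.ndarray,
             wp: float, wa: float, min_features: int, min_samples: int) -> float:
    """Local search: exact one-axis re-optimization plus single-move steps.

    Because the score is a sum of independent pair weights, the optimal
    sample set given the feature set (and vice versa) is closed-form:
    keep every axis element with positive total contribution, topped up
    to the minimum size. The search alternates these exact
    re-optimizations with greedy single add/remove moves (which can
    escape some alternation fixpoints) until neither improves. Mutates
    the masks in place and returns the final score; the score strictly
    increases per accepted step and is bounded by the total positive
    weight, so termination is guaranteed. Never shrinks the bicluster
    below min_features x min_samples.
    """
    p, n = resp.shape
    cur = _submatrix_score(resp, fmask, smask, wp, wa)
    tol = 1e-12
    while True:
        # exact re-optimization of the sample set given the features
        nf = int(fmask.sum())
        s_cnt = resp[fmask, :].sum(axis=0)
        s_contrib = wp * s_cnt + wa * (nf - s_cnt)
        new_smask = _best_axis_set(s_contrib, min_samples)
        new_score = float(s_contrib[new_smask].sum())
        if new_score > cur + tol:
            smask[:] = new_smask
            cur = new_score
            continue
        # exact re-optimization of the feature set given the samples
        ns = int(smask.sum())
        f_cnt = resp[:, smask].sum(axis=1)
        f_contrib = wp * f_cnt + wa * (ns - f_cnt)
        new_fmask = _best_axis_set(f_contrib, min_features)
        new_score = float(f_contrib[new_fmask].sum())
        if new_score > cur + tol:
            fmask[:] = new_fmask
            cur = new_score
            continue
        # single add/remove step (f_cnt/f_contrib reflect the current masks)
        add_f = np.where(~fmask, f_contrib, -np.inf)
        rem_f = np.where(fmask, -f_contrib, -np.inf) if nf > min_features else np.full(p, -np.inf)
        s_gain = wp * s_cnt + wa * (nf - s_cnt)
        add_s = np.where(~smask, s_gain, -np.inf)
        rem_s = np.where(smask, -s_gain, -np.inf) if ns > min_samples else np.full(n, -np.inf)
        gains = np.concatenate([add_f, rem_f, add_s, rem_s])
        best = int(np.argmax(gains))
        if gains[best] <= tol:
            return cur
        cur += float(gains[best])
        if best < p:
            fmask[best] = True
        elif best < 2 * p:
            fmask[best - p] = False
        elif best < 2 * p + n:
            smask[best - 2 * p] = True
        else:
            smask[best - 2 * p - n] = False


def find_biclusters(
    g: WeightedBipartiteGraph,
    d: int = 30,
    k: int = 3,
    n_keep: int = 20,
    max_overlap: float = 0.25,
    min_features: int = 2,
    min_samples: int = 2,
    coherent_signs: bool = False,
) -> list[Bicluster]:
    """Seed-and-grow heavy subgraph search.

    For every sample vertex with degree <= ``d``, all feature subsets of
    its neighborhood of size 2..``k`` are scored as seeds (the subset
    together with every sample responding on all of it) and the
    ``n_keep`` best kept. Each surviving seed is refined by local search
    (exact one-axis re-optimization alternating with greedy single
    add/remove moves) until no step increases the score, then the
    improved biclusters are emitted in score order, skipping any whose
    Jaccard overlap on feature-union-sample sets with an already emitted
    bicluster exceeds ``max_overlap``.

    With ``coherent_signs`` the up- and down-response graphs are
    searched separately (weights computed against the per-sign density),
    so a bicluster mixes no up and down responses; useful when the
    expected signal is sign-coherent, since it halves the effective
    noise density. Default off: both signs count as responses.

    Deterministic: ties everywhere are broken by lexicographic vertex
    ID (the axes are sorted internally before the search).
    """
    if not 0 <= max_overlap <= 1:
        raise ValueError("max_overlap must be in [0, 1]")
    if g.response.sum() == 0:
        warnings.warn("response graph has no edges; no biclusters found", stacklevel=2)
        return []
    # lexicographic axis order makes every argmax tie-break by vertex ID
    forder = np.argsort(np.array(g.feature_ids, dtype=object))
    sorder = np.argsort(np.array(g.sample_ids, dtype=object))
    fids = [g.feature_ids[i] for i in forder]
    sids = [g.sample_ids[i] for i in sorder]
    signs = g.signs[np.ix_(forder, sorder)]

    results: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    if coherent_signs:
        for sign in (1, -1):
            resp = signs == sign
            dens = resp.sum() / resp.size
            if dens == 0:
                continue
            if g.p_c <= dens:
                raise ValueError(
                    f"degenerate model: p_c={g.p_c} must exceed sign density {dens:.4f}"
                )
            wp = math.log(g.p_c / dens)
            wa = math.log((1 - g.p_c) / (1 - dens))
            for key, sc in _search(resp, wp, wa, d, k, n_keep, min_features, min_samples).items():
                if key not in results or sc > results[key]:
                    results[key] = sc
    else:
        resp = signs != 0
        results = _search(resp, g.w_present, g.w_absent, d, k, n_keep,
                          min_features, min_samples)

    ranked = sorted(results.items(), key=lambda kv: (-kv[1], kv[0]))
    emitted: list[Bicluster] = []
    for (fidx, sidx), sc in ranked:
        cand = Bicluster(
            frozenset(fids[i] for i in fidx),
            frozenset(sids[j] for j in sidx),
            sc,
        )
        if all(cand.jaccard(prev) <= max_overlap for prev in emitted):
            emitted.append(cand)
    return emitted


def _search(
    resp: np.ndarray,
    wp: float,
    wa: float,
    d: int,
    k: int,
    n_keep: int,
    min_features: int,
    min_samples: int,
) -> dict[tuple[tuple[int, ...], tuple[int, ...]], float]:
    """Seed enumeration + local improvement on one response matrix."""
    resp_f32 = resp.astype(np.float32)
    p, n = resp.shape

    seeds: dict[tuple[int, ...], float] = {}
    if p <= 15:
        # small graph: every feature subset of size 2..k is a seed
        for size in range(2, min(k, p) + 1):
            for combo in itertools.combinations(range(p), size):
                seeds[combo] = 0.0
    else:
        for s in range(n):
            neigh = np.flatnonzero(resp[:, s])
            if len(neigh) == 0 or len(neigh) > d:
                continue
            for sc, combo in _seed_candidates(resp_f32, resp, neigh, k, n_keep, wp, min_samples):
                if combo not in seeds:
                    seeds[combo] = sc

    results: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    for combo in sorted(seeds):
        fmask = np.zeros(p, dtype=bool)
        fmask[list(combo)] = True
        smask = resp[list(combo)].all(axis=0).copy()
        if smask.sum() < min_samples:
            # no common responders; let the local search pick the samples
            nf = len(combo)
            cnt = resp[list(combo)].sum(axis=0)
            smask = _best_axis_set(wp * cnt + wa * (nf - cnt), min_samples)
        final = _improve(resp, fmask, smask, wp, wa, min_features, min_samples)
        key = (tuple(np.flatnonzero(fmask).tolist()), tuple(np.flatnonzero(smask).tolist()))
        results.setdefault(key, final)
    return results
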