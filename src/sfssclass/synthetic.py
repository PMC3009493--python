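"""Seeded generators for synthetic study data.

Everything the pipeline consumes can be generated here: multiclass
expression matrices with class-specific informative miRNAs, matrices
with planted expression biclusters, and cancer-miRNA association
networks consistent (up to controllable noise) with the planted
structure. All generators are bit-reproducible given their seed.

The noise model is additive Gaussian on a log-like scale: background
values are i.i.d. N(0, 1) (or N(0, noise_sd)), and signal enters as a
mean shift. This mimics standardized log2 expression, where class
effects of 2-3 within-feature standard deviations are typical of
strongly dysregulated miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CancerMirnaNetwork, ExpressionMatrix

__all__ = [
    "ClassificationTruth",
    "BiclusterTruth",
    "make_classification_data",
    "make_planted_bicluster_data",
    "make_network",
]


@dataclass
class ClassificationTruth:
    """Which features are informative for which class."""

    informative: dict[str, list[str]]  # class -> feature ids
    effect: float

    def feature_class_pairs(self) -> set[tuple[str, str]]:
        return {(c, f) for c, feats in self.informative.items() for f in feats}

    def all_informative(self) -> set[str]:
        return {f for feats in self.informative.values() for f in feats}


@dataclass
class BiclusterTruth:
    """Planted bicluster index sets and identifiers."""

    blocks: list[dict] = field(default_factory=list)  # feature_ids, sample_ids, shift


def _feature_ids(p: int) -> list[str]:
    width = max(3, len(str(p)))
    return [f"miR-{i:0{width}d}" for i in range(1, p + 1)]


def make_classification_data(
    K: int = 5,
    p: int = 100,
    n_k: int = 20,
    p_info: int = 5,
    effect: float = 3.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, str], ClassificationTruth]:
    """Multiclass matrix with ``p_info`` informative features per class.

    Background entries are i.i.d. N(0, 1); each class's informative
    features are shifted by ``+effect`` in that class's samples. Class
    blocks of informative features are disjoint (``p_info * K <= p``).

    Returns (matrix, labels, truth); the matrix also carries the labels.
    """
    if p_info * K > p:
        raise ValueError("p_info * K must not exceed p")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    n = K * n_k
    X = rng.standard_normal((p, n))
    feats = _feature_ids(p)
    classes = [f"class{c + 1:02d}" for c in range(K)]
    samples = [f"S{j + 1:03d}" for j in range(n)]
    labels = {samples[j]: classes[j // n_k] for j in range(n)}
    informative: dict[str, list[str]] = {}
    for c in range(K):
        fs = slice(c * p_info, (c + 1) * p_info)
        ss = slice(c * n_k, (c + 1) * n_k)
        X[fs, ss] += effect
        informative[classes[c]] = feats[fs]
    m = ExpressionMatrix(feats, samples, X, scale="log2", labels=dict(labels))
    return m, labels, ClassificationTruth(informative=informative, effect=effect)


def make_planted_bicluster_data(
    p: int = 30,
    n: int = 30,
    blocks: list[tuple[int, int, float]] = ((6, 5, 3.0),),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, BiclusterTruth]:
    """Matrix of N(0, noise_sd) noise with shifted rectangular blocks.

    Blocks are placed along the diagonal without overlap: block b
    occupies the next ``f_count`` features and ``s_count`` samples and
    its entries are shifted by ``shift``. Raises if the blocks do not
    fit.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, noise_sd, size=(p, n))
    feats = _feature_ids(p)
    samples = [f"S{j + 1:03d}" for j in range(n)]
    truth = BiclusterTruth()
    f0 = s0 = 0
    for fc, sc, shift in blocks:
        if f0 + fc > p or s0 + sc > n:
            raise ValueError("planted blocks exceed matrix dimensions")
        X[f0:f0 + fc, s0:s0 + sc] += shift
        truth.blocks.append(
            {
                "feature_ids": feats[f0:f0 + fc],
                "sample_ids": samples[s0:s0 + sc],
                "shift": shift,
            }
        )
        f0 += fc
        s0 += sc
    m = ExpressionMatrix(feats, samples, X, scale="log2")
    return m, truth


def make_network(
    truth: ClassificationTruth,
    coverage: float = 1.0,
    false_edge_rate: float = 0.0,
    seed: int = 0,
    *,
    feature_ids: list[str] | None = None,
) -> CancerMirnaNetwork:
    """Cancer-miRNA network consistent with a classification truth.

    Each true (class, informative miRNA) pair becomes an edge with
    probability ``coverage``. False edges are then added: every
    (class, miRNA) pair not in the truth (over ``feature_ids`` if
    given, else the truth's informative miRNAs) enters independently
    with probability ``false_edge_rate``.
    """
    if not 0 <= coverage <= 1 or not 0 <= false_edge_rate <= 1:
        raise ValueError("coverage and false_edge_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    net = CancerMirnaNetwork()
    classes = sorted(truth.informative)
    for c in classes:
        for f in truth.informative[c]:
            if rng.random() < coverage:
                net.add_edge(c, f, "up")
    if false_edge_rate > 0:
        pool = feature_ids if feature_ids is not None else sorted(truth.all_informative())
        true_pairs = truth.feature_class_pairs()
        for c in classes:
            for f in pool:
                if (c, f) in true_pairs:
                    continue
                if rng.random() < false_edge_rate:
                    net.add_edge(c, f, "unknown")
    return net
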