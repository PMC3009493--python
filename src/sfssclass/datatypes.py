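"""Core domain types shared by every stage of the pipeline.

The central container is :class:`ExpressionMatrix`, a features x samples
real-valued matrix (miRNAs in rows, tissue samples in columns) carrying a
scale flag (``raw`` vs ``log2``) and optional per-sample class labels.
Biclusters, the cancer-miRNA association network, the fitted classifier
state and cross-validation results each get a small dedicated type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "Bicluster",
    "CancerMirnaNetwork",
    "UscModel",
    "CvResult",
    "normalize_id",
]

#: allowed per-edge dysregulation direction tags
DIRECTIONS = ("up", "down", "mixed", "unknown")


def normalize_id(name: str) -> str:
    """Canonical form for cancer-type / miRNA identifiers.

    Literature-derived names vary in case and padding, so matching is
    case-insensitive after trimming.
    """
    return name.strip().lower()


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dupes))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Features x samples expression matrix with optional class labels.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique row / column identifiers.
    values
        Real matrix, ``(len(feature_ids), len(sample_ids))``. No NaN/inf.
    scale
        ``"raw"`` for linear-scale intensities, ``"log2"`` after log
        transform.
    standardized
        True once each feature has been centred to mean 0 / sd 1.
    labels
        Optional ``sample_id -> class label`` map; every key must be a
        known sample.
    feature_meta
        Optional per-feature free-text description (the GCT Description
        column).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "raw"
    standardized: bool = False
    labels: Optional[dict[str, str]] = None
    feature_meta: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.feature_ids = _check_unique(self.feature_ids, "feature IDs")
        self.sample_ids = _check_unique(self.sample_ids, "sample IDs")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if self.labels is not None:
            unknown = set(self.labels) - set(self.sample_ids)
            if unknown:
                raise ValueError(f"labels refer to unknown samples: {sorted(unknown)[:5]}")

    # -- convenience -----------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def label_array(self) -> np.ndarray:
        """Class label per column; raises if any sample is unlabeled."""
        if self.labels is None:
            raise ValueError("matrix has no sample labels")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"unlabeled samples: {missing[:5]}")
        return np.array([self.labels[s] for s in self.sample_ids])

    def with_labels(self, labels: Mapping[str, str]) -> "ExpressionMatrix":
        sub = {s: labels[s] for s in self.sample_ids if s in labels}
        return replace(self, labels=dict(sub))

    def subset(
        self,
        features: Optional[Iterable[str]] = None,
        samples: Optional[Iterable[str]] = None,
    ) -> "ExpressionMatrix":
        """Restrict to the given features/samples, preserving matrix order."""
        feats = self.feature_ids if features is None else [
            f for f in self.feature_ids if f in set(features)
        ]
        samps = self.sample_ids if samples is None else [
            s for s in self.sample_ids if s in set(samples)
        ]
        fi = [self.feature_ids.index(f) for f in feats]
        si = [self.sample_ids.index(s) for s in samps]
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in samps if s in self.labels}
        meta = None
        if self.feature_meta is not None:
            meta = {f: self.feature_meta[f] for f in feats if f in self.feature_meta}
        return ExpressionMatrix(
            feats,
            samps,
            self.values[np.ix_(fi, si)].copy(),
            scale=self.scale,
            standardized=self.standardized,
            labels=labels,
            feature_meta=meta,
        )


@dataclass(frozen=True)
class Bicluster:
    """A (feature subset, sample subset, score) triple.

    The score is the sum of likelihood-ratio edge weights of the induced
    feature x sample submatrix in the weighted bipartite response graph.
    """

    features: frozenset[str]
    samples: frozenset[str]
    score: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", frozenset(self.features))
        object.__setattr__(self, "samples", frozenset(self.samples))
        if not self.features or not self.samples:
            raise ValueError("bicluster must have non-empty feature and sample sets")

    def elements(self) -> frozenset[str]:
        """Union of feature and sample identifiers (for overlap tests)."""
        return self.features | self.samples

    def jaccard(self, other: "Bicluster") -> float:
        a, b = self.elements(), other.elements()
        return len(a & b) / len(a | b)


class CancerMirnaNetwork:
    """Bipartite cancer-type <-> miRNA association network G = (U, V, E).

    U is the set of cancer types, V the set of miRNAs, and an edge (u, v)
    records literature evidence that miRNA v is dysregulated in cancer
    type u, optionally tagged with a direction (up / down / mixed /
    unknown). Identifiers are matched case-insensitively after trimming.
    """

    def __init__(
        self,
        edges: Iterable[tuple] = (),
    ) -> None:
        # normalized (u, v) -> direction; display names kept separately
        self._edges: dict[tuple[str, str], str] = {}
        self._display: dict[str, str] = {}
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                d = "unknown"
            else:
                u, v, d = edge
            self.add_edge(u, v, d)

    def add_edge(self, cancer_type: str, mirna: str, direction: str = "unknown") -> None:
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction tag {direction!r}")
        u, v = normalize_id(cancer_type), normalize_id(mirna)
        if u == v:
            raise ValueError(f"cancer type and miRNA share identifier {cancer_type!r}")
        self._display.setdefault(u, cancer_type.strip())
        self._display.setdefault(v, mirna.strip())
        key = (u, v)
        prev = self._edges.get(key)
        if prev is None or prev == "unknown":
            self._edges[key] = direction
        elif direction not in ("unknown", prev):
            # conflicting evidence (up vs down) collapses to "mixed"
            self._edges[key] = "mixed"

    @property
    def cancer_types(self) -> set[str]:
        return {u for u, _ in self._edges}

    @property
    def mirnas(self) -> set[str]:
        return {v for _, v in self._edges}

    @property
    def edges(self) -> dict[tuple[str, str], str]:
        return dict(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    def has_edge(self, cancer_type: str, mirna: str) -> bool:
        return (normalize_id(cancer_type), normalize_id(mirna)) in self._edges

    def mirnas_of(self, cancer_type: str) -> set[str]:
        u = normalize_id(cancer_type)
        return {v for (uu, v) in self._edges if uu == u}

    def display_name(self, normalized: str) -> str:
        return self._display.get(normalized, normalized)

    def to_graph(self):
        """Export as a networkx bipartite graph (nodes tagged with
        ``bipartite`` 0 = cancer types, 1 = miRNAs)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.cancer_types), bipartite=0)
        g.add_nodes_from(sorted(self.mirnas), bipartite=1)
        for (u, v), d in self._edges.items():
            g.add_edge(u, v, direction=d)
        return g

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CancerMirnaNetwork) and self._edges == other._edges


@dataclass
class UscModel:
    """Fitted (uncorrelated) shrunken centroid classifier state.

    ``shrunken_centroids[i, k]`` holds the class-k shrunken centroid of
    the i-th selected feature; ``s_i`` the pooled within-class standard
    deviations, ``s_0`` their median, and ``priors`` the class prior
    probabilities used in the discriminant score.
    """

    selected_features: list[str]
    class_labels: list[str]
    shrunken_centroids: np.ndarray  # selected features x classes
    overall_centroid: np.ndarray  # per selected feature
    s_i: np.ndarray  # per selected feature
    s_0: float
    priors: np.ndarray  # per class
    delta: float
    rho: float
    standardizer: Optional[dict] = None  # feature -> (mean, sd) on the raw scale

    def __post_init__(self) -> None:
        self.shrunken_centroids = np.asarray(self.shrunken_centroids, dtype=float)
        self.overall_centroid = np.asarray(self.overall_centroid, dtype=float)
        self.s_i = np.asarray(self.s_i, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        p, k = len(self.selected_features), len(self.class_labels)
        if self.shrunken_centroids.shape != (p, k):
            raise ValueError("shrunken centroid matrix shape mismatch")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        if self.delta < 0 or not (0.0 <= self.rho <= 1.0):
            raise ValueError("invalid (delta, rho)")


@dataclass
class CvResult:
    """Grid of mean classification error over (delta, rho).

    ``per_repeat_errors`` has shape (repeats, folds, |delta|, |rho|);
    ``mean_error`` is its mean over repeats and folds. ``failed`` marks
    grid cells where at least one fold's fit failed (e.g. delta so large
    no feature survives); those folds contribute error 1.0.
    """

    delta_grid: list[float]
    rho_grid: list[float]
    mean_error: np.ndarray
    per_repeat_errors: np.ndarray
    failed: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.mean_error = np.asarray(self.mean_error, dtype=float)
        self.per_repeat_errors = np.asarray(self.per_repeat_errors, dtype=float)
        self.failed = np.asarray(self.failed, dtype=bool)
        nd, nr = len(self.delta_grid), len(self.rho_grid)
        if self.mean_error.shape != (nd, nr):
            raise ValueError("mean_error shape mismatch")
        if self.per_repeat_errors.shape[2:] != (nd, nr):
            raise ValueError("per_repeat_errors grid shape mismatch")
        if np.any((self.mean_error < 0) | (self.mean_error > 1)):
            raise ValueError("mean_error entries must lie in [0, 1]")
        recomputed = self.per_repeat_errors.mean(axis=(0, 1))
        if not np.allclose(recomputed, self.mean_error, atol=1e-12):
            raise ValueError("mean_error inconsistent with per_repeat_errors")
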