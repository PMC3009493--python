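"""Network-guided simultaneous feature and sample selection.

A bicluster is *potential* when at least one of its miRNAs is a known
associate of the cancer type of at least one of its samples, i.e. the
bicluster touches the cancer-miRNA network. From each potential
bicluster, every miRNA is kept (members of a bicluster are likely
co-regulated) but only the *relevant* samples — those whose cancer type
is adjacent in the network to at least one miRNA of that bicluster.
The union over potential biclusters of kept miRNAs and samples forms
the reduced training set; classes left without samples are dropped and
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .datatypes import Bicluster, CancerMirnaNetwork, ExpressionMatrix, normalize_id

__all__ = ["is_potential", "select_relevant", "build_training_set", "SelectionReport"]


def _require_labels(b: Bicluster, labels: Mapping[str, str]) -> None:
    missing = [s for s in sorted(b.samples) if s not in labels]
    if missing:
        raise ValueError(f"bicluster samples without class labels: {missing[:5]}")


def is_potential(
    b: Bicluster,
    net: CancerMirnaNetwork,
    labels: Mapping[str, str],
    *,
    class_anywhere: bool = False,
) -> bool:
    """True iff the bicluster contains at least one cancer-miRNA association.

    With ``class_anywhere`` the looser reading is used: a bicluster is
    potential if any of its samples' classes appears anywhere in the
    network, regardless of which miRNAs the bicluster holds.
    """
    _require_labels(b, labels)
    classes = {labels[s] for s in b.samples}
    if class_anywhere:
        known = {normalize_id(c) for c in net.cancer_types}
        return any(normalize_id(c) in known for c in classes)
    return any(net.has_edge(c, m) for c in classes for m in b.features)


def select_relevant(
    b: Bicluster,
    net: CancerMirnaNetwork,
    labels: Mapping[str, str],
) -> tuple[frozenset[str], frozenset[str]]:
    """Keep all miRNAs of a potential bicluster and its relevant samples.

    A sample is relevant when its cancer type is associated in the
    network with at least one miRNA of this bicluster.
    """
    if not is_potential(b, net, labels):
        raise ValueError("bicluster has no cancer-miRNA association (not potential)")
    kept = frozenset(
        s for s in b.samples if any(net.has_edge(labels[s], m) for m in b.features)
    )
    return b.features, kept


@dataclass
class SelectionReport:
    """Counts and class bookkeeping from the selection stage."""

    n_biclusters: int
    n_potential: int
    n_features: int
    n_samples: int
    kept_classes: list[str] = field(default_factory=list)
    dropped_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "biclusters": self.n_biclusters,
            "potential_biclusters": self.n_potential,
            "selected_mirnas": self.n_features,
            "selected_samples": self.n_samples,
            "kept_classes": self.kept_classes,
            "dropped_classes": self.dropped_classes,
        }


def build_training_set(
    biclusters: list[Bicluster],
    m: ExpressionMatrix,
    net: CancerMirnaNetwork,
    labels: Mapping[str, str],
    *,
    class_anywhere: bool = False,
) -> tuple[ExpressionMatrix, SelectionReport]:
    """Assemble the reduced training matrix from potential biclusters.

    Features are the union of feature sets of potential biclusters,
    samples the union of their relevant sample sets; both keep the
    parent matrix's ordering. Classes with no surviving sample are
    dropped and listed in the report.
    """
    if not biclusters:
        raise ValueError("no biclusters supplied")
    feats: set[str] = set()
    samps: set[str] = set()
    n_potential = 0
    for b in biclusters:
        if not is_potential(b, net, labels, class_anywhere=class_anywhere):
            continue
        n_potential += 1
        if class_anywhere:
            known = {normalize_id(c) for c in net.cancer_types}
            kept = frozenset(s for s in b.samples if normalize_id(labels[s]) in known)
            bf = b.features
        else:
            bf, kept = select_relevant(b, net, labels)
        feats |= set(bf)
        samps |= set(kept)
    if n_potential == 0:
        raise ValueError("no cancer-miRNA evidence found: every bicluster is non-potential")
    sub = m.subset(features=feats, samples=samps)
    all_classes = sorted({labels[s] for s in m.sample_ids if s in labels})
    kept_classes = sorted({labels[s] for s in sub.sample_ids})
    dropped = [c for c in all_classes if c not in kept_classes]
    sub = sub.with_labels({s: labels[s] for s in sub.sample_ids})
    report = SelectionReport(
        n_biclusters=len(biclusters),
        n_potential=n_potential,
        n_features=sub.n_features,
        n_samples=sub.n_samples,
        kept_classes=kept_classes,
        dropped_classes=dropped,
    )
    return sub, report
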