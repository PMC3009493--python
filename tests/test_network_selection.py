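import numpy as np
import pytest

from oracles import potential_by_double_loop, relevant_samples_by_double_loop
from sfssclass.datatypes import Bicluster, CancerMirnaNetwork, ExpressionMatrix
from sfssclass.network_selection import build_training_set, is_potential, select_relevant


def random_case(seed):
    """A random bicluster / labeling / network triple."""
    rng = np.random.default_rng(seed)
    mirnas = [f"miR-{i}" for i in range(8)]
    cancers = [f"cancer{c}" for c in range(4)]
    samples = [f"s{j}" for j in range(10)]
    labels = {s: cancers[rng.integers(4)] for s in samples}
    b = Bicluster(
        frozenset(rng.choice(mirnas, size=rng.integers(1, 5), replace=False)),
        frozenset(rng.choice(samples, size=rng.integers(1, 6), replace=False)),
    )
    net = CancerMirnaNetwork(
        (c, m)
        for c in cancers
        for m in mirnas
        if rng.random() < 0.15
    )
    return b, net, labels


class TestIsPotential:
    def test_single_association_suffices(self):
        b = Bicluster(frozenset({"miR-21", "miR-99"}), frozenset({"s1"}))
        net = CancerMirnaNetwork([("colon", "miR-21")])
        assert is_potential(b, net, {"s1": "colon"})

    def test_empty_network_never_potential(self):
        b = Bicluster(frozenset({"miR-21"}), frozenset({"s1"}))
        assert not is_potential(b, CancerMirnaNetwork(), {"s1": "colon"})

    def test_unlabeled_sample_is_an_error(self):
        b = Bicluster(frozenset({"miR-21"}), frozenset({"s1", "s2"}))
        with pytest.raises(ValueError, match="without class labels"):
            is_potential(b, CancerMirnaNetwork([("colon", "miR-21")]), {"s1": "colon"})

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_double_loop_oracle(self, seed):
        b, net, labels = random_case(seed)
        assert is_potential(b, net, labels) == potential_by_double_loop(b, net, labels)


class TestSelectRelevant:
    def test_only_network_supported_samples_kept(self):
        b = Bicluster(frozenset({"miR-21"}), frozenset({"s1", "s2"}))
        net = CancerMirnaNetwork([("colon", "miR-21")])
        feats, samps = select_relevant(b, net, {"s1": "colon", "s2": "lung"})
        assert feats == frozenset({"miR-21"})
        assert samps == frozenset({"s1"})

    def test_saturated_network_keeps_all_samples(self):
        b = Bicluster(frozenset({"miR-1", "miR-2"}), frozenset({"s1", "s2", "s3"}))
        labels = {"s1": "colon", "s2": "lung", "s3": "colon"}
        net = CancerMirnaNetwork(
            (c, m) for c in {"colon", "lung"} for m in {"miR-1", "miR-2"}
        )
        _, samps = select_relevant(b, net, labels)
        assert samps == b.samples

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_double_loop_oracle(self, seed):
        b, net, labels = random_case(seed)
        if not is_potential(b, net, labels):
            with pytest.raises(ValueError, match="not potential"):
                select_relevant(b, net, labels)
            return
        _, samps = select_relevant(b, net, labels)
        assert samps == frozenset(relevant_samples_by_double_loop(b, net, labels))


def training_case():
    feats = [f"miR-{i}" for i in range(6)]
    samples = [f"s{j}" for j in range(8)]
    labels = {s: ("colon" if j < 3 else "lung" if j < 6 else "ovary")
              for j, s in enumerate(samples)}
    vals = np.arange(48, dtype=float).reshape(6, 8)
    m = ExpressionMatrix(feats, samples, vals, labels=labels)
    return m, labels


class TestBuildTrainingSet:
    def test_union_of_potential_biclusters(self):
        m, labels = training_case()
        net = CancerMirnaNetwork([("colon", "miR-0"), ("lung", "miR-3")])
        bcs = [
            Bicluster(frozenset({"miR-0", "miR-1"}), frozenset({"s0", "s1"})),
            Bicluster(frozenset({"miR-3"}), frozenset({"s4", "s5"})),
        ]
        sub, report = build_training_set(bcs, m, net, labels)
        assert set(sub.feature_ids) == {"miR-0", "miR-1", "miR-3"}
        assert set(sub.sample_ids) == {"s0", "s1", "s4", "s5"}
        assert report.n_potential == 2

    def test_classes_without_survivors_are_dropped_and_reported(self):
        m, labels = training_case()
        # ovary samples (s6, s7) never appear in a network-supported bicluster
        net = CancerMirnaNetwork([("colon", "miR-0")])
        bcs = [Bicluster(frozenset({"miR-0"}), frozenset({"s0", "s6"}))]
        sub, report = build_training_set(bcs, m, net, labels)
        assert report.dropped_classes == ["lung", "ovary"]
        assert report.kept_classes == ["colon"]
        assert sorted(report.kept_classes + report.dropped_classes) == [
            "colon", "lung", "ovary"
        ]
        assert all(labels[s] == "colon" for s in sub.sample_ids)

    def test_no_potential_bicluster_is_an_error(self):
        m, labels = training_case()
        bcs = [Bicluster(frozenset({"miR-0"}), frozenset({"s0"}))]
        with pytest.raises(ValueError, match="no cancer-miRNA evidence"):
            build_training_set(bcs, m, CancerMirnaNetwork(), labels)

    def test_selected_sets_are_subsets_with_network_support(self):
        m, labels = training_case()
        rng = np.random.default_rng(3)
        net = CancerMirnaNetwork(
            (c, f) for c in {"colon", "lung", "ovary"}
            for f in m.feature_ids if rng.random() < 0.4
        )
        bcs = [
            Bicluster(
                frozenset(rng.choice(m.feature_ids, 2, replace=False)),
                frozenset(rng.choice(m.sample_ids, 3, replace=False)),
            )
            for _ in range(5)
        ]
        sub, _ = build_training_set(bcs, m, net, labels)
        assert set(sub.feature_ids) <= set(m.feature_ids)
        assert set(sub.sample_ids) <= set(m.sample_ids)
        for s in sub.sample_ids:
            assert any(net.has_edge(labels[s], f) for f in sub.feature_ids)

    def test_more_edges_never_shrink_selection(self):
        m, labels = training_case()
        net1 = CancerMirnaNetwork([("colon", "miR-0")])
        net2 = CancerMirnaNetwork([("colon", "miR-0"), ("lung", "miR-1"), ("ovary", "miR-2")])
        bcs = [
            Bicluster(frozenset({"miR-0", "miR-1", "miR-2"}), frozenset({"s0", "s4", "s7"})),
        ]
        sub1, _ = build_training_set(bcs, m, net1, labels)
        sub2, _ = build_training_set(bcs, m, net2, labels)
        assert set(sub1.feature_ids) <= set(sub2.feature_ids)
        assert set(sub1.sample_ids) <= set(sub2.sample_ids)

    def test_invariant_to_bicluster_order(self):
        m, labels = training_case()
        net = CancerMirnaNetwork([("colon", "miR-0"), ("lung", "miR-3")])
        bcs = [
            Bicluster(frozenset({"miR-0"}), frozenset({"s0"})),
            Bicluster(frozenset({"miR-3", "miR-4"}), frozenset({"s3", "s4"})),
        ]
        a, _ = build_training_set(bcs, m, net, labels)
        b, _ = build_training_set(list(reversed(bcs)), m, net, labels)
        assert a.feature_ids == b.feature_ids
        assert a.sample_ids == b.sample_ids
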