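"""Affinity propagation, per-bin concept clustering, and flow tracing."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from sklearn.cluster import AffinityPropagation as SkAP
from sklearn.metrics import adjusted_rand_score

import diachron as dc
from diachron.clustering import Cluster, ClusterSet, SimilarityMatrix, _resolve_preference


# ---------------------------------------------------------------- oracle ---

def exhaustive_ap_oracle(s: np.ndarray) -> tuple[frozenset[int], float]:
    """Best exemplar set by brute-force net-similarity maximisation.

    Net similarity of an exemplar set E: every point pays its similarity to
    its best exemplar (exemplars pay their own preference s[k,k]).
    """
    n = s.shape[0]
    best, best_score = None, -np.inf
    for size in range(1, n + 1):
        for E in combinations(range(n), size):
            score = sum(s[k, k] for k in E)
            for i in range(n):
                if i not in E:
                    score += max(s[i, k] for k in E)
            if score > best_score:
                best, best_score = frozenset(E), score
    return best, best_score


def net_similarity(s: np.ndarray, exemplars: frozenset[int]) -> float:
    score = sum(s[k, k] for k in exemplars)
    for i in range(s.shape[0]):
        if i not in exemplars:
            score += max(s[i, k] for k in exemplars)
    return float(score)


def random_blocks_instance(rng, n_points=6, dim=4):
    """Two well-separated point blocks; returns (SimilarityMatrix, labels)."""
    centers = np.array([[1.0] + [0.0] * (dim - 1), [-1.0] + [0.0] * (dim - 1)])
    labels = rng.integers(0, 2, size=n_points)
    while len(set(labels.tolist())) < 2:
        labels = rng.integers(0, 2, size=n_points)
    X = centers[labels] + rng.normal(0, 0.05, size=(n_points, dim))
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    s = Xn @ Xn.T
    off = s[~np.eye(n_points, dtype=bool)]
    p = float(np.median(off))
    np.fill_diagonal(s, p)
    items = [f"w{i}" for i in range(n_points)]
    return SimilarityMatrix(items=items, s=s, preference=p), labels


# ------------------------------------------------------------ similarity ---

class TestSimilarityMatrix:
    def test_identical_vectors_offdiag_one(self, qc_run):
        _, truth, model = qc_run
        label = model.binning.labels[0]
        word = truth.topics["cardiology"][0]
        tok = model.time_token(word, label)
        clone = dc.EmbeddingModel(
            vocab=model.vocab, counts=model.counts,
            vectors=model.vectors.copy(), context_vectors=model.context_vectors,
            config=model.config, binning=model.binning)
        other = model.time_token(truth.topics["cardiology"][1], label)
        clone.vectors[clone.index[other]] = clone.vectors[clone.index[tok]]
        S = dc.similarity_matrix(clone, label,
                                 [word, truth.topics["cardiology"][1]])
        assert S.s[0, 1] == pytest.approx(1.0)

    def test_median_preference(self):
        assert _resolve_preference(np.array([0.1, 0.3, 0.5, 0.5, 0.3, 0.1]),
                                   "median") == pytest.approx(0.3)

    def test_symmetry(self, qc_run):
        _, truth, model = qc_run
        label = model.binning.labels[1]
        words = truth.topics["infection"][:12]
        S = dc.similarity_matrix(model, label, words)
        assert np.max(np.abs(S.s - S.s.T)) < 1e-12

    def test_missing_word_rejected(self, qc_run):
        _, _, model = qc_run
        with pytest.raises(KeyError):
            dc.similarity_matrix(model, model.binning.labels[0], ["notaword"])


# ---------------------------------------------------------------------- AP ---

class TestAffinityPropagation:
    def test_single_item_self_exemplar(self):
        S = SimilarityMatrix(items=["only"], s=np.array([[0.0]]), preference=0.0)
        cs = dc.affinity_propagation(S)
        assert cs.clusters == (Cluster("only", ("only",)),)

    def test_two_separated_blocks_recovered(self):
        rng = np.random.default_rng(0)
        S, labels = random_blocks_instance(rng)
        cs = dc.affinity_propagation(S)
        assert cs.converged
        assert len(cs.clusters) == 2
        got = {frozenset(c.members) for c in cs.clusters}
        want = {frozenset(S.items[i] for i in np.flatnonzero(labels == b))
                for b in (0, 1)}
        assert got == want

    def test_all_identical_vectors_single_cluster(self):
        n = 5
        s = np.ones((n, n))
        np.fill_diagonal(s, 0.5)  # preference below off-diagonal similarity
        S = SimilarityMatrix(items=[f"w{i}" for i in range(n)], s=s, preference=0.5)
        cs = dc.affinity_propagation(S)
        assert len(cs.clusters) == 1
        assert set(cs.clusters[0].members) == set(S.items)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """Converged AP attains the brute-force net-similarity optimum on at
        least 18 of 20 random well-separated 6-point instances.  Exemplar
        sets are compared by achieved net similarity because tight blocks
        make several exemplar choices exactly tied in the objective."""
        rng = np.random.default_rng(2024)
        matches = 0
        for _ in range(20):
            S, _ = random_blocks_instance(rng)
            cs = dc.affinity_propagation(S)
            got = frozenset(S.items.index(c.exemplar) for c in cs.clusters)
            _, best_score = exhaustive_ap_oracle(S.s)
            got_score = net_similarity(S.s, got)
            if cs.converged and got_score >= best_score - 1e-9:
                matches += 1
        assert matches >= 18

    def test_agrees_with_sklearn_reference(self):
        rng = np.random.default_rng(11)
        S, _ = random_blocks_instance(rng, n_points=8)
        ours = dc.affinity_propagation(S, damping=0.7)
        ref = SkAP(affinity="precomputed", damping=0.7, random_state=0,
                   max_iter=1000).fit(S.s)
        ours_labels = [ours.cluster_of(w) for w in S.items]
        assert adjusted_rand_score(ours_labels, ref.labels_) == pytest.approx(1.0)

    def test_invalid_damping_rejected(self):
        S = SimilarityMatrix(items=["a", "b"], s=np.zeros((2, 2)), preference=0.0)
        for bad in (0.4, 1.0):
            with pytest.raises(ValueError):
                dc.affinity_propagation(S, damping=bad)

    def test_nonconvergence_is_flagged(self):
        rng = np.random.default_rng(1)
        S, _ = random_blocks_instance(rng)
        cs = dc.affinity_propagation(S, max_iter=3, conv_iter=50)
        assert cs.converged is False


# ----------------------------------------------------------- time binning ---

class TestClusterTimeBins:
    def test_topics_recovered_per_bin(self, qc_run):
        corpus, truth, model = qc_run
        targets = {w for ws in truth.topics.values() for w in ws} | set(truth.drift_words)
        cluster_sets, robustness = dc.cluster_time_bins(model, targets)
        assert len(cluster_sets) == len(model.binning.labels)
        for cs in cluster_sets:
            # partition property: disjoint cover of the eligible word set
            members = [w for c in cs.clusters for w in c.members]
            assert len(members) == len(set(members))
            for c in cs.clusters:
                assert c.exemplar in c.members
            start, end = (int(x) for x in cs.bin_label.split("-"))
            mid = min(max((start + end) // 2, corpus.year_min), corpus.year_max)
            words = sorted(cs.members())
            planted = [truth.topic_members[w][mid] for w in words]
            got = [cs.labels()[w] for w in words]
            assert adjusted_rand_score(planted, got) >= 0.9
            assert robustness[cs.bin_label] >= 0.8

    def test_drift_word_changes_comembership_stable_words_do_not(self, qc_run):
        corpus, truth, model = qc_run
        targets = {w for ws in truth.topics.values() for w in ws} | set(truth.drift_words)
        cluster_sets, _ = dc.cluster_time_bins(model, targets)
        change_year = next(iter(truth.drift_words.values()))[2]
        pre_cs = next(cs for cs in cluster_sets
                      if int(cs.bin_label.split("-")[1]) < change_year)
        post_cs = next(cs for cs in cluster_sets
                       if int(cs.bin_label.split("-")[0]) >= change_year)

        def comembers(cs, w):
            return set(cs.clusters[cs.labels()[w]].members) - {w}

        for word, (pre, post, _) in truth.drift_words.items():
            pre_mates = comembers(pre_cs, word)
            post_mates = comembers(post_cs, word)
            assert pre_mates.intersection(truth.topics[pre])
            assert post_mates.intersection(truth.topics[post])
            # co-membership changed across the switch
            assert pre_mates != post_mates
        stable = [w for ws in truth.topics.values() for w in ws]
        kept = sum(
            1 for w in stable
            if {m for m in comembers(pre_cs, w) if m in stable}
            == {m for m in comembers(post_cs, w) if m in stable})
        assert kept / len(stable) >= 0.9

    def test_empty_target_list(self, qc_run):
        _, _, model = qc_run
        cluster_sets, robustness = dc.cluster_time_bins(model, [])
        assert cluster_sets == []
        assert robustness == {}


# ------------------------------------------------------------------- flow ---

def _cs(label, *groups):
    return ClusterSet(label, tuple(Cluster(g[0], tuple(g)) for g in groups))


class TestConceptFlow:
    def test_handcrafted_two_bin_example(self):
        bin1 = _cs("1900-1924", ["a", "b", "c"], ["d", "e"])
        bin2 = _cs("1925-1949", ["a", "d"], ["b", "c", "e"])
        # seed cluster {a, d}: edges abc->ad:1, de->ad:1
        flow = dc.trace_concept_flow([bin1, bin2], bin2.clusters[0])
        weights = {(f, t): w for f, t, w in flow.edges}
        assert weights == {(("1900-1924", 0), ("1925-1949", 0)): 1,
                           (("1900-1924", 1), ("1925-1949", 0)): 1}
        # tracking all of bin2 reproduces the full four-edge flow
        flow_all = dc.trace_concept_flow([bin1, bin2], {"a", "b", "c", "d", "e"})
        weights = {(f, t): w for f, t, w in flow_all.edges}
        assert weights == {(("1900-1924", 0), ("1925-1949", 0)): 1,
                           (("1900-1924", 1), ("1925-1949", 0)): 1,
                           (("1900-1924", 0), ("1925-1949", 1)): 2,
                           (("1900-1924", 1), ("1925-1949", 1)): 1}

    def test_identity_partitions_identity_flow(self):
        bins = [_cs("b1", ["a", "b"], ["c"]), _cs("b2", ["a", "b"], ["c"])]
        flow = dc.trace_concept_flow(bins, bins[-1].clusters[0])
        assert flow.edges == [(("b1", 0), ("b2", 0), 2)]

    def test_disjoint_vocabularies_no_edges(self):
        bins = [_cs("b1", ["x", "y"]), _cs("b2", ["a", "b"])]
        flow = dc.trace_concept_flow(bins, bins[-1].clusters[0])
        assert flow.edges == []

    def test_missing_seed_cluster_rejected(self):
        bins = [_cs("b1", ["a"])]
        with pytest.raises(KeyError):
            dc.trace_concept_flow(bins, 5)

    def test_flow_conservation_on_random_partitions(self):
        """Sum of edge weights between consecutive bins equals the number of
        tracked words present in both partitions."""
        rng = np.random.default_rng(42)
        words = [f"w{i}" for i in range(40)]
        for trial in range(10):
            bins = []
            for b in range(4):
                present = [w for w in words if rng.random() < 0.8]
                k = int(rng.integers(1, 6))
                assign = rng.integers(0, k, size=len(present))
                groups = [[w for w, a in zip(present, assign) if a == g]
                          for g in range(k)]
                groups = [g for g in groups if g]
                bins.append(_cs(f"b{b}", *groups))
            seed_idx = int(rng.integers(0, len(bins[-1].clusters)))
            flow = dc.trace_concept_flow(bins, seed_idx)
            tracked = set(bins[-1].clusters[seed_idx].members)
            for b in range(3):
                expected = len(tracked & bins[b].members() & bins[b + 1].members())
                got = sum(w for (fb, _), (tb, _), w in flow.edges
                          if fb == f"b{b}" and tb == f"b{b+1}")
                assert got == expected
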