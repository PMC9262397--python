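"""Concept clustering per time bin and cluster-flow tracing across bins.

Word vectors for a given time period are clustered with affinity propagation
(AP), an exemplar-based message-passing algorithm that does not require the
number or size of clusters in advance: the "preference" (self-similarity
placed on the diagonal) controls granularity, and damped responsibility /
availability messages are iterated until the exemplar set is stable.

Higher-level concept evolution is then read off a flow graph: clusters in
consecutive bins are connected by edges weighted by how many tracked words
they share.  Cluster identity across periods is never inferred from labels
or exemplars — only shared members create a connection, and the absence of
an edge means two consecutive clusters share no words.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .corpus import TimeBinning
from .embeddings import EmbeddingModel, TIME_SEP

__all__ = [
    "SimilarityMatrix",
    "APResult",
    "Cluster",
    "ClusterSet",
    "FlowGraph",
    "similarity_matrix",
    "affinity_propagation",
    "cluster_time_bins",
    "trace_concept_flow",
    "export_cluster_sets_json",
    "load_cluster_sets_json",
    "export_flow_json",
]


@dataclass
class SimilarityMatrix:
    """Pairwise similarities over an ordered item list, diagonal = preference."""

    items: list[str]
    s: np.ndarray
    preference: float

    def __post_init__(self) -> None:
        n = len(self.items)
        if self.s.shape != (n, n):
            raise ValueError("similarity matrix shape does not match item count")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("similarity matrix contains non-finite entries")


def _resolve_preference(s_off: np.ndarray, preference: float | str) -> float:
    if isinstance(preference, str):
        if preference != "median":
            raise ValueError(f"unknown preference {preference!r}")
        return float(np.median(s_off)) if s_off.size else 0.0
    return float(preference)


def similarity_matrix(
    model: EmbeddingModel,
    bin_label: str,
    words: Sequence[str],
    preference: float | str = "median",
    metric: str = "cosine",
) -> SimilarityMatrix:
    """Pairwise similarity of bin-specific word vectors.

    ``metric`` is cosine (default, consistent with the neighbour analysis) or
    ``neg_euclidean`` (negative squared Euclidean distance, the classic AP
    similarity).  The diagonal carries the preference; "median" resolves to
    the median off-diagonal similarity.
    """
    vecs = []
    for w in words:
        tok = model.time_token(w, bin_label)
        if tok not in model:
            raise KeyError(f"no vector for {w!r} in bin {bin_label!r}")
        vecs.append(model.vector(tok))
    X = np.asarray(vecs, dtype=np.float64)
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        Xn = X / norms
        s = Xn @ Xn.T
    elif metric == "neg_euclidean":
        sq = (X ** 2).sum(1)
        s = -(sq[:, None] + sq[None, :] - 2.0 * X @ X.T)
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    n = len(words)
    off = s[~np.eye(n, dtype=bool)]
    p = _resolve_preference(off, preference)
    np.fill_diagonal(s, p)
    return SimilarityMatrix(items=list(words), s=s, preference=p)


@dataclass(frozen=True)
class Cluster:
    exemplar: str
    members: tuple[str, ...]


@dataclass
class ClusterSet:
    """A partition of one bin's word set into exemplar-led clusters."""

    bin_label: str
    clusters: tuple[Cluster, ...]
    converged: bool = True
    n_iter: int = 0

    def labels(self) -> dict[str, int]:
        return {w: ci for ci, cl in enumerate(self.clusters) for w in cl.members}

    def members(self) -> set[str]:
        return {w for cl in self.clusters for w in cl.members}

    def cluster_of(self, word: str) -> int:
        return self.labels()[word]


@dataclass
class APResult:
    cluster_set: ClusterSet
    exemplar_indices: tuple[int, ...]


def affinity_propagation(
    S: SimilarityMatrix,
    damping: float = 0.5,
    max_iter: int = 1000,
    conv_iter: int = 50,
    noise_seed: int = 0,
    bin_label: str = "",
) -> ClusterSet:
    """Cluster by damped responsibility/availability message passing.

    Iterates the standard updates

        r(i,k) <- (1-l) * [s(i,k) - max_{k'!=k} (a(i,k') + s(i,k'))] + l * r
        a(i,k) <- (1-l) * min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k))) + l * a   (i != k)
        a(k,k) <- (1-l) * sum_{i'!=k} max(0, r(i',k)) + l * a

    until the exemplar set E = {k : r(k,k) + a(k,k) > 0} is unchanged for
    ``conv_iter`` iterations or ``max_iter`` is reached.  Each non-exemplar
    joins the exemplar maximising s(i,k).  Non-convergence is never silent:
    the returned partition is flagged ``converged=False``.

    Tiny symmetric seeded noise (scale 1e-12) is added to the similarities to
    break exemplar ties deterministically.
    """
    if not (0.5 <= damping < 1.0):
        raise ValueError(f"damping must be in [0.5, 1), got {damping}")
    n = len(S.items)
    if n == 1:
        return ClusterSet(bin_label, (Cluster(S.items[0], (S.items[0],)),),
                          converged=True, n_iter=0)
    rng = np.random.default_rng(noise_seed)
    jitter = rng.standard_normal((n, n)) * 1e-12
    s = S.s + (jitter + jitter.T) / 2.0

    r = np.zeros((n, n))
    a = np.zeros((n, n))
    lam = damping
    idx = np.arange(n)
    prev_exemplars: frozenset[int] | None = None
    stable = 0
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        # responsibilities
        as_ = a + s
        first = as_.max(axis=1)
        first_k = as_.argmax(axis=1)
        tmp = as_.copy()
        tmp[idx, first_k] = -np.inf
        second = tmp.max(axis=1)
        max_excl = np.full((n, n), first[:, None])
        max_excl[idx, first_k] = second
        r = (1.0 - lam) * (s - max_excl) + lam * r
        # availabilities
        rp = np.maximum(r, 0.0)
        np.fill_diagonal(rp, 0.0)
        col = rp.sum(axis=0)
        a_new = np.minimum(0.0, r.diagonal()[None, :] + col[None, :] - rp)
        np.fill_diagonal(a_new, col)
        a = (1.0 - lam) * a_new + lam * a
        exemplars = frozenset(np.flatnonzero(r.diagonal() + a.diagonal() > 0).tolist())
        if exemplars and exemplars == prev_exemplars:
            stable += 1
            if stable >= conv_iter:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars
    ex = sorted(np.flatnonzero(r.diagonal() + a.diagonal() > 0).tolist())
    if not ex:
        # degenerate fallback: the best single exemplar under net similarity
        ex = [int(np.argmax(s.sum(axis=0)))]
    assign = {}
    ex_arr = np.array(ex)
    for i in range(n):
        if i in ex:
            assign[i] = i
        else:
            assign[i] = int(ex_arr[np.argmax(s[i, ex_arr])])
    clusters = []
    for k in ex:
        members = tuple(S.items[i] for i in range(n) if assign[i] == k)
        clusters.append(Cluster(exemplar=S.items[k], members=members))
    return ClusterSet(bin_label, tuple(clusters), converged=converged, n_iter=it)


def _eligible_words(model: EmbeddingModel, targets: Iterable[str], label: str) -> list[str]:
    return sorted(w for w in set(targets) if model.time_token(w, label) in model)


def _ap_converged(S: SimilarityMatrix, damping: float, max_iter: int,
                  conv_iter: int, noise_seed: int, bin_label: str) -> ClusterSet:
    """AP with damping escalation: oscillation at low damping is a known
    failure mode on dense similarity matrices, so on non-convergence the
    run is retried with heavier damping before the partial result is
    accepted (still flagged unconverged if every level fails)."""
    result = None
    lam = damping
    while True:
        result = affinity_propagation(S, damping=lam, max_iter=max_iter,
                                      conv_iter=conv_iter, noise_seed=noise_seed,
                                      bin_label=bin_label)
        if result.converged or lam >= 0.9:
            return result
        lam = min(0.9, lam + 0.2)


def cluster_time_bins(
    model: EmbeddingModel,
    targets: Iterable[str],
    binning: TimeBinning | None = None,
    preference: float | str = "median",
    damping: float = 0.5,
    max_iter: int = 1000,
    conv_iter: int = 50,
    noise_seed: int = 0,
    robustness_dampings: Sequence[float] = (0.5, 0.7, 0.9),
) -> tuple[list[ClusterSet], dict[str, float]]:
    """One ClusterSet per time bin over the eligible target words.

    Eligibility = the word has a vector for that bin (it met min_count there).
    Alongside the partitions, a robustness report is returned: for each bin,
    the mean pairwise adjusted Rand index between repeat AP runs with
    different damping factors (and correspondingly different tie-break
    seeds) — high agreement indicates the clusters are not an artefact of one
    parameterisation.
    """
    targets = sorted(set(targets))
    if binning is None:
        binning = model.binning
    if binning is None:
        raise ValueError("no binning available: pass one or use a temporal model")
    cluster_sets: list[ClusterSet] = []
    robustness: dict[str, float] = {}
    if not targets:
        return cluster_sets, robustness
    for label in binning.labels:
        words = _eligible_words(model, targets, label)
        if not words:
            continue
        if len(words) < 2:
            cluster_sets.append(ClusterSet(label, (Cluster(words[0], (words[0],)),)))
            robustness[label] = 1.0
            continue
        S = similarity_matrix(model, label, words, preference=preference)
        primary = _ap_converged(S, damping, max_iter, conv_iter, noise_seed, label)
        cluster_sets.append(primary)
        runs = [primary]
        for j, dmp in enumerate(robustness_dampings):
            if dmp == damping:
                continue
            runs.append(_ap_converged(S, dmp, max_iter, conv_iter,
                                      noise_seed + j + 1, label))
        aris = []
        for ra, rb in combinations(runs, 2):
            la, lb = ra.labels(), rb.labels()
            aris.append(adjusted_rand_score([la[w] for w in words],
                                            [lb[w] for w in words]))
        robustness[label] = float(np.mean(aris)) if aris else 1.0
    return cluster_sets, robustness


@dataclass
class FlowGraph:
    """Clusters per bin plus shared-word flow edges between consecutive bins."""

    tracked_words: tuple[str, ...]
    nodes: list[tuple[str, int]]                       # (bin label, cluster id)
    edges: list[tuple[tuple[str, int], tuple[str, int], int]]  # (from, to, weight)
    node_members: dict[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)


def trace_concept_flow(cluster_sets: Sequence[ClusterSet],
                       seed_cluster: Cluster | int | Iterable[str]) -> FlowGraph:
    """Trace a latest-bin cluster's members backward through time.

    The tracked words are the seed cluster's members in the final bin (the
    seed may be given as a cluster, its index within the latest bin, or an
    explicit word set).  In every bin, nodes are the clusters containing at
    least one tracked word; edges connect clusters in consecutive bins,
    weighted by the number of tracked words in both endpoints.  A word absent
    from a bin's partition contributes nothing there, and zero shared words
    means no edge.
    """
    if not cluster_sets:
        raise ValueError("no cluster sets to trace")
    last = cluster_sets[-1]
    if isinstance(seed_cluster, int):
        try:
            seed = last.clusters[seed_cluster]
        except IndexError:
            raise KeyError(f"no cluster {seed_cluster} in bin {last.bin_label!r}")
        tracked = set(seed.members)
    elif isinstance(seed_cluster, Cluster):
        if seed_cluster not in last.clusters:
            raise KeyError("seed cluster does not belong to the latest bin")
        tracked = set(seed_cluster.members)
    else:
        tracked = set(seed_cluster)

    nodes: list[tuple[str, int]] = []
    node_members: dict[tuple[str, int], tuple[str, ...]] = {}
    per_bin_hits: list[list[tuple[int, set[str]]]] = []
    for cs in cluster_sets:
        hits = []
        for ci, cl in enumerate(cs.clusters):
            shared = tracked.intersection(cl.members)
            if shared:
                nodes.append((cs.bin_label, ci))
                node_members[(cs.bin_label, ci)] = tuple(sorted(shared))
                hits.append((ci, shared))
        per_bin_hits.append(hits)

    edges: list[tuple[tuple[str, int], tuple[str, int], int]] = []
    for b in range(len(cluster_sets) - 1):
        early, late = cluster_sets[b], cluster_sets[b + 1]
        for ci, early_shared in per_bin_hits[b]:
            for cj, late_shared in per_bin_hits[b + 1]:
                w = len(early_shared & late_shared)
                if w >= 1:
                    edges.append(((early.bin_label, ci), (late.bin_label, cj), w))
    return FlowGraph(tracked_words=tuple(sorted(tracked)), nodes=nodes,
                     edges=edges, node_members=node_members)


def export_cluster_sets_json(cluster_sets: Sequence[ClusterSet], path: str | Path,
                             robustness: dict[str, float] | None = None) -> Path:
    payload = {
        "bins": [
            {
                "bin": cs.bin_label,
                "converged": cs.converged,
                "n_iter": cs.n_iter,
                "clusters": [
                    {"exemplar": cl.exemplar, "members": list(cl.members)}
                    for cl in cs.clusters
                ],
            }
            for cs in cluster_sets
        ],
        "robustness_ari": robustness or {},
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return path


def load_cluster_sets_json(path: str | Path) -> list[ClusterSet]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for entry in payload["bins"]:
        clusters = tuple(Cluster(c["exemplar"], tuple(c["members"]))
                         for c in entry["clusters"])
        out.append(ClusterSet(entry["bin"], clusters,
                              converged=entry.get("converged", True),
                              n_iter=entry.get("n_iter", 0)))
    return out


def export_flow_json(flow: FlowGraph, path: str | Path) -> Path:
    payload = {
        "tracked_words": list(flow.tracked_words),
        "nodes": [{"bin": b, "cluster": c,
                   "tracked_members": list(flow.node_members.get((b, c), ()))}
                  for b, c in flow.nodes],
        "edges": [{"from": {"bin": fb, "cluster": fc},
                   "to": {"bin": tb, "cluster": tc}, "weight": w}
                  for (fb, fc), (tb, tc), w in flow.edges],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return path
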