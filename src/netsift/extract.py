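"""Adaptive dense-subnetwork extraction from a weighted inference matrix.

A candidate node set ``S`` is scored by

    T(S) = sum over pairs {i,j} in S of (w_ij - lambda)

so each intra-set edge must clear the shrinkage floor ``lambda`` (in
``-log10 p`` units) to contribute.  The penalty is an l0-style control on the
number of edges: sparse or weakly significant sets score at or below zero
and are never reported.  ``lambda = -log10(0.05)`` by default, i.e. an edge
"pays for itself" only when its p-value beats 0.05.

Extraction is greedy with local refinement and peel-off:

1. seed from a maximal remaining edge (several top edges are tried and the
   best resulting candidate kept);
2. grow by repeatedly adding the node with the largest positive score gain;
3. refine by single-node removal and swap passes until no move improves;
4. accept the set if its score is positive and it has at least ``min_size``
   nodes, remove its nodes from the graph, and repeat.

An exhaustive enumerator over all node subsets is provided for small graphs
as an independent optimum oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

DEFAULT_LAMBDA = -float(np.log10(0.05))


@dataclass
class Subnetwork:
    """A scored node set: ``T(S)``, significant-edge density and count."""

    nodes: tuple
    score: float
    density: float = np.nan
    n_edges_sig: int = 0
    p_value: float = np.nan

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class ExtractionResult:
    subnetworks: list
    lam: float
    trace: list = field(default_factory=list)

    def __len__(self):
        return len(self.subnetworks)

    def __iter__(self):
        return iter(self.subnetworks)

    @property
    def node_sets(self) -> list:
        return [set(s.nodes) for s in self.subnetworks]


def _as_weight_matrix(W) -> np.ndarray:
    w = getattr(W, "w", W)
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("W must be a square matrix or an InferenceMatrix")
    w = np.where(np.isfinite(w), w, 0.0)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


def subnetwork_score(W, S, lam: float) -> float:
    """``T(S) = sum_{i<j in S} (w_ij - lambda)``."""
    w = _as_weight_matrix(W)
    nodes = sorted(set(int(v) for v in S))
    if len(nodes) < 2:
        raise ValueError("a subnetwork needs at least 2 nodes")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if nodes[0] < 0 or nodes[-1] >= w.shape[0]:
        raise ValueError(f"node ids out of range for {w.shape[0]} nodes")
    sub = w[np.ix_(nodes, nodes)]
    k = len(nodes)
    return float(sub.sum() / 2.0 - lam * k * (k - 1) / 2.0)


def density(W, S, p_thresh: float = 0.05) -> float:
    """Fraction of intra-set edges significant at ``p_thresh``.

    Works directly on the weight scale: an edge counts when
    ``w > -log10(p_thresh)``.
    """
    w = _as_weight_matrix(W)
    nodes = sorted(set(int(v) for v in S))
    if len(nodes) < 2:
        raise ValueError("density needs at least 2 nodes")
    thr = -np.log10(p_thresh)
    sub = w[np.ix_(nodes, nodes)]
    iu = np.triu_indices(len(nodes), k=1)
    sig = int((sub[iu] > thr).sum())
    return sig / len(iu[0])


def _count_significant(w, nodes, p_thresh):
    thr = -np.log10(p_thresh)
    sub = w[np.ix_(list(nodes), list(nodes))]
    iu = np.triu_indices(len(nodes), k=1)
    return int((sub[iu] > thr).sum())


def _grow_and_refine(w, lam, seed_edge, active, max_passes=60):
    """Greedy growth from a seed edge plus removal/swap refinement.

    Returns (nodes tuple, score, growth trace).  ``active`` is a boolean mask
    of nodes still available.  Ties broken by lowest node id (argmax on a
    vector returns the first maximum, and node order is ascending).
    """
    n = w.shape[0]
    i, j = seed_edge
    in_set = np.zeros(n, dtype=bool)
    in_set[[i, j]] = True
    score = w[i, j] - lam
    # gain[v] = sum_{u in S} (w[v,u] - lam) for v outside S
    gain = w[:, i] + w[:, j] - 2 * lam
    trace = [(2, score)]
    # growth
    while True:
        cand = active & ~in_set
        if not cand.any():
            break
        masked = np.where(cand, gain, -np.inf)
        v = int(np.argmax(masked))
        if masked[v] <= 0:
            break
        in_set[v] = True
        score += gain[v]
        gain = gain + w[:, v] - lam
        trace.append((int(in_set.sum()), score))
    # refinement: removals, additions, swaps
    for _ in range(max_passes):
        nodes = np.flatnonzero(in_set)
        k = len(nodes)
        if k < 2:
            break
        # in-gain of member v: its contribution to the score
        contrib = w[np.ix_(range(n), nodes)].sum(axis=1) - lam * k
        in_gain = contrib[nodes] + lam  # v's own (zero) diagonal costs no lam
        # worst member and best outsider
        worst = nodes[int(np.argmin(in_gain))]
        worst_gain = float(in_gain.min())
        out_mask = active & ~in_set
        if out_mask.any():
            out_gain_vec = np.where(out_mask, contrib, -np.inf)
            best_out = int(np.argmax(out_gain_vec))
            best_out_gain = float(out_gain_vec[best_out])
        else:
            best_out, best_out_gain = None, -np.inf
        moved = False
        if worst_gain < 0 and k > 2:
            in_set[worst] = False
            score -= worst_gain
            moved = True
        elif best_out is not None and best_out_gain > 0:
            in_set[best_out] = True
            score += best_out_gain
            moved = True
        elif (
            best_out is not None
            and k > 2
            and best_out_gain - (w[best_out, worst] - lam) - worst_gain > 1e-12
        ):
            # swap worst member for best outsider
            delta = best_out_gain - (w[best_out, worst] - lam) - worst_gain
            in_set[worst] = False
            in_set[best_out] = True
            score += delta
            moved = True
        if not moved:
            break
        trace.append((int(in_set.sum()), score))
    nodes = tuple(int(v) for v in np.flatnonzero(in_set))
    return nodes, float(score), trace


def extract_subnetworks(
    W,
    lam: float = DEFAULT_LAMBDA,
    min_size: int = 5,
    max_subnetworks: int = 10,
    p_thresh: float = 0.05,
    n_seed_candidates: int = 5,
    max_seed_attempts: int = 25,
) -> ExtractionResult:
    """Peel off disjoint positive-score dense subnetworks from ``W``.

    Candidate growth is attempted from the ``n_seed_candidates`` strongest
    remaining edges; the best accepted candidate is peeled (its nodes'
    rows/columns zeroed) and the search restarts.  Extraction stops when no
    candidate of size >= ``min_size`` with positive score is found within
    ``max_seed_attempts`` rejected seeds, or ``max_subnetworks`` is reached.
    All returned node sets are pairwise disjoint.
    """
    w = _as_weight_matrix(W).copy()
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    n = w.shape[0]
    active = np.ones(n, dtype=bool)
    found, trace = [], []
    while len(found) < max_subnetworks:
        best = None
        attempts = 0
        # candidate seed edges in decreasing weight among active nodes
        wa = np.where(np.outer(active, active), w, 0.0)
        iu = np.triu_indices(n, k=1)
        weights = wa[iu]
        order = np.argsort(-weights, kind="stable")
        for pos in order[: max(n_seed_candidates, 1)]:
            if weights[pos] <= lam:
                break
            if attempts >= max_seed_attempts:
                break
            seed = (int(iu[0][pos]), int(iu[1][pos]))
            nodes, score, gtrace = _grow_and_refine(w, lam, seed, active)
            attempts += 1
            if len(nodes) >= min_size and score > 0:
                if best is None or score > best[1]:
                    best = (nodes, score, seed, gtrace)
        if best is None:
            break
        nodes, score, seed, gtrace = best
        sub = Subnetwork(
            nodes=nodes,
            score=score,
            density=density(w, nodes, p_thresh),
            n_edges_sig=_count_significant(w, nodes, p_thresh),
        )
        found.append(sub)
        trace.append({"seed_edge": seed, "growth": gtrace, "score": score})
        # peel off: drop the accepted nodes entirely
        active[list(nodes)] = False
        w[list(nodes), :] = 0.0
        w[:, list(nodes)] = 0.0
    return ExtractionResult(subnetworks=found, lam=lam, trace=trace)


def brute_force_best_subgraph(W, lam: float, max_nodes: int = 15) -> Subnetwork:
    """Exhaustive maximizer of ``T(S)`` over all node subsets of size >= 2.

    Refuses graphs larger than ``max_nodes`` (combinatorial guard).  Ties are
    broken toward smaller sets, then lexicographic node order.  An all-zero
    (or uniformly sub-threshold) matrix yields an empty degenerate result
    with score 0.
    """
    w = _as_weight_matrix(W)
    n = w.shape[0]
    if n > max_nodes:
        raise ValueError(f"brute force refused for N={n} > max_nodes={max_nodes}")
    best_nodes, best_score = (), 0.0
    for k in range(2, n + 1):
        penalty = lam * k * (k - 1) / 2.0
        for S in combinations(range(n), k):
            sub = w[np.ix_(S, S)]
            score = sub.sum() / 2.0 - penalty
            if score > best_score + 1e-12:
                best_nodes, best_score = S, score
    if not best_nodes:
        return Subnetwork(nodes=(), score=0.0, density=0.0)
    return Subnetwork(
        nodes=tuple(best_nodes),
        score=float(best_score),
        density=density(w, best_nodes),
        n_edges_sig=_count_significant(w, best_nodes, 0.05),
    )
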