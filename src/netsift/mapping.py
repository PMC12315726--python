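"""Interpretation of extracted subnetworks against predefined networks.

Data-driven node sets are tallied against a parcellation's predefined
functional networks (e.g. the Yeo-7 assignment), compared across cohorts by
node-set overlap, and screened for hub regions whose age-related edges reach
essentially every other member of the subnetwork.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ParcellationInfo


def map_to_predefined(S, parc: ParcellationInfo) -> pd.DataFrame:
    """Tally a node set per predefined network.

    Returns a frame indexed by network with columns ``count`` (members of S
    in that network), ``network_size`` and ``fraction_of_network``
    (count / network_size).  Counts sum to ``|S|``; networks with zero counts
    are included so reports are comparable across sets.
    """
    S = sorted(set(int(v) for v in S))
    if S and (S[0] < 0 or S[-1] >= parc.n_nodes):
        raise ValueError("node set contains ids outside the parcellation")
    sizes = parc.df.groupby("network").size()
    counts = pd.Series(0, index=sizes.index, dtype=int)
    if S:
        in_set = parc.df[parc.df["node_id"].isin(S)]
        got = in_set.groupby("network").size()
        counts.loc[got.index] = got
    out = pd.DataFrame(
        {
            "count": counts,
            "network_size": sizes,
            "fraction_of_network": counts / sizes,
        }
    )
    out.index.name = "network"
    return out.sort_values("count", ascending=False)


def replication_overlap(S1, S2):
    """Node-set replication: ``(overlap set, overlap count, Jaccard index)``."""
    a, b = set(int(v) for v in S1), set(int(v) for v in S2)
    inter = a & b
    union = a | b
    jaccard = len(inter) / len(union) if union else 1.0
    return sorted(inter), len(inter), jaccard


def overlap_pvalue(n_total: int, size1: int, size2: int, overlap: int) -> float:
    """Hypergeometric tail probability of observing >= ``overlap`` shared nodes.

    A convenience measure of cross-cohort consistency under random node
    sampling; this is this package's own construction, not a replication of
    any published joint false-positive computation.
    """
    if not (0 <= overlap <= min(size1, size2) <= n_total):
        raise ValueError("inconsistent overlap arguments")
    return float(stats.hypergeom.sf(overlap - 1, n_total, size1, size2))


def identify_hubs(W, S, p_thresh: float = 0.05, coverage_min: float = 1.0):
    """Members of ``S`` whose significant edges cover >= ``coverage_min`` of S.

    Coverage of node ``i`` is ``#{j in S, j != i : p_ij < p_thresh}/(|S|-1)``,
    evaluated on the weight scale as ``w_ij > -log10(p_thresh)``.  The default
    ``coverage_min = 1.0`` demands connections to *all* other members (the
    strict hub definition).
    """
    from .extract import _as_weight_matrix

    if not (0.0 < coverage_min <= 1.0):
        raise ValueError("coverage_min must be in (0, 1]")
    nodes = sorted(set(int(v) for v in S))
    if len(nodes) < 2:
        raise ValueError("hub search needs at least 2 nodes")
    w = _as_weight_matrix(W)
    if nodes[-1] >= w.shape[0]:
        raise ValueError("node set exceeds matrix size")
    thr = -np.log10(p_thresh)
    sub = w[np.ix_(nodes, nodes)] > thr
    np.fill_diagonal(sub, False)
    coverage = sub.sum(axis=1) / (len(nodes) - 1)
    return [nodes[k] for k in np.flatnonzero(coverage >= coverage_min - 1e-12)]


def edge_overlap(W1, W2, p_thresh: float = 0.05):
    """Secondary report: Jaccard of significant edge sets of two matrices."""
    from .extract import _as_weight_matrix

    a = _as_weight_matrix(W1)
    b = _as_weight_matrix(W2)
    if a.shape != b.shape:
        raise ValueError("matrices must share the parcellation")
    thr = -np.log10(p_thresh)
    iu = np.triu_indices(a.shape[0], k=1)
    sa, sb = a[iu] > thr, b[iu] > thr
    union = int((sa | sb).sum())
    inter = int((sa & sb).sum())
    return inter, (inter / union if union else 1.0)
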