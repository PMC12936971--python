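"""Hub-topology profiling of morphometric similarity networks.

Three node-level hubness metrics are computed on proportionally
thresholded, weighted MSNs:

* degree centrality — node strength, the sum of incident edge weights;
* nodal efficiency — mean inverse shortest-path length to every other
  node, with edge lengths 1/weight and 1/d = 0 for unreachable pairs;
* participation coefficient — Guimera-Amaral 1 - sum_s (k_is / k_i)^2
  against a fixed community partition, so that values are comparable
  across subjects.

The partition is estimated once from the mean control network by
seeded consensus modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "threshold_network",
    "degree_centrality",
    "nodal_efficiency",
    "participation_coefficient",
    "consensus_partition",
    "topology_profile",
    "TopologyProfile",
]

METRIC_NAMES = ("degree_centrality", "nodal_efficiency", "participation_coefficient")

DEFAULT_SPARSITY = 0.3


@dataclass
class TopologyProfile:
    """Per-subject node x metric hubness array.

    ``metrics`` columns follow :data:`METRIC_NAMES` order.
    """

    subject_id: str
    metrics: np.ndarray = field(repr=False)  # nodes x 3
    partition_used: np.ndarray = field(repr=False)
    sparsity: float = DEFAULT_SPARSITY


def threshold_network(matrix: np.ndarray, sparsity: float) -> np.ndarray:
    """Keep the strongest ``sparsity`` fraction of off-diagonal edges.

    Retains the top ``round(sparsity * R*(R-1)/2)`` undirected edges by
    weight; ties at the cutoff are broken in favor of lexicographically
    smaller (i, j).  Returns a symmetric weighted adjacency matrix with
    zero diagonal.  Idempotent at fixed sparsity.
    """
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    m = np.asarray(matrix, dtype=float)
    R = m.shape[0]
    iu, ju = np.triu_indices(R, k=1)
    w = m[iu, ju]
    n_keep = int(round(sparsity * w.size))
    # sort by (-weight, i, j): stable lexicographic tie-break
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_keep]
    out = np.zeros_like(m)
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    return out


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(a < 0):
        raise ValueError("edge weights must be non-negative")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    return a


def degree_centrality(adj: np.ndarray) -> np.ndarray:
    """Weighted degree (node strength): row sums of the adjacency."""
    a = _check_adjacency(adj)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    """E(i) = mean over j != i of 1/d(i, j) with lengths 1/weight.

    Unreachable pairs contribute 0.  A single-node graph returns [0].
    """
    a = _check_adjacency(adj)
    R = a.shape[0]
    if R == 1:
        return np.zeros(1)
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return inv.sum(axis=1) / (R - 1)


def participation_coefficient(adj: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Guimera-Amaral participation coefficient against a fixed partition.

    PC(i) = 1 - sum_s (k_is / k_i)^2 where k_is is node i's strength into
    module s.  Isolated nodes (zero strength) get PC = 0 by convention.
    """
    a = _check_adjacency(adj)
    part = np.asarray(partition)
    if part.shape[0] != a.shape[0]:
        raise ValueError("partition must label every node")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    modules = np.unique(part)
    onehot = (part[:, None] == modules[None, :]).astype(float)
    k_is = a @ onehot  # nodes x modules
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, k_is / np.where(k > 0, k, 1.0)[:, None], 0.0)
    pc = 1.0 - np.sum(frac**2, axis=1)
    pc[k == 0] = 0.0
    return pc


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities by first appearance so output is order-stable."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _louvain(adj: np.ndarray, gamma: float, seed: int) -> np.ndarray:
    g = nx.from_numpy_array(adj)
    comms = nx.community.louvain_communities(g, weight="weight", resolution=gamma, seed=seed)
    labels = np.empty(adj.shape[0], dtype=int)
    for lab, nodes in enumerate(comms):
        for n in nodes:
            labels[n] = lab
    return _canonical_labels(labels)


def consensus_partition(
    control_adjs: list[np.ndarray] | np.ndarray,
    gamma: float = 1.0,
    n_reps: int = 20,
    seed: int = 0,
    max_consensus_iter: int = 10,
) -> np.ndarray:
    """Consensus modularity partition of the mean control network.

    Louvain is run ``n_reps`` times with derived seeds on the mean network;
    the co-assignment matrix is then itself partitioned, iterating until
    all runs agree (Lancichinetti-Fortunato consensus).  Deterministic for
    a fixed ``seed``.
    """
    adjs = list(control_adjs) if not isinstance(control_adjs, np.ndarray) else [control_adjs]
    if len(adjs) == 0:
        raise ValueError("need at least one control graph")
    mean_adj = np.mean([_check_adjacency(a) for a in adjs], axis=0)
    np.fill_diagonal(mean_adj, 0.0)

    current = mean_adj
    for _ in range(max_consensus_iter):
        runs = np.stack([_louvain(current, gamma, seed * 100003 + r) for r in range(n_reps)])
        if all(np.array_equal(runs[0], runs[i]) for i in range(1, n_reps)):
            return runs[0]
        co = np.mean(runs[:, :, None] == runs[:, None, :], axis=0).astype(float)
        np.fill_diagonal(co, 0.0)
        co[co < 0.5] = 0.0  # standard consensus threshold
        current = co
    return runs[0]


def topology_profile(
    msn_matrix: np.ndarray,
    partition: np.ndarray,
    subject_id: str = "subject",
    sparsity: float = DEFAULT_SPARSITY,
    warn_disconnected: bool = False,
) -> TopologyProfile:
    """Threshold an MSN and compute the three hubness metrics."""
    adj = threshold_network(msn_matrix, sparsity)
    if warn_disconnected:
        n_comp = nx.number_connected_components(nx.from_numpy_array(adj))
        if n_comp > 1:
            warnings.warn(
                f"{subject_id}: thresholded network has {n_comp} components; "
                "efficiency treats unreachable pairs as zero inverse distance",
                stacklevel=2,
            )
    metrics = np.column_stack(
        [
            degree_centrality(adj),
            nodal_efficiency(adj),
            participation_coefficient(adj, partition),
        ]
    )
    return TopologyProfile(
        subject_id=subject_id, metrics=metrics, partition_used=np.asarray(partition), sparsity=sparsity
    )
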