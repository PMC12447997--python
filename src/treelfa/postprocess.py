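"""Post-processing of posterior samples: label-switching resolution.

Topic order is not identifiable across posterior samples, so topics
cannot be averaged positionally. All N_ps * K posterior topic vectors
are pooled and clustered: first Louvain community detection on a shared
nearest neighbor (SNN) graph, then (optionally) hierarchical merging of
near-duplicate cluster means under cosine distance. Topic weights,
alpha entries and ESS diagnostics are then routed through the same
cluster assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics.pairwise import cosine_distances
from sklearn.neighbors import NearestNeighbors

from .gibbs_sampler import GibbsResult

logger = logging.getLogger(__name__)


@dataclass
class TopicClusters:
    """Cluster assignment of pooled (sample, topic) vectors.

    ``assignment`` gives the Louvain cluster of each pooled topic vector
    (row-major over samples then topics); ``merged_assignment`` and
    ``topics_ave_h`` are filled in by the hierarchical merge.
    """

    assignment: np.ndarray  # (N_ps * K,)
    topics_ave: np.ndarray  # (n_clusters, S) Louvain cluster means
    n_samples: int
    K: int
    merged_assignment: np.ndarray | None = None
    topics_ave_h: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return self.topics_ave.shape[0]

    @property
    def final_assignment(self) -> np.ndarray:
        return self.merged_assignment if self.merged_assignment is not None else self.assignment

    @property
    def final_topics(self) -> np.ndarray:
        return self.topics_ave_h if self.topics_ave_h is not None else self.topics_ave


@dataclass
class PostResult:
    """Final aligned summaries after clustering."""

    topics_ave_h: np.ndarray  # (K', S)
    tw_ave: np.ndarray  # (D, K')
    alpha_ave: np.ndarray  # (K',)
    ess_topics: np.ndarray  # (K', S)
    ess_tw: np.ndarray  # (D, K')
    topics_all: list[np.ndarray] = field(default_factory=list)  # per cluster (n, S)
    tw_all: list[np.ndarray] = field(default_factory=list)  # per cluster (n, D)


def match_topics(
    reference: np.ndarray, inferred: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match each reference topic to a distinct inferred topic by
    maximizing total cosine similarity (Hungarian assignment).

    Returns (indices into `inferred`, cosine similarities), one entry
    per reference topic. Used to score recovery of generating topics.
    """
    from scipy.optimize import linear_sum_assignment

    ref = np.asarray(reference, dtype=float)
    inf = np.asarray(inferred, dtype=float)
    norms_r = np.linalg.norm(ref, axis=1)
    norms_i = np.linalg.norm(inf, axis=1)
    sim = (ref @ inf.T) / np.outer(np.maximum(norms_r, 1e-300), np.maximum(norms_i, 1e-300))
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]


def snn_graph(vectors: np.ndarray, k: int) -> nx.Graph:
    """Shared-nearest-neighbor graph over row vectors.

    Each point's neighborhood is its k nearest rows under cosine
    distance (the point itself included); edges join points that appear
    in each other's neighborhoods (union rule) with Jaccard overlap of
    the two neighbor sets as weight.
    """
    n = vectors.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    nn = NearestNeighbors(n_neighbors=k, metric="cosine").fit(vectors)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    sets = [set(row) | {i} for i, row in enumerate(idx)]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(sets[i] & sets[j])
            if inter:
                w = inter / len(sets[i] | sets[j])
                G.add_edge(i, j, weight=w)
    # symmetrize the union rule: j in N(i) already added; i in N(j) pairs
    for j in range(n):
        for i in idx[j]:
            i = int(i)
            if i < j and not G.has_edge(i, j):
                inter = len(sets[i] & sets[j])
                if inter:
                    G.add_edge(i, j, weight=inter / len(sets[i] | sets[j]))
    return G


def cls_louvain(result: GibbsResult, k: int, seed: int = 0) -> TopicClusters:
    """Louvain clustering of all pooled posterior topic vectors.

    k is the SNN neighbor count; values in (N_ps/2, N_ps) are a good
    default. Cluster ids are relabelled by decreasing cluster size
    (ties by smallest member index) for determinism.
    """
    if result.N_ps == 0:
        raise ValueError("GibbsResult holds no posterior samples")
    pool = np.vstack(result.Phi_samples)  # (N_ps * K, S)
    G = snn_graph(pool, k)
    communities = nx.community.louvain_communities(G, weight="weight", seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = np.empty(pool.shape[0], dtype=np.int64)
    for cid, members in enumerate(communities):
        assignment[list(members)] = cid
    topics_ave = np.vstack(
        [pool[assignment == cid].mean(axis=0) for cid in range(len(communities))]
    )
    K = result.Phi_samples[0].shape[0]
    return TopicClusters(
        assignment=assignment, topics_ave=topics_ave, n_samples=result.N_ps, K=K
    )


def cls_hier(clusters: TopicClusters, k: int) -> TopicClusters:
    """Merge the closest pair of cluster means (cosine distance) until k
    clusters remain; means are member-weighted centroids."""
    if k < 1:
        raise ValueError("k must be at least 1")
    n = clusters.n_clusters
    if k > n:
        raise ValueError(f"cannot merge {n} clusters into {k}")
    means = [clusters.topics_ave[i].copy() for i in range(n)]
    counts = [int((clusters.assignment == i).sum()) for i in range(n)]
    groups: list[list[int]] = [[i] for i in range(n)]
    while len(groups) > k:
        M = np.vstack(means)
        dist = cosine_distances(M)
        np.fill_diagonal(dist, np.inf)
        # lowest-index pair wins ties
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        i, j = int(min(i, j)), int(max(i, j))
        w_i, w_j = counts[i], counts[j]
        means[i] = (w_i * means[i] + w_j * means[j]) / (w_i + w_j)
        counts[i] = w_i + w_j
        groups[i] = groups[i] + groups[j]
        del means[j], counts[j], groups[j]
    merged = np.empty_like(clusters.assignment)
    for new_id, members in enumerate(groups):
        for old_id in members:
            merged[clusters.assignment == old_id] = new_id
    clusters.merged_assignment = merged
    clusters.topics_ave_h = np.vstack(means)
    return clusters


def estimate_topic_weights(Z_sum: np.ndarray, alpha: np.ndarray, S: int) -> np.ndarray:
    """Collapsed posterior mean of theta: (Z_sum + alpha) / (S + sum(alpha)).

    Topic weights are integrated out during sampling; this recovers an
    estimate from the assignment counts. Rows sum to 1.
    """
    alpha = np.asarray(alpha, dtype=float)
    return (Z_sum + alpha[None, :]) / (S + alpha.sum())


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS via autocovariance with Geyer initial-monotone truncation.

    A constant chain is reported as its own length (with a warning),
    since autocorrelation is undefined for it.
    """
    chain = np.asarray(chain, dtype=float)
    n = chain.shape[0]
    if n < 4:
        raise ValueError("chain must have length >= 4")
    x = chain - chain.mean()
    var0 = float(x @ x) / n
    if var0 == 0:
        warnings.warn("constant chain: ESS reported as the chain length", stacklevel=2)
        return float(n)
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    # Geyer: sums of adjacent autocorrelation pairs, kept while positive
    # and monotone nonincreasing
    tau = 1.0
    prev = np.inf
    m = 0
    while 2 * m + 2 < n:
        pair = rho[2 * m + 1] + rho[2 * m + 2]
        if pair <= 0:
            break
        pair = min(pair, prev)
        tau += 2 * pair
        prev = pair
        m += 1
    return float(n / tau)


def cls_others(
    result: GibbsResult, clusters: TopicClusters, alpha: np.ndarray | None = None
) -> PostResult:
    """Route alpha entries, topic weights and Phi chains through the
    final cluster assignment and average across posterior samples.

    Within one posterior sample, topics falling in the same cluster have
    their alpha entries and topic-weight columns summed (their usage
    accumulates) and their Phi vectors averaged. A cluster absent from a
    sample receives no contribution from that sample (logged).
    """
    if alpha is None:
        alpha = result.alpha
    alpha = np.asarray(alpha, dtype=float)
    assignment = clusters.final_assignment
    Kp = int(assignment.max()) + 1
    N_ps, K = clusters.n_samples, clusters.K
    D = result.Z_sum_samples[0].shape[0]
    S = result.Phi_samples[0].shape[1]

    tw_sum = np.zeros((D, Kp))
    alpha_sum = np.zeros(Kp)
    present_counts = np.zeros(Kp)
    phi_chains = [[] for _ in range(Kp)]
    tw_chains = [[] for _ in range(Kp)]

    for t in range(N_ps):
        theta = estimate_topic_weights(result.Z_sum_samples[t], alpha, S)
        labels = assignment[t * K : (t + 1) * K]
        for c in range(Kp):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                logger.info("cluster %d absent from posterior sample %d", c, t)
                continue
            present_counts[c] += 1
            alpha_sum[c] += alpha[members].sum()
            tw_sum[:, c] += theta[:, members].sum(axis=1)
            phi_chains[c].append(result.Phi_samples[t][members].mean(axis=0))
            tw_chains[c].append(theta[:, members].sum(axis=1))

    if np.any(present_counts == 0):
        raise ValueError("a final cluster is absent from every posterior sample")
    tw_ave = tw_sum / present_counts[None, :]
    alpha_ave = alpha_sum / present_counts
    topics_all = [np.vstack(ch) for ch in phi_chains]
    tw_all = [np.vstack(ch) for ch in tw_chains]

    ess_topics = np.full((Kp, S), np.nan)
    ess_tw = np.full((D, Kp), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in range(Kp):
            if topics_all[c].shape[0] < 4:  # too few samples for an ESS
                continue
            for s in range(S):
                ess_topics[c, s] = effective_sample_size(topics_all[c][:, s])
            for d in range(D):
                ess_tw[d, c] = effective_sample_size(tw_all[c][:, d])

    return PostResult(
        topics_ave_h=clusters.final_topics,
        tw_ave=tw_ave,
        alpha_ave=alpha_ave,
        ess_topics=ess_topics,
        ess_tw=ess_tw,
        topics_all=topics_all,
        tw_all=tw_all,
    )
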