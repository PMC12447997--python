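"""Resolve label switching: cluster posterior topic samples.

Deliberately over-fits (K=8 topics on 4-topic data), then runs the
two-step clustering: Louvain on the SNN graph of all pooled posterior
topic vectors, hierarchical merging of near-duplicate cluster means
under cosine distance, and routing of alpha/topic weights through the
final clusters. The four generating topics should reappear among the
final topics at high cosine similarity; surplus topics come out empty.
"""

import numpy as np

from treelfa import (
    SimConfig,
    cls_hier,
    cls_louvain,
    cls_others,
    gibbs_em_train,
    gibbs_train,
    match_topics,
    simulate_example,
)

data, tree, topics_true, _ = simulate_example(SimConfig(D=2000, seed=8))

em = gibbs_em_train(data, tree, K=8, alpha0=np.full(8, 0.1),
                    cycle_1=60, cycle_2=15, seed=9)
g = gibbs_train(data, tree, em.state, em.alpha,
                burn_in=500, cycle=1500, interval=40, seed=10)  # 25 samples

clusters = cls_louvain(g, k=20, seed=0)  # k in (N_ps/2, N_ps)
print(f"Louvain: {clusters.n_clusters} clusters from "
      f"{g.N_ps * 8} pooled topic vectors")
clusters = cls_hier(clusters, k=min(5, clusters.n_clusters))
post = cls_others(g, clusters)

cols, sims = match_topics(topics_true, post.topics_ave_h)
print("cosine similarity of final topics to generating topics:",
      np.round(sims, 3))
print("alpha_ave per final topic:", np.round(post.alpha_ave, 3))
print("tw_ave row sums (should be 1):",
      np.round(post.tw_ave.sum(axis=1)[:3], 6))
print("median ESS of topic entries per cluster:",
      np.round(np.median(post.ess_topics, axis=1), 1))
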