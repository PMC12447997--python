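"""Score topics with coherence (NPMI) and diversity.

Compares the generating topics against two degenerate alternatives on
the same data: shuffled topics (codes that do not co-occur) and
duplicated topics (no diversity). Good topics group codes that co-occur
in individuals (high coherence) and different topics cover different
codes (high diversity).
"""

import numpy as np

from treelfa import SimConfig, simulate_example, topic_coherence, topic_diversity

data, _, topics_true, _ = simulate_example(SimConfig(seed=13))

rng = np.random.default_rng(0)
shuffled = topics_true.copy()
for row in shuffled:
    rng.shuffle(row)
duplicated = np.tile(topics_true[:1], (4, 1))

for name, topics in [("generating", topics_true), ("shuffled", shuffled),
                     ("duplicated", duplicated)]:
    tc = topic_coherence(topics, data, top_n=4)
    td = topic_diversity(topics, N=4)
    print(f"{name:11s} coherence={tc:+.3f}  diversity={td:.2f}")
print("higher coherence = top codes co-occur; diversity 1 = disjoint top codes")
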