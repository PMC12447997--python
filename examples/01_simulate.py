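"""Simulate a diagnosis dataset from the generative process.

Draws the worked-example design — 5,000 individuals, 15 disease codes
under 5 internal tree nodes, 4 topics with disjoint active code sets at
probability 0.3, symmetric Dirichlet(0.1) — and prints the code
prevalences. Each code is active in exactly one topic, so its expected
prevalence is P(topic) * 0.3 = 0.25 * 0.3 = 0.075.
"""

import numpy as np

from treelfa import SimConfig, simulate_example

data, tree, topics_true, alpha_true = simulate_example(SimConfig(seed=42))

print(f"dataset: {data.D} individuals x {data.S} codes")
print(f"tree: {tree.n_nodes} nodes ({len(tree.terminals)} terminals)")
print("generating topics (rows = topics, entries = P(code | topic)):")
print(topics_true)
print("empirical prevalence per code (expected 0.075):")
print(np.round(data.prevalence(), 4))
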