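"""Read and validate the two input files.

Writes a small dataset and its tree to disk, reads them back through
the format validators, then shows how a malformed tree (terminal codes
not matching the data header) is reported rule by rule.
"""

import tempfile
from pathlib import Path

from treelfa import (
    SimConfig,
    estimate_memory_kb,
    read_diagnosis_matrix,
    read_tree_structure,
    simulate_example,
    tree_from_edges,
    validate_tree,
    write_diagnosis_matrix,
    write_tree_structure,
)

tmp = Path(tempfile.mkdtemp())
data, tree, _, _ = simulate_example(SimConfig(D=500, seed=1))
write_diagnosis_matrix(data, tmp / "data.tsv")
write_tree_structure(tree, tmp / "tree.tsv")

data2 = read_diagnosis_matrix(tmp / "data.tsv")
tree2 = read_tree_structure(tmp / "tree.tsv", codes=data2.codes)
print(f"validated: {data2.D} x {data2.S} binary matrix, "
      f"{len(tree2.terminals)} terminals match the header")

bad = tree_from_edges([("X1", "root"), ("X2", "root")])
for v in validate_tree(bad, data2.codes):
    print("violation:", v)

# memory needed to hold 25 posterior samples of the example run
kb = estimate_memory_kb(D=5000, K=10, N_ps=25, S=15)
print(f"posterior-sample storage estimate: {kb:,} (8*D*K*N_ps + 8*D*S*2)")
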