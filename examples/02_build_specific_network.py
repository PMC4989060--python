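"""Build the condition-specific binary network.

Per condition, every gene pair's Pearson correlation is ranked and the
top/bottom 1% become coexpression status +1/-1. The functional network
is filtered to combined scores > 500, and an edge enters the specific
network iff it survives the filter and is coexpressed in at least one
condition.
"""

from collections import Counter

import coexmark as cm

config = cm.SimulationConfig(seed=1)
normal, cancer, truth = cm.simulate_expression(config)
functional = cm.simulate_functional_network(truth, config)

status_normal = cm.coexpression_status(normal, top_fraction=0.01)
status_cancer = cm.coexpression_status(cancer, top_fraction=0.01)
print(f"evaluated {status_normal.n_pairs_evaluated} gene pairs per condition")
print(f"normal: {len(status_normal.positive_pairs)} pairs at +1, "
      f"{len(status_normal.negative_pairs)} at -1")

filtered = cm.filter_functional_network(functional, min_score=500)
print(f"functional network: {functional.n_edges} edges, "
      f"{filtered.n_edges} with score > 500")

specific = cm.build_specific_network(status_normal, status_cancer, filtered)
print(f"specific network: {specific.n_nodes} genes, {specific.n_edges} edges")

# Each edge carries both conditions' statuses; a (+1, -1) edge means the
# pair's correlation reversed sign from normal to cancer.
combos = Counter((sn, sc) for _, _, sn, sc in specific.iter_edges())
for (sn, sc), count in sorted(combos.items()):
    print(f"  status (normal={sn:+d}, cancer={sc:+d}): {count} edges")
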