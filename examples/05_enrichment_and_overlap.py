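"""Validate modules by gene-set enrichment and compare two predictions.

Fisher enrichment checks whether a module over-represents an annotated
gene set; the overlap randomization test asks whether two predicted
gene lists share more genes than uniform draws from the universe would.
"""

import coexmark as cm

config = cm.SimulationConfig(seed=1)
normal, cancer, truth = cm.simulate_expression(config)
gene_sets = cm.simulate_gene_sets(truth, n_extra_sets=10, seed=1)

modules = [cm.GeneModule(mid, frozenset(truth.genes_of(mid)))
           for mid in truth.module_ids]
table = cm.enrich_modules(modules, gene_sets)
top = table[table.top_set]
print("top enrichment per module (planted sets should win):")
print(top[["module", "gene_set", "overlap", "p_value", "adj_p_value"]]
      .to_string(index=False))

# overlap of two gene lists: e.g. predictions from two different cohorts
universe = set(truth.genes)
list_a = set(truth.rewired_genes)
list_b = set(list(truth.rewired_genes)[:4]) | {"G0100", "G0101"}
observed, emp_p, hyper_p = cm.overlap_randomization_test(
    list_a, list_b, universe, n_rand=10_000, seed=1)
print(f"\noverlap of the two lists: {observed} genes")
print(f"empirical p (10,000 randomizations): {emp_p:.2e}; "
      f"hypergeometric tail: {hyper_p:.2e}")
print("a small p means the two predictions agree far more than chance")
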