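"""Generate a synthetic two-condition study and inspect what was planted.

The generator creates paired normal/cancer expression matrices with
latent-factor gene modules, shifts some modules in the cancer condition,
and rewires a few genes so their correlations with module partners flip
sign — those rewired genes are the planted biomarkers the rest of the
pipeline should recover.
"""

import coexmark as cm

config = cm.SimulationConfig(seed=1)
normal, cancer, truth = cm.simulate_expression(config)

print(f"normal matrix:  {normal.n_genes} genes x {normal.n_samples} samples")
print(f"cancer matrix:  {cancer.n_genes} genes x {cancer.n_samples} samples")
print(f"planted modules: {truth.module_ids}")
print(f"shifted (differential) modules: {truth.de_modules}")
print(f"planted biomarker (rewired) genes: {sorted(truth.rewired_genes)}")

# The shifted modules' genes move by de_log2_shift on the log2 scale;
# the rewired genes keep their mean but invert their coexpression.
for mid, direction in truth.de_modules.items():
    members = truth.genes_of(mid)
    delta = (cancer.data.loc[members].to_numpy().mean()
             - normal.data.loc[members].to_numpy().mean())
    print(f"module {mid} ({direction}): mean log2 shift {delta:+.2f}")
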