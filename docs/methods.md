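# Methods

This note records the models, parameter choices and numerical
conventions behind `coexmark`, and what the synthetic studies used in
the test suite do and do not demonstrate.

## Coexpression status and the specific network

For a condition with expression matrix X (genes × samples, log2
scale), the Pearson correlation is computed for every unordered gene
pair — by default all C(n, 2) pairs of the matrix ("every gene pair");
an option restricts the universe to the pairs of the score-filtered
functional network, which is the practical choice for genome-scale
matrices where C(n, 2) is in the hundreds of millions. Pairs are
ranked by PCC with ties broken by lexicographic pair order, so the +1
and −1 sets have exactly ceil(f·N) members each (f = `top_fraction`,
default 0.01) and the output is reproducible; the two tails are
assigned top-first and never overlap. Genes with zero variance get
PCC 0 for all their pairs (warned). A gene present in only one
condition's matrix can carry a nonzero status only in that condition.

Normalisation defaults to quantile normalisation per condition (each
sample column mapped onto the mean empirical distribution, average
ranks for ties); `"none"` is available and is what the test suite uses
so that its oracles stay exact. Correlations are computed on the
matrix as given — the simulator emits log2-scale values and no further
transform is applied.

The functional-network filter keeps scores *strictly* greater than
`min_score` (default 500: a score of exactly 500 is removed, 501
kept). The specific network is the intersection: filtered edges whose
pair has nonzero status in at least one condition, annotated with both
statuses. It is binary — the only edge information downstream stages
use is the status pair.

## Module detection

The specific network is partitioned by Louvain modularity optimisation
(`networkx.community.louvain_communities`) on the binary graph with a
fixed seed and stable (sorted) node insertion, giving a deterministic
disjoint cover of the nodes. The partitioner is a stand-in behind a
narrow interface (`partition_network`), chosen because the downstream
analysis only needs coherent disjoint modules and treats the partition
algorithm as a black box; any community-detection routine returning a
node cover can be substituted. Modules are labelled M1, M2, … by
decreasing size (ties by smallest gene id) and modules with ≤ 4 genes
are discarded (`min_size = 5`), since a median over very few genes is
unstable.

## Module selection

The representative expression of a module in a sample is the median
over its genes (numpy convention: mean of the central pair for even
counts). Differential testing uses the two-sided Welch (unequal
variance) t-test — the closest reading of a default `t.test` in R —
on the two conditions' representative vectors, treated as unpaired
(the cohorts are disjoint). If both vectors are constant the p-value
is defined as 1 with a warning. P-values are Benjamini–Hochberg
adjusted across modules (statsmodels `fdr_bh`, the standard step-up
formula).

The fold change is computed on the linear scale by default:
log2(mean(2^rep_cancer) / mean(2^rep_normal)); a `scale="log"` variant
takes the difference of log2-scale means directly. Selection requires
adjusted p ≤ 0.01 **and** |log2FC| ≥ 2 — the absolute value matters,
since downregulated modules are as informative as upregulated ones.

The module AUC uses cancer = 1, normal = 0 labels on the concatenated
representative values and equals the normalised Mann–Whitney U
statistic with half credit for ties — identical to sweeping a
threshold down the sorted values and integrating the ROC curve with
the trapezoid rule. Direction is up for AUC > 0.5, down otherwise.

## Biomarker scoring

specificity(g) = AUC(module of g) − 0.5, in [−0.5, 0.5].
change(g) = mean over edges of g in the specific network of
|status_cancer − status_normal|, in [0, 2].

By default *all* network partners of a gene count, not only those in
its own module (`within_module_only=False`); restricting would
silently ignore cross-module edges. A gene with no network edge (or
absent from the network) has change 0 — it cannot exhibit a
coexpression change — which is also why zero-score genes are excluded
from the ranking rather than thresholded. Ranking sorts positive final
scores descending and negative ones ascending, ties broken by larger
change score then gene id.

## Enrichment and overlap validation

Enrichment is the one-sided (over-representation) Fisher exact test on
the 2×2 table of module × set membership, equal to the hypergeometric
upper tail at overlap − 1. The universe for module enrichment defaults
to the genes of the specific network, since modules are drawn from it.
Adjustment is BH across all (module, set) tests.

The overlap randomization test redraws the second list uniformly
without replacement from the universe `n_rand` times (vectorised,
seeded) and reports the add-one-corrected empirical tail
p = (1 + #{overlap ≥ observed}) / (n_rand + 1); it can never return
exactly 0 — at n_rand = 10⁴ the smallest representable value is
1/10001 ≈ 10⁻⁴. The hypergeometric upper tail is returned alongside as
the analytic reference.

## The synthetic-data generator

Module gene g in condition c is modelled on the log2 scale as

x_gs = baseline_g + shift_gc + noise_sd · (l_gc · f_cs + √(1−ρ) · e_gs)

with a per-module standard-normal factor f per sample, loading
l = √ρ so the expected within-module PCC is exactly
ρ = `within_module_correlation` (default 0.7), per-gene baselines
N(8, 0.5) mimicking log2 microarray intensities, and independent
standard-normal noise e. Differential modules have their cancer mean
shifted by ±`de_log2_shift` (default 3 log2 units, direction random
per module). Rewired genes — the planted biomarkers — have their
loading negated in the cancer condition (correlation sign flips) or,
with `rewire_mode="zero"`, zeroed with compensating noise (correlation
vanishes). Background genes are independent noise. The functional
network connects within-module pairs with probability 0.9 and scores
uniform in [601, 1000], background pairs with probability 0.005 and
scores in [50, 700], so roughly half the (few) background edges
survive the score filter. All draws flow from one seed; fixtures are
byte-identical across runs.

Default study size — 300 genes, 8 modules of 8–15 genes, 200 + 200
samples, 3 of 8 modules shifted, 2 rewired genes per shifted module —
is a desk-scale stand-in for cohort studies whose matrices have tens
of thousands of genes and hundreds to thousands of samples. The
generator does **not** model microarray platform effects, probe-level
structure, heavy-tailed intensity distributions, sample outliers or
batch effects; passing tests show the pipeline's statistics and
plumbing are correct and that planted signal of the assumed form is
recovered, not that any particular real dataset would yield particular
biomarkers.

One consequence of the tail-based status definition is worth noting:
when many equally correlated pairs compete for the top-1% slots, which
of them receive status +1 in each condition is sampling noise, so
non-rewired genes acquire small spurious change scores. The planted
biomarkers are nevertheless cleanly separated (their change scores
exceed their module's median by ≈ 1 on average), which mirrors the
method's robustness argument: module-level AUC and partner-averaged
change are both more stable than any single pair's status.

## Numerical conventions and degenerate inputs

- Tie-breaks everywhere are deterministic (lexicographic gene/pair
  order); identical inputs and seeds give byte-identical outputs.
- ceil() is used for tail sizes, so tiny universes still get one +1
  and one −1 pair.
- Empty specific network → valid empty outputs with a warning; empty
  module set, fdr_cut = 0, or no selected module propagate to empty
  tables and a successful exit.
- `top_fraction` must lie in (0, 0.5); score filters are strict
  inequalities; BH output is clipped to [0, 1].
- Representative vectors of length < 2 are an error (no variance
  estimate); modules with no gene in a matrix are an error naming the
  module.

## Problem sizes used by the test and acceptance runs

Unit and property tests run on matrices up to 300 × 200, pair
universes up to ~45k pairs, 1,000-instance AUC oracle sweeps, 500
random BH vectors, 200 random Fisher tables, randomization tests at
n_rand = 10⁵, and 50-seed null calibration of module selection; the
full pipeline examples complete in seconds on one core.
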