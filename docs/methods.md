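# Methods

This note records the modelling choices behind `microhdf`, their
defaults, and the points where the design was genuinely open.

## Input model and normalization

Profiles are samples × taxa matrices of non-negative abundances with
MetaPhlAn-style lineage identifiers. Tables may arrive as proportions
or percentages; every pipeline entry point renormalizes rows to sum to
1, so the two conventions are indistinguishable downstream. Reading is
deliberately lenient (only non-negativity, numeric completeness and id
uniqueness are enforced); a `require_fractions` flag adds the strict
row-sum ≤ 1 check, which also catches transposed tables. At training
time every labelled sample must exist in the profile and both classes
must be non-empty; at prediction time unlabelled samples are fine,
missing taxa are zero-filled and unseen taxa dropped with a warning.

## Taxonomy tree and traversal templates

The tree is built from the lineage strings themselves: each lineage is
a root-to-leaf path, shared prefixes share nodes, and single-child
chains are kept so rank depth stays aligned. Children are sorted
lexicographically by name at every node — the "left-to-right" order of
a tree drawn by an external tool is not recoverable from its inputs, so
determinism was preferred over fidelity to any particular rendering.
Profiles that mix ranks (a taxon that is an ancestor of another) are
rejected with instructions to filter to one rank.

The level template records the breadth-first order over all nodes;
internal positions are populated with descendant-leaf sums, making each
column a clade abundance and the root column the sample total. The
post-order template records the depth-first leaf order only. Both
`include_internal` flags are configurable because either reading of
"template" is defensible; the defaults (level = all nodes, post-order =
leaves) follow the natural reading of each traversal. A user-supplied
Newick tree overrides the lineage-built one: its leaves are matched to
taxa by terminal rank token, unmatched leaves pruned, unplaced taxa
appended under the root with a warning.

## RF-CUS: cluster-guided undersampling

Majority-class samples are clustered on Bray–Curtis dissimilarity with
affinity propagation (similarity = −D). AP is swept over damping
{0.5, 0.7, 0.9} × preference {median, min}; the first convergent run
with a cluster count in [2, k] (k = 15 by default) wins, otherwise
K-means with k = min(15, n) on the raw features is the fallback. The
undersampling ratio u is read as the fraction of the majority class
each balanced subset retains: m = round(u·n_majority) majority samples
drawn without replacement, allocated across clusters proportionally to
size by largest-remainder rounding (every non-empty cluster contributes
at least one sample when m allows), paired with m minority bootstrap
draws. N = 10 subsets by default (the subset count is a free parameter;
10 balances vote stability against cost), each training one 100-tree
random forest; the unit's prediction is the unweighted mean of the N
forests' class probabilities. Subsets are paired one-to-one
("pairwise"), not cross-producted.

## ERT unit: ranking and wrapper selection

Features are ranked by an LDA effect score: a two-group Kruskal–Wallis
screen at α = 0.05 (vectorized with tie correction; verified against
scipy per-feature), then log10(1 + |Δ|) where Δ is the class-mean
difference after rescaling each sample to a per-million total. The
subclass/bootstrap machinery of full LDA-effect-size analysis is
omitted — the score is only a ranking statistic here. Sequential
forward selection seeds with the top-ranked feature and greedily keeps
a candidate iff it improves internal 3-fold balanced accuracy of a
small ERT scorer by more than 1e-4, stopping after 10 consecutive
misses or `sfs_max_candidates` (50) scanned features; the cap bounds
wrapper cost on wide matrices. The final ERT ensemble (100 trees)
restricts split candidates to the selected subset. Selection reruns at
every cascade layer so augmented dimensions can be chosen; a flag can
freeze it to the raw features.

## Cascade architecture

Two channels: raw abundance (mode O) and phylogeny views (default
L+P concatenated; raw O already lives in the other channel). Each
layer holds 2 RF-CUS + 2 ERT units in fixed order; its output is the
8-value concatenation of their class vectors; the next layer's input
re-appends the *original* channel features, so the augmented width is
always raw width + 8. Augmentation class vectors are produced
out-of-fold (3-fold stratified internal split): in-sample augmentation
lets later layers read the labels through the probabilities and
overfits badly. When a class is too small for the internal split the
layer degrades to in-sample augmentation with a warning rather than
refusing tiny data sets.

Depth is chosen by early stopping on the out-of-fold AUC of each
layer's mean class vector (patience 1, max 5 layers, best depth kept,
channels stop independently); `min_layers` can pin a floor. The final
layer fits one plain random forest and one ERT ensemble on the
concatenated last-layer class vectors of the active channels (class
vectors only by default; `final_append_raw` appends the raw features
for the alternative reading) and averages their two distributions.
Probability threshold is 0.5 with ties resolved to the control class,
biasing against false positives.

All randomness flows from a single seed through named, independent
spawned streams (per channel, per unit, per fold), so fits are
bit-reproducible.

## Feature importance

"Information gain" is implemented as Gini impurity decrease, the
measure the underlying forests actually optimize. A layer's raw gain
for a feature sums the weighted impurity decrease over every tree of
every forest in the layer (each RF-CUS sub-forest counts as a forest).
Gains landing on augmented class-vector dimensions accumulate in a
reserved `__augmented__` bucket and are excluded from the
normalization, which runs over original features only; a taxon observed
through several views (raw, level, post-order) is merged under its
single lineage id, and internal template positions report under the
internal node's name. A degenerate all-zero total yields a uniform
distribution with a warning.

## Evaluation protocol

Stratified 5-fold cross-validation repeated 10 times by default; every
fold refits the entire pipeline — clustering, ranking, wrapper
selection — inside the training fold. Metrics: AUC (tie-corrected rank
statistic), AUPR (precision-recall step integral), accuracy, recall and
F1 for the case class at threshold 0.5. The imbalance ratio is
majority/minority count rounded half-up to two decimals. Cross-study
validation fits once on the training cohort and evaluates once on the
test cohort with id-based taxon alignment; batch-effect correction
between cohorts is expected upstream (e.g. MMUPHin) and is not
reimplemented.

## Synthetic data generator

The generator emulates species-level gut profiles: per-taxon base
log-means ~ Normal(0, 2) (heavy-tailed abundance spectrum), per-sample
log-normal variation with dispersion σ = 1, per-entry dropout at
zero-inflation π = 0.3, rows renormalized to 1. Case samples multiply
the `n_differential` planted taxa by `effect_size` before
renormalization. Because a real fold-change shifts prevalence along
with abundance (detection scales with abundance), the dropout
probability of affected entries is divided by the fold-change (capped
at 0.95); without this coupling a nominally strong effect is erased
from a π-fraction of case samples and no classifier can reach the
performance a strong effect should support. Differential taxa are
planted on sibling leaves by default so the phylogeny views carry
signal; a flag scatters them. Lineages follow a balanced hierarchy with
branching factor 3, so consecutive species indices are phylogenetic
siblings.

The generator does **not** model cohort batch effects, sequencing-depth
variation, taxon-taxon interaction networks, or strain structure.
Passing tests on these data show the pipeline recovers planted
compositional signal under dropout and imbalance; they do not certify
performance on real cohorts, where effect structure is messier and
confounding is real.

## Test and acceptance problem sizes

Stochastic end-to-end checks run a scaled-down configuration — 15
trees per forest, 2 balanced subsets, wrapper scan capped at 8
candidates with an 8-tree scorer, 1 cascade layer, 2 out-of-fold
splits — on cohorts of 40–125 samples and 50–200 taxa. These sizes
keep dozens of full refits affordable while preserving every
architectural property being tested; headline numbers (e.g.
strong-signal CV AUC ≥ 0.95, chance-level AUC on permuted labels)
hold at this scale. The ablation check uses heavy dropout (π = 0.7)
with a clade-wide 2.5-fold effect, the regime in which clade-aggregated
features are genuinely informative beyond the raw leaves.

## Known limitations

Binary phenotypes only. The AP parameter sweep is a pragmatic
stand-in for an unspecified tuning procedure. The LDA effect score is
one-dimensional per feature, not the full multi-feature discriminant.
Greedy forward selection deliberately drops redundant informative
features (a locally optimal subset, not a complete biomarker list) —
use the FIV ranking, not the selected subset, for biomarker reading.
Printed cohort imbalance ratios reproduce under half-up rounding for
the ratios quoted in the test suite; cohorts whose published values
were truncated differently are not asserted.
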