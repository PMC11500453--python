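# microhdf

Deep-forest prediction of binary host phenotypes (disease vs. healthy)
from metagenomic relative-abundance profiles.

Gut-microbiome case/control cohorts are small, high-dimensional and
usually class-imbalanced: a few dozen cases against hundreds of
controls, described by hundreds of species-level relative abundances.
`microhdf` implements MicroHDF, a cascade ("deep forest") classifier
built for exactly this regime. It is aimed at researchers who have a
MetaPhlAn-style taxon-by-sample table and want calibrated predictions
plus a ranked list of candidate biomarker taxa, without GPUs or
large-cohort pretraining.

## The model

**Phylogeny-derived features.** The taxonomy spanning the profile's
lineage strings (`k__...|p__...|...|s__...`) is assembled into a
least-pruned tree. Two traversal templates linearize it: the *level*
template visits every node breadth-first (internal positions carry
clade-summed abundance), and the *post-order* template lists the leaves
depth-first so related taxa sit in adjacent columns. Populating the
templates per sample yields feature matrices in which evolutionary
neighbourhood structure is explicit.

**Two-channel cascade.** One channel consumes the raw abundance matrix,
the other the phylogeny views. Each cascade layer holds four forest
units — two RF-CUS and two ERT — and maps its input `h_l` to the
concatenation of their class-probability vectors, re-appending the
original features:

    h_{l+1} = f_{l+1}(h_l) ‖ x

so a layer over width-`D` input emits width `D + 8` (4 units × 2
classes). Augmentation vectors are produced out-of-fold to avoid
self-fitting. Layers grow until the internal AUC stops improving; the
final layer (a random forest plus an ERT ensemble) averages its two
class distributions over the concatenated channel outputs.

**RF-CUS** (cluster-based undersampling) rebalances skewed training
sets: majority samples are clustered by affinity propagation on
Bray–Curtis dissimilarity (K-means fallback on non-convergence), N
balanced subsets draw a fraction u = 0.4 of the majority class
stratified across clusters plus an equal-size minority bootstrap, and
one 100-tree random forest per subset votes into the unit's prediction.

**ERTs** (extremely randomized trees with wrapper selection) handle
dimensionality: features are ranked by a Kruskal–Wallis-screened,
log-scaled LDA effect score, a sequential-forward-selection wrapper
keeps the locally optimal subset, and the ERT ensemble restricts its
splits to it.

**Feature importance (FIV).** The gain of feature *d* in layer *l* is
the Gini impurity decrease summed over all T trees of all N forests,
`F_l^d = Σ_n Σ_t gain_{n,t}^{d,l}`; the normalized importance is
`F_d = Σ_l F_l^d / Σ_d Σ_l F_l^d` over the original features, with a
taxon's raw, level and post-order columns merged under one id.

## Worked example

Simulate an imbalanced cohort (120 taxa, 30 cases vs 90 controls, 8
differential sibling taxa at 6-fold change), train, and inspect:

```bash
microhdf simulate --out-dir cohort --n-taxa 120 --n-case 30 --n-control 90 \
    --n-differential 8 --effect-size 6 --seed 7
microhdf train cohort/abundance.tsv cohort/labels.tsv \
    --tree cohort/tree.nwk --config fast.yaml --seed 7 --out-dir model
microhdf predict model cohort/abundance.tsv --out predictions.tsv
microhdf explain model --out fiv.tsv
microhdf evaluate cohort/abundance.tsv cohort/labels.tsv \
    --tree cohort/tree.nwk --config fast.yaml --seed 7 -k 5 --repeats 2 --out eval.tsv
```

(`fast.yaml` here shrinks the forests for a quick demo:
`n_trees: 40`, `n_subsets: 4`, `sfs_max_candidates: 20`, `max_layers: 2`.)

The evaluate command prints

```
mean AUC 0.9718 ± 0.0449 over 10 folds
```

— the 5-fold × 2-repeat cross-validated AUC, the primary performance
number. `fiv.tsv` begins

```
feature                                                    FIV      rank
k__K000|p__P000|c__C001|o__O003|f__F011|g__G034|s__Sp103   0.0936   1
k__K000|p__P000|c__C001|o__O003|f__F011|g__G033|s__Sp100   0.0571   2
k__K000|p__P000|c__C001|o__O003|f__F010|g__G032|s__Sp097   0.0565   3
```

The top-ranked features are exactly the planted differential taxa
(Sp097–Sp104) and their shared family node `f__F011` — the importance
ranking recovers both the taxa and the clade that carries the signal.

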