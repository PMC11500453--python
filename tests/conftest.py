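import numpy as np
import pytest

from microhdf.config import CascadeConfig, ForestConfig
from microhdf.io_profiles import AbundanceProfile, SampleLabels
from microhdf.tree import TaxonomyTree

#: toy tree used throughout: ((A,B)C,(D)E)R
TOY_NEWICK = "((A,B)C,(D)E)R;"


def fast_forest(seed: int = 0, **kw) -> ForestConfig:
    """Small forests so a full cascade fit stays in the seconds range."""
    defaults = dict(
        n_trees=15,
        n_subsets=2,
        sfs_trees=8,
        sfs_folds=2,
        sfs_max_candidates=8,
        seed=seed,
    )
    defaults.update(kw)
    return ForestConfig(**defaults)


def fast_cascade(seed: int = 0, **kw) -> CascadeConfig:
    forest_kw = {
        k: kw.pop(k)
        for k in list(kw)
        if k in ForestConfig().__dict__ and k != "seed"
    }
    defaults = dict(forest=fast_forest(seed, **forest_kw), max_layers=1, oof_folds=2)
    defaults.update(kw)
    return CascadeConfig(**defaults)


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    return TaxonomyTree.from_newick(TOY_NEWICK)


@pytest.fixture
def toy_profile() -> AbundanceProfile:
    """Leaves A, B, D of the toy tree with abundances 0.5, 0.3, 0.2."""
    return AbundanceProfile(["s1"], ["A", "B", "D"], np.array([[0.5, 0.3, 0.2]]))


@pytest.fixture
def lineage_profile() -> AbundanceProfile:
    """3 species, two sharing a genus."""
    taxa = [
        "k__Bacteria|p__Firmicutes|g__Roseburia|s__Roseburia_hominis",
        "k__Bacteria|p__Firmicutes|g__Roseburia|s__Roseburia_intestinalis",
        "k__Bacteria|p__Bacteroidetes|g__Bacteroides|s__Bacteroides_fragilis",
    ]
    values = np.array([[0.2, 0.3, 0.5], [0.6, 0.1, 0.3]])
    return AbundanceProfile(["s1", "s2"], taxa, values)


@pytest.fixture
def separable_data():
    """Linearly separable two-class data: feature 0 decides the class."""
    rng = np.random.default_rng(7)
    n = 40
    y = np.array([0] * 25 + [1] * 15)
    X = rng.uniform(0, 0.1, size=(n, 5))
    X[y == 1, 0] += 1.0
    return X, y


def labels_of(profile: AbundanceProfile, y) -> SampleLabels:
    return SampleLabels(dict(zip(profile.sample_ids, [int(v) for v in y])))
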