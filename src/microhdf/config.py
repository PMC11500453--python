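"""Configuration dataclasses for forest units and the cascade."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np

__all__ = ["ForestConfig", "CascadeConfig", "seed_streams"]


@dataclass
class ForestConfig:
    """Hyperparameters shared by the RF-CUS and ERT forest units.

    n_trees
        Decision trees per forest (T). 100 follows the published setting.
    n_subsets
        Balanced majority/minority subset pairs per RF-CUS unit (N).
    undersampling_ratio
        Fraction u of the majority class drawn (without replacement) into
        each balanced subset; the published optimum is 0.4.
    ap_target_clusters
        Upper bound k on the affinity-propagation cluster count considered
        acceptable (typically 15); beyond it the K-means fallback engages.
    """

    n_trees: int = 100
    n_subsets: int = 10
    undersampling_ratio: float = 0.4
    ap_target_clusters: int = 15
    ap_max_iter: int = 200
    sfs_folds: int = 3
    sfs_patience: int = 10
    sfs_tol: float = 1e-4
    sfs_trees: int = 25
    sfs_max_candidates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if not 0 < self.undersampling_ratio <= 1:
            raise ValueError("undersampling_ratio must be in (0, 1]")
        if self.ap_target_clusters < 1:
            raise ValueError("ap_target_clusters must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CascadeConfig:
    """Architecture-level settings of the two-channel cascade.

    Each cascade layer holds `n_rf_cus` class-rebalancing units and
    `n_ert` dimensionality-reducing units (2 + 2 in the published
    architecture).  Layers are grown until the internal out-of-fold AUC
    stops improving (`patience` layers of grace) or `max_layers` is hit.
    `phylo_mode` selects the views fed to the phylogeny channel.
    """

    forest: ForestConfig = field(default_factory=ForestConfig)
    n_rf_cus: int = 2
    n_ert: int = 2
    max_layers: int = 5
    min_layers: int = 1
    patience: int = 1
    oof_folds: int = 3
    use_abundance_channel: bool = True
    use_phylo_channel: bool = True
    abundance_mode: str = "O"
    phylo_mode: str = "L+P"
    final_append_raw: bool = False
    sfs_per_layer: bool = True
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if not 1 <= self.min_layers <= self.max_layers:
            raise ValueError("min_layers must lie in [1, max_layers]")
        if self.oof_folds < 2:
            raise ValueError("oof_folds must be >= 2")
        if not (self.use_abundance_channel or self.use_phylo_channel):
            raise ValueError("at least one channel must be enabled")

    @property
    def n_units(self) -> int:
        return self.n_rf_cus + self.n_ert

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeConfig":
        d = dict(d)
        forest = d.pop("forest", {})
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        fknown = {f.name for f in fields(ForestConfig)}
        funknown = set(forest) - fknown
        if funknown:
            raise ValueError(f"unknown forest config keys: {sorted(funknown)}")
        return cls(forest=ForestConfig(**forest), **d)


def seed_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent named RNG streams derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sklearn_seed(rng: np.random.Generator) -> int:
    """Draw a seed acceptable to scikit-learn estimators."""
    return int(rng.integers(0, 2**31 - 1))
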