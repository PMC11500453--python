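"""Synthetic compositional microbiome profiles with planted signal.

The generator emulates the gross statistical features of species-level
gut-metagenome profiles: heavy-tailed mean abundances (log-normal base
means), per-entry dropout (zero inflation), compositional closure
(rows renormalized to 1), configurable class imbalance, and a taxonomy
whose lineage strings yield a branching tree.  Differential taxa are
multiplied by a fold-change in case samples *before* renormalization and
are planted on sibling leaves by default so the phylogeny-derived views
carry signal; a flag scatters them instead.

It deliberately does not model real-data features such as cohort batch
effects, sequencing depth variation, taxon-taxon correlation beyond the
shared composition, or strain-level structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CascadeConfig, ForestConfig
from .evaluation import repeated_cv
from .io_profiles import AbundanceProfile, SampleLabels
from .phylo_features import build_taxonomy_tree
from .tree import TaxonomyTree

__all__ = ["SyntheticSpec", "simulate", "sweep"]

_RANK_PREFIXES = ("k", "p", "c", "o", "f", "g")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    effect_size is a multiplicative fold-change applied to the
    differential taxa of case samples; zero_inflation is the per-entry
    dropout probability; dispersion is the log-normal sigma of sample-
    to-sample variation around each taxon's base abundance.
    """

    n_taxa: int = 200
    n_case: int = 50
    n_control: int = 50
    n_differential: int = 10
    effect_size: float = 5.0
    zero_inflation: float = 0.3
    dispersion: float = 1.0
    tree_branching: int = 3
    clustered_differential: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_taxa, n_case and n_control must be >= 1")
        if not 0 <= self.n_differential <= self.n_taxa:
            raise ValueError("n_differential must lie in [0, n_taxa]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.tree_branching < 1:
            raise ValueError("tree_branching must be >= 1")

    @property
    def imbalance_ratio(self) -> float:
        hi, lo = max(self.n_case, self.n_control), min(self.n_case, self.n_control)
        return hi / lo


def _lineages(spec: SyntheticSpec) -> list[str]:
    """Rank-prefixed lineage strings over a balanced-ish hierarchy.

    Taxon i's ancestor at each higher rank is i // b^depth, so blocks of
    `tree_branching` consecutive species share a genus, b^2 share a
    family, and so on — consecutive indices are phylogenetic siblings.
    """
    b = spec.tree_branching
    width = len(str(spec.n_taxa))
    out = []
    for i in range(spec.n_taxa):
        tokens = []
        names = []
        for depth in range(len(_RANK_PREFIXES) - 1, -1, -1):
            group_id = i // (b ** (depth + 1))
            names.append((_RANK_PREFIXES[len(_RANK_PREFIXES) - 1 - depth], group_id))
        for rank, gid in names:
            tokens.append(f"{rank}__{rank.upper()}{gid:0{width}d}")
        tokens.append(f"s__Sp{i:0{width}d}")
        out.append("|".join(tokens))
    return out


def simulate(
    spec: SyntheticSpec,
) -> tuple[AbundanceProfile, SampleLabels, TaxonomyTree, list[str]]:
    """Generate one synthetic cohort; fully deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    taxa = _lineages(spec)
    n = spec.n_control + spec.n_case
    y = np.array([0] * spec.n_control + [1] * spec.n_case)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    mu = rng.normal(0.0, 2.0, size=spec.n_taxa)  # heavy-tailed base means
    if spec.clustered_differential:
        # a run of consecutive leaves = sibling clade on the generated tree
        start = int(rng.integers(0, spec.n_taxa - spec.n_differential + 1))
        diff_idx = np.arange(start, start + spec.n_differential)
    else:
        diff_idx = rng.choice(spec.n_taxa, size=spec.n_differential, replace=False)
    diff_idx = np.sort(diff_idx)

    z = rng.normal(0.0, 1.0, size=(n, spec.n_taxa))
    values = np.exp(mu[None, :] + spec.dispersion * z)
    # detection scales with abundance: a fold-change on a differential taxon
    # shifts its prevalence along with its abundance, so the dropout
    # probability of affected entries is divided by the fold-change
    # (capped to stay a probability)
    dropout = np.full((n, spec.n_taxa), spec.zero_inflation)
    if spec.n_differential:
        values[np.ix_(y == 1, diff_idx)] *= spec.effect_size
        affected = np.clip(spec.zero_inflation / spec.effect_size, 0.0, 0.95)
        dropout[np.ix_(y == 1, diff_idx)] = affected
    keep = rng.random((n, spec.n_taxa)) >= dropout
    values *= keep
    # guard the (vanishingly rare) all-zero row
    dead = values.sum(axis=1) == 0
    if dead.any():
        for i in np.nonzero(dead)[0]:
            j = int(rng.integers(0, spec.n_taxa))
            values[i, j] = np.exp(mu[j])
    values /= values.sum(axis=1, keepdims=True)

    profile = AbundanceProfile(sample_ids, taxa, values)
    labels = SampleLabels(
        dict(zip(sample_ids, y.tolist())), {0: "control", 1: "case"}
    )
    tree = build_taxonomy_tree(profile)
    return profile, labels, tree, [taxa[i] for i in diff_idx]


def sweep(
    imbalance_ratios: list[float],
    undersampling_ratios: list[float],
    base_spec: SyntheticSpec,
    cfg: CascadeConfig | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean CV AUC per (IR, undersampling ratio) grid cell.

    The minority-class size is held at base_spec's smaller class; the
    majority class is scaled to hit each target IR.
    """
    cfg = cfg if cfg is not None else CascadeConfig()
    n_min = min(base_spec.n_case, base_spec.n_control)
    rows = []
    for ir in imbalance_ratios:
        spec = SyntheticSpec(
            **{
                **base_spec.__dict__,
                "n_case": n_min,
                "n_control": int(round(ir * n_min)),
                "seed": base_spec.seed + int(round(ir * 100)) % 1000,
            }
        )
        profile, labels, tree, _ = simulate(spec)
        for u in undersampling_ratios:
            forest = ForestConfig(**{**cfg.forest.to_dict(), "undersampling_ratio": u})
            cell_cfg = CascadeConfig(**{**_cfg_dict(cfg), "forest": forest})
            report = repeated_cv(
                profile, labels, tree=tree, cfg=cell_cfg, k=k, repeats=repeats, seed=seed
            )
            rows.append(
                {"imbalance_ratio": ir, "undersampling_ratio": u, "auc": report.mean("auc")}
            )
    return pd.DataFrame(rows)


def _cfg_dict(cfg: CascadeConfig) -> dict:
    d = cfg.to_dict()
    d.pop("forest")
    return d
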