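"""Two-channel deep-forest cascade.

Each cascade layer holds two RF-CUS and two ERT units.  A layer maps its
input h_l to the concatenation of the units' two-class probability
vectors (8 values for the 2+2 architecture); the next layer's input is
that class vector concatenated with the *original* feature vector x, so
the augmented width is always ``n_units * 2 + width(x)``.

The class vectors used for augmentation are produced out-of-fold (an
internal stratified split), so no unit ever scores a sample it was
fitted on — naive in-sample augmentation overfits the stack.  One
channel consumes the raw abundance matrix, the other the
phylogeny-derived views; the final layer (a plain random forest plus an
ERT ensemble) consumes the concatenated last-layer class vectors of both
channels and averages its two units' distributions into the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import CascadeConfig, sklearn_seed
from .forest_units import (
    ERTUnit,
    RFCUSUnit,
    _align_proba,
    fit_ert_unit,
    fit_rf_cus,
)
from .io_profiles import AbundanceProfile, SampleLabels, to_relative
from .phylo_features import (
    assemble_views,
    build_taxonomy_tree,
    level_template,
    populate_template,
    postorder_template,
    reconcile_tree,
)
from .tree import TaxonomyTree

__all__ = [
    "LayerState",
    "ChannelState",
    "CascadeModel",
    "fit_layer",
    "fit_channel",
    "fit_microhdf",
    "predict_proba",
    "predict",
]

AUGMENTED = "__augmented__"


def _fit_units(
    H: np.ndarray, y: np.ndarray, cfg: CascadeConfig, rng: np.random.Generator
) -> list[RFCUSUnit | ERTUnit]:
    units: list[RFCUSUnit | ERTUnit] = []
    for _ in range(cfg.n_rf_cus):
        units.append(fit_rf_cus(H, y, cfg.forest, rng))
    for _ in range(cfg.n_ert):
        units.append(fit_ert_unit(H, y, cfg.forest, rng))
    return units


def _units_proba(units, H: np.ndarray) -> np.ndarray:
    """Concatenated class vectors in fixed unit order (RF-CUS first)."""
    return np.hstack([u.predict_proba(H) for u in units])


@dataclass
class LayerState:
    """One fitted cascade layer: 2 RF-CUS + 2 ERT units plus OOF outputs."""

    units: list  # fitted on the full layer input, used at predict time
    oof: np.ndarray  # out-of-fold class vectors, shape (n, n_units*2)
    input_width: int
    column_features: list[str]  # original feature id per input column

    @property
    def augmented_width(self) -> int:
        return self.oof.shape[1]


def fit_layer(
    H: np.ndarray,
    y: np.ndarray,
    cfg: CascadeConfig,
    rng: np.random.Generator,
    column_features: list[str] | None = None,
) -> LayerState:
    """Fit one layer and produce out-of-fold class vectors for augmentation."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit a layer")
    if H.shape[0] < 2:
        raise ValueError("too few samples to fit a layer")
    folds = min(cfg.oof_folds, int(np.min(np.bincount(y))))
    n_out = (cfg.n_rf_cus + cfg.n_ert) * 2
    units = _fit_units(H, y, cfg, rng)
    if folds < 2:
        # too few per-class samples for an internal split; degrade to
        # in-sample augmentation rather than refusing tiny datasets
        warnings.warn(
            "fewer samples per class than internal folds; "
            "augmentation vectors are in-sample",
            stacklevel=2,
        )
        oof = _units_proba(units, H)
    else:
        oof = np.zeros((H.shape[0], n_out))
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=sklearn_seed(rng)
        )
        for tr, te in skf.split(H, y):
            fold_units = _fit_units(H[tr], y[tr], cfg, rng)
            oof[te] = _units_proba(fold_units, H[te])
    cols = (
        list(column_features)
        if column_features is not None
        else [f"f{i:06d}" for i in range(H.shape[1])]
    )
    return LayerState(units, oof, H.shape[1], cols)


@dataclass
class ChannelState:
    layers: list[LayerState]
    trace: list[float]  # internal OOF AUC per depth
    raw_features: list[str]

    @property
    def best_auc(self) -> float:
        return max(self.trace)

    def last_oof(self) -> np.ndarray:
        return self.layers[-1].oof

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Class vectors of the last layer for new samples."""
        h = X
        probs = None
        for layer in self.layers:
            probs = _units_proba(layer.units, h)
            h = np.hstack([probs, X])
        return probs


def _layer_auc(y: np.ndarray, oof: np.ndarray) -> float:
    """Internal validation AUC of a layer: mean case-probability over units."""
    case = oof[:, 1::2].mean(axis=1)
    return float(roc_auc_score(y, case))


def fit_channel(
    X0: np.ndarray,
    y: np.ndarray,
    cfg: CascadeConfig,
    rng: np.random.Generator,
    column_features: list[str] | None = None,
) -> ChannelState:
    """Grow cascade layers with early stopping on internal OOF AUC.

    Layer l+1 consumes [class vectors of layer l ‖ original X0].  Growth
    stops when the OOF AUC fails to improve for `patience` consecutive
    layers or `max_layers` is reached; the best-scoring depth is kept.
    """
    if X0.shape[0] < 2:
        raise ValueError("need at least two samples")
    feats = (
        list(column_features)
        if column_features is not None
        else [f"f{i:06d}" for i in range(X0.shape[1])]
    )
    layers: list[LayerState] = []
    trace: list[float] = []
    h = X0
    cols = feats
    best = -np.inf
    misses = 0
    for depth in range(1, cfg.max_layers + 1):
        layer = fit_layer(h, y, cfg, rng, column_features=cols)
        layers.append(layer)
        auc = _layer_auc(y, layer.oof)
        trace.append(auc)
        if auc > best:
            best = auc
            misses = 0
        elif depth >= cfg.min_layers:
            misses += 1
            if misses >= cfg.patience:
                break
        h = np.hstack([layer.oof, X0])
        cols = [AUGMENTED] * layer.oof.shape[1] + feats
    best_depth = max(int(np.argmax(trace)) + 1, min(cfg.min_layers, len(layers)))
    return ChannelState(layers[:best_depth], trace, feats)


@dataclass
class CascadeModel:
    """Fitted two-channel cascade with its final averaging layer."""

    config: CascadeConfig
    channel_abundance: ChannelState | None
    channel_phylo: ChannelState | None
    final_rf: RandomForestClassifier
    final_ert: ExtraTreesClassifier
    taxon_ids: list[str]
    tree: TaxonomyTree | None
    class_names: dict[int, str]
    phylo_builder: dict | None = None
    validation_trace: dict = field(default_factory=dict)
    final_column_features: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------
    def _channel_inputs(self, profile: AbundanceProfile) -> dict[str, np.ndarray]:
        aligned = profile.align_taxa(self.taxon_ids, warn=True)
        aligned = _safe_relative(aligned)
        out: dict[str, np.ndarray] = {}
        if self.channel_abundance is not None:
            X, _, _ = self._abundance_view(aligned)
            out["abundance"] = X
        if self.channel_phylo is not None:
            X, _, _ = self._phylo_view(aligned)
            out["phylo"] = X
        return out

    def _abundance_view(self, profile: AbundanceProfile):
        if self.config.abundance_mode == "O":
            return assemble_views(profile, None, None, "O")
        return populate_and_assemble(
            profile, self.tree, self.phylo_builder, self.config.abundance_mode
        )

    def _phylo_view(self, profile: AbundanceProfile):
        return populate_and_assemble(
            profile, self.tree, self.phylo_builder, self.config.phylo_mode
        )

    def _final_input(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        blocks = []
        if self.channel_abundance is not None:
            blocks.append(self.channel_abundance.transform(inputs["abundance"]))
        if self.channel_phylo is not None:
            blocks.append(self.channel_phylo.transform(inputs["phylo"]))
        F = np.hstack(blocks)
        if self.config.final_append_raw:
            F = np.hstack([F] + [inputs[k] for k in inputs])
        return F

    def predict_proba(self, profile: AbundanceProfile) -> np.ndarray:
        F = self._final_input(self._channel_inputs(profile))
        p = (_align_proba(self.final_rf, F) + _align_proba(self.final_ert, F)) / 2
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, profile: AbundanceProfile) -> list[str]:
        p = self.predict_proba(profile)
        # ties at the threshold resolve to control (class 0)
        hard = (p[:, 1] > self.config.threshold).astype(int)
        return [self.class_names[int(v)] for v in hard]

    def iter_forest_groups(self):
        """Yield (layer_key, forests, column_features) over all cascade layers.

        `forests` is a list of (sklearn forest, selected column indices or
        None); importances of selected-column forests map through
        `selected` back to layer-input columns.  The final layer's inputs
        are all class-vector (augmented) dimensions.
        """
        for name, chan in (
            ("abundance", self.channel_abundance),
            ("phylo", self.channel_phylo),
        ):
            if chan is None:
                continue
            for depth, layer in enumerate(chan.layers, start=1):
                forests = []
                for unit in layer.units:
                    if isinstance(unit, RFCUSUnit):
                        forests.extend((rf, None) for rf in unit.forests)
                    else:
                        forests.append((unit.forest, unit.selected))
                yield f"{name}:layer{depth}", forests, layer.column_features
        yield "final", [(self.final_rf, None), (self.final_ert, None)], list(
            self.final_column_features
        )


def _safe_relative(profile: AbundanceProfile) -> AbundanceProfile:
    """Renormalize rows, leaving all-zero rows (valid at predict time) as zeros."""
    sums = profile.values.sum(axis=1)
    if np.all(sums > 0):
        return to_relative(profile)
    safe = np.where(sums > 0, sums, 1.0)
    return AbundanceProfile(
        list(profile.sample_ids), list(profile.taxon_ids), profile.values / safe[:, None]
    )


def fit_microhdf(
    profile: AbundanceProfile,
    labels: SampleLabels,
    tree: TaxonomyTree | None = None,
    cfg: CascadeConfig | None = None,
) -> CascadeModel:
    """Fit the full two-channel cascade on a labelled abundance profile."""
    cfg = cfg if cfg is not None else CascadeConfig()
    labels.check_against(profile, training=True)
    sample_ids = [s for s in profile.sample_ids if s in labels.labels]
    prof = to_relative(profile.subset_samples(sample_ids))
    y = labels.vector(sample_ids)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("abundance", "phylo", "final"),
            np.random.SeedSequence(cfg.forest.seed).spawn(3),
        )
    }

    needs_tree = cfg.use_phylo_channel or any(
        v in cfg.abundance_mode.split("+") for v in ("L", "P")
    )
    phylo_builder = None
    if needs_tree:
        if tree is None:
            tree = build_taxonomy_tree(prof)
        else:
            tree = reconcile_tree(tree, prof)
        phylo_builder = {
            "level": level_template(tree),
            "post": postorder_template(tree),
        }

    chan_phylo = None
    Xp = feats_p = None
    if cfg.use_phylo_channel:
        Xp, _, feats_p = populate_and_assemble(prof, tree, phylo_builder, cfg.phylo_mode)
        chan_phylo = fit_channel(Xp, y, cfg, rngs["phylo"], column_features=feats_p)

    chan_ab = None
    Xa = feats_a = None
    if cfg.use_abundance_channel:
        if cfg.abundance_mode == "O":
            Xa, _, feats_a = assemble_views(prof, None, None, "O")
        else:
            Xa, _, feats_a = populate_and_assemble(
                prof, tree, phylo_builder, cfg.abundance_mode
            )
        chan_ab = fit_channel(Xa, y, cfg, rngs["abundance"], column_features=feats_a)

    blocks = []
    if chan_ab is not None:
        blocks.append(chan_ab.last_oof())
    if chan_phylo is not None:
        blocks.append(chan_phylo.last_oof())
    F = np.hstack(blocks)
    final_cols = [AUGMENTED] * F.shape[1]
    if cfg.final_append_raw:
        raws = []
        if chan_ab is not None:
            raws.append(Xa)
            final_cols.extend(feats_a)
        if chan_phylo is not None:
            raws.append(Xp)
            final_cols.extend(feats_p)
        F = np.hstack([F] + raws)
    rng_f = rngs["final"]
    final_rf = RandomForestClassifier(
        n_estimators=cfg.forest.n_trees, random_state=sklearn_seed(rng_f), n_jobs=1
    ).fit(F, y)
    final_ert = ExtraTreesClassifier(
        n_estimators=cfg.forest.n_trees, random_state=sklearn_seed(rng_f), n_jobs=1
    ).fit(F, y)

    trace = {
        "abundance": chan_ab.trace if chan_ab else None,
        "phylo": chan_phylo.trace if chan_phylo else None,
    }
    return CascadeModel(
        config=cfg,
        channel_abundance=chan_ab,
        channel_phylo=chan_phylo,
        final_rf=final_rf,
        final_ert=final_ert,
        taxon_ids=list(prof.taxon_ids),
        tree=tree,
        class_names=dict(labels.class_names),
        phylo_builder=phylo_builder,
        validation_trace=trace,
        final_column_features=final_cols,
    )


def populate_and_assemble(profile, tree, builder, mode):
    mL = populate_template(profile, tree, builder["level"]) if builder else None
    mP = populate_template(profile, tree, builder["post"]) if builder else None
    return assemble_views(profile, mL, mP, mode)


def predict_proba(model: CascadeModel, profile: AbundanceProfile) -> np.ndarray:
    return model.predict_proba(profile)


def predict(model: CascadeModel, profile: AbundanceProfile) -> list[str]:
    return model.predict(profile)
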