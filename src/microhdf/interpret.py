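"""Feature-importance values (FIV) of a fitted cascade.

The raw gain of feature d in layer l is the summed impurity decrease
(Gini) attributed to splits on d over all T trees of all N forests in
the layer; the FIV is that gain summed over layers and normalized over
the original features:

    F_l^d = sum_n sum_t gain_{n,t}^{d,l}
    F_d   = sum_l F_l^d / sum_d sum_l F_l^d

Gains on augmented class-vector dimensions accumulate under a reserved
``__augmented__`` bucket and are excluded from the normalization, which
runs over the d = 1..D original features only.  A taxon that appears in
several views (raw, level, post-order) has its gains summed under the
single taxon id before normalizing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import AUGMENTED, CascadeModel

__all__ = ["FIVReport", "layer_feature_gain", "layer_gains", "compute_fiv", "top_k"]


@dataclass
class FIVReport:
    fiv: dict[str, float]  # original feature id -> normalized F_d
    per_layer: dict[str, dict[str, float]]  # layer key -> feature -> raw gain
    augmented_gain: float
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        ranked = top_k(self, len(self.fiv))
        return pd.DataFrame(
            {
                "feature": [f for f, _ in ranked],
                "FIV": [v for _, v in ranked],
                "rank": np.arange(1, len(ranked) + 1),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        payload = {
            "fiv": self.fiv,
            "per_layer": self.per_layer,
            "augmented_gain": self.augmented_gain,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _forest_gains(forest, selected) -> dict[int, float]:
    """Total impurity decrease per layer-input column for one sklearn forest."""
    out: dict[int, float] = {}
    for est in forest.estimators_:
        t = est.tree_
        # per-feature mean decrease rescaled back to the total decrease
        imp = t.compute_feature_importances(normalize=False)
        total_weight = t.weighted_n_node_samples[0]
        for j, v in enumerate(imp):
            if v <= 0:
                continue
            col = selected[j] if selected is not None else j
            out[col] = out.get(col, 0.0) + float(v) * float(total_weight)
    return out


def layer_gains(model: CascadeModel, layer_key: str) -> dict[str, float]:
    """Raw gain per original feature id for one layer (augmented bucketed)."""
    for key, forests, columns in model.iter_forest_groups():
        if key != layer_key:
            continue
        gains: dict[str, float] = {}
        for forest, selected in forests:
            for col, v in _forest_gains(forest, selected).items():
                fid = columns[col]
                gains[fid] = gains.get(fid, 0.0) + v
        return gains
    raise IndexError(f"no such layer: {layer_key!r}")


def layer_feature_gain(model: CascadeModel, layer_key: str, feature: str) -> float:
    """Raw gain F_l^d of one feature in one layer (0 when never split on)."""
    return layer_gains(model, layer_key).get(feature, 0.0)


def compute_fiv(model: CascadeModel) -> FIVReport:
    """Normalized FIV over the original features of all layers and channels."""
    per_layer: dict[str, dict[str, float]] = {}
    totals: dict[str, float] = {}
    augmented = 0.0
    layer_keys = []
    for key, forests, columns in model.iter_forest_groups():
        layer_keys.append(key)
        gains: dict[str, float] = {}
        for forest, selected in forests:
            for col, v in _forest_gains(forest, selected).items():
                fid = columns[col]
                gains[fid] = gains.get(fid, 0.0) + v
        per_layer[key] = gains
        for fid, v in gains.items():
            if fid == AUGMENTED:
                augmented += v
            else:
                totals[fid] = totals.get(fid, 0.0) + v
    # every original feature appears in the report, split on or not
    feature_ids = sorted(
        {
            fid
            for _, _, columns in model.iter_forest_groups()
            for fid in columns
            if fid != AUGMENTED
        }
    )
    for fid in feature_ids:
        totals.setdefault(fid, 0.0)
    grand = sum(totals.values())
    if grand <= 0:
        warnings.warn("all-zero total gain; FIV falls back to uniform", stacklevel=2)
        fiv = {fid: 1.0 / len(totals) for fid in totals}
    else:
        fiv = {fid: v / grand for fid, v in totals.items()}
    cfg = model.config
    meta = {
        "layers": layer_keys,
        "n_features": len(fiv),
        "n_trees": cfg.forest.n_trees,
        "n_subsets": cfg.forest.n_subsets,
    }
    return FIVReport(fiv, per_layer, augmented, meta)


def top_k(report: FIVReport, k: int) -> list[tuple[str, float]]:
    """Top-k features by descending FIV; ties broken by feature name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(report.fiv.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[: min(k, len(ranked))]
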