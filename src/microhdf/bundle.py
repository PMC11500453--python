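"""Model bundle persistence: a directory with metadata plus serialized forests."""

from __future__ import annotations

import json
from pathlib import Path

import joblib

from . import __version__
from .cascade import CascadeModel
from .io_profiles import write_newick

__all__ = ["save_bundle", "load_bundle", "BUNDLE_FORMAT"]

BUNDLE_FORMAT = 1


def save_bundle(model: CascadeModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": BUNDLE_FORMAT,
        "package_version": __version__,
        "config": model.config.to_dict(),
        "class_names": {str(k): v for k, v in model.class_names.items()},
        "taxon_ids": model.taxon_ids,
        "validation_trace": model.validation_trace,
        "templates": {
            name: model.phylo_builder[name].node_ids
            for name in ("level", "post")
        }
        if model.phylo_builder
        else None,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    if model.tree is not None:
        write_newick(model.tree, out / "tree.nwk")
    joblib.dump(model, out / "model.joblib")
    return out


def load_bundle(path: str | Path) -> CascadeModel:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a model bundle (no meta.json): {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format") != BUNDLE_FORMAT:
        raise ValueError(
            f"bundle format {meta.get('format')} incompatible with {BUNDLE_FORMAT}"
        )
    model = joblib.load(path / "model.joblib")
    if not isinstance(model, CascadeModel):
        raise ValueError("bundle does not contain a cascade model")
    return model
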