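"""Reading, validation and normalization of abundance tables, labels and trees.

Abundance tables are tab-separated text with MetaPhlAn-style lineage
strings as taxon identifiers (``k__...|p__...|...|s__...``).  Tables may
carry proportions or percentages; :func:`to_relative` renormalizes each
sample so both conventions behave identically downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import TaxonomyTree

__all__ = [
    "AbundanceProfile",
    "SampleLabels",
    "Lineage",
    "RANKS",
    "read_abundance_table",
    "write_abundance_table",
    "to_relative",
    "parse_lineage",
    "read_labels",
    "write_labels",
    "read_newick",
    "write_newick",
]

#: canonical taxonomic ranks, outermost first, keyed by their single-letter prefix
RANKS: dict[str, str] = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
_RANK_ORDER = {prefix: i for i, prefix in enumerate(RANKS)}


@dataclass
class Lineage:
    """Ordered (rank, name) pairs parsed from a lineage string."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty lineage")
        order = [_RANK_ORDER[r] for r, _ in self.entries]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError(f"ranks out of canonical order: {self.entries}")

    @property
    def terminal(self) -> tuple[str, str]:
        return self.entries[-1]

    def prefixed_tokens(self) -> list[str]:
        return [f"{r}__{n}" for r, n in self.entries]


def parse_lineage(taxon_id: str) -> Lineage:
    """Parse a ``|``-separated, rank-prefixed lineage string.

    >>> parse_lineage("k__Bacteria|s__Roseburia_hominis").terminal
    ('s', 'Roseburia_hominis')
    """
    tokens = taxon_id.split("|")
    entries: list[tuple[str, str]] = []
    for token in tokens:
        if "__" not in token:
            raise ValueError(f"malformed lineage token {token!r} in {taxon_id!r}")
        prefix, name = token.split("__", 1)
        if prefix not in RANKS:
            raise ValueError(f"unknown rank prefix {prefix!r} in {taxon_id!r}")
        if not name:
            raise ValueError(f"empty name in lineage token {token!r}")
        entries.append((prefix, name))
    return Lineage(entries)


@dataclass
class AbundanceProfile:
    """Samples x taxa relative-abundance matrix with lineage-string taxon ids."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, d = self.values.shape
        if n != len(self.sample_ids) or d != len(self.taxon_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if n == 0 or d == 0:
            raise ValueError("empty abundance table")
        for kind, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {kind} ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite abundance values")
        if np.any(self.values < 0):
            raise ValueError("negative abundance values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def require_fractions(self, tol: float = 1e-6) -> "AbundanceProfile":
        """Assert per-sample sums lie in [0, 1 + tol] (proportion convention)."""
        sums = self.values.sum(axis=1)
        bad = np.nonzero(sums > 1.0 + tol)[0]
        if bad.size:
            raise ValueError(
                f"sample rows do not sum to <= 1: e.g. {self.sample_ids[bad[0]]} "
                f"sums to {sums[bad[0]]:.6g} (wrong orientation or unnormalized data?)"
            )
        return self

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceProfile":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceProfile(list(sample_ids), list(self.taxon_ids), self.values[idx])

    def align_taxa(self, taxon_ids: list[str], warn: bool = True) -> "AbundanceProfile":
        """Reindex columns onto `taxon_ids`: missing taxa zero-filled, extras dropped."""
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in pos]
        extra = [t for t in self.taxon_ids if t not in set(taxon_ids)]
        if not any(t in pos for t in taxon_ids):
            raise ValueError("no overlap between profile taxa and requested taxa")
        if warn and (missing or extra):
            warnings.warn(
                f"taxon alignment: {len(missing)} taxa zero-filled, "
                f"{len(extra)} dropped",
                stacklevel=2,
            )
        out = np.zeros((len(self.sample_ids), len(taxon_ids)))
        for j, t in enumerate(taxon_ids):
            if t in pos:
                out[:, j] = self.values[:, pos[t]]
        return AbundanceProfile(list(self.sample_ids), list(taxon_ids), out)


@dataclass
class SampleLabels:
    """Binary phenotype per sample: 0 = control, 1 = case."""

    labels: dict[str, int]
    class_names: dict[int, str] = field(default_factory=lambda: {0: "0", 1: "1"})

    def __post_init__(self) -> None:
        bad = {s: v for s, v in self.labels.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"labels must be 0/1, got {bad}")

    def counts(self) -> tuple[int, int]:
        vals = list(self.labels.values())
        return vals.count(0), vals.count(1)

    def vector(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return np.array([self.labels[s] for s in sample_ids], dtype=int)

    def check_against(self, profile: AbundanceProfile, training: bool = True) -> None:
        present = set(profile.sample_ids)
        orphans = [s for s in self.labels if s not in present]
        if orphans:
            raise ValueError(f"labelled samples missing from profile: {orphans[:5]}")
        if training:
            labelled = [s for s in profile.sample_ids if s in self.labels]
            y = [self.labels[s] for s in labelled]
            if len(set(y)) < 2:
                raise ValueError("training requires both classes to be non-empty")


# ----------------------------------------------------------------------
# file IO


def read_abundance_table(
    path: str | Path,
    orientation: str = "taxa_rows",
    require_fractions: bool = False,
) -> AbundanceProfile:
    """Read a TSV abundance table.

    `orientation="taxa_rows"` (MetaPhlAn convention) means rows are taxa and
    columns are samples; `"samples_rows"` is the transpose.  Values must be
    non-negative numbers with no missing cells.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty abundance table: {path}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in abundance table {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing cells in abundance table: {path}")
    if orientation == "taxa_rows":
        df = df.T
    profile = AbundanceProfile(
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        values=df.to_numpy(),
    )
    if require_fractions:
        profile.require_fractions()
    return profile


def write_abundance_table(
    profile: AbundanceProfile, path: str | Path, orientation: str = "taxa_rows"
) -> None:
    df = profile.to_frame()
    if orientation == "taxa_rows":
        df = df.T
    df.to_csv(path, sep="\t")


def to_relative(profile: AbundanceProfile) -> AbundanceProfile:
    """Renormalize each sample row to sum to 1 (idempotent)."""
    sums = profile.values.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(
            f"all-zero sample rows cannot be normalized: "
            f"{[profile.sample_ids[i] for i in zero[:5]]}"
        )
    return AbundanceProfile(
        list(profile.sample_ids), list(profile.taxon_ids), profile.values / sums[:, None]
    )


def read_labels(path: str | Path, positive_class: str | None = None) -> SampleLabels:
    """Read a two-column TSV of sample id and phenotype.

    Labels may be literal 0/1 or two arbitrary strings; strings are mapped
    by first-seen order (first string seen -> 0) unless `positive_class`
    names the label that should map to 1 (case).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label table needs two columns: {path}")
    # tolerate a header row like "sample_id<TAB>label"
    first = df.iloc[0]
    if first[0].lower() in ("sample", "sample_id", "sampleid", "id"):
        df = df.iloc[1:]
    raw = dict(zip(df[0].astype(str), df[1].astype(str)))
    uniques = sorted(set(raw.values()), key=list(raw.values()).index)
    if len(uniques) > 2:
        raise ValueError(f"more than two label values: {uniques}")
    if set(uniques) <= {"0", "1"}:
        mapping = {"0": 0, "1": 1}
    elif positive_class is not None:
        if positive_class not in uniques:
            raise ValueError(f"positive class {positive_class!r} not among {uniques}")
        mapping = {v: int(v == positive_class) for v in uniques}
    else:
        mapping = {v: i for i, v in enumerate(uniques)}
    class_names = {v: k for k, v in mapping.items() if v in (0, 1)}
    class_names = {0: class_names.get(0, "0"), 1: class_names.get(1, "1")}
    return SampleLabels({s: mapping[v] for s, v in raw.items()}, class_names)


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, v in labels.labels.items():
            fh.write(f"{s}\t{labels.class_names[v]}\n")


def read_newick(path: str | Path) -> TaxonomyTree:
    text = Path(path).read_text()
    return TaxonomyTree.from_newick(text)


def write_newick(tree: TaxonomyTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
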