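"""The two cascade building blocks.

**RF-CUS** (random forest with cluster-based undersampling) rebalances a
class-skewed training set: majority samples are clustered by affinity
propagation on Bray–Curtis dissimilarity (K-means fallback on
non-convergence), each of N balanced subsets draws a cluster-stratified
fraction u of the majority class without replacement plus an equal-size
bootstrap of the minority class, one random forest is fitted per subset,
and predictions are the unweighted mean of the N forests' class
probabilities.

**ERTs** (extremely randomized trees with wrapper selection) reduce
dimensionality: features are ranked by an LDA effect score (LEfSe-style
Kruskal–Wallis screen followed by a log-scaled one-dimensional effect
size), a sequential-forward-selection wrapper with an ERT scorer keeps
the locally optimal subset, and the final ERT ensemble restricts its
split candidates to that subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, rankdata
from sklearn.cluster import AffinityPropagation, KMeans
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .config import ForestConfig, sklearn_seed

__all__ = [
    "ClusterAssignment",
    "BalancedTrainingSet",
    "RFCUSUnit",
    "ERTUnit",
    "bray_curtis",
    "cluster_majority",
    "build_balanced_sets",
    "fit_rf_cus",
    "rf_cus_proba",
    "lda_effect_scores",
    "kruskal_pvalues",
    "sequential_forward_select",
    "fit_erts",
    "erts_proba",
]


# ----------------------------------------------------------------------
# Bray–Curtis and majority-class clustering


def bray_curtis(X: np.ndarray) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity, BC = 1 - 2·Σmin/(Σa+Σb) ∈ [0, 1].

    A pair of all-zero samples has an undefined BC; it is defined as 0
    (identical emptiness) with a warning.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("Bray–Curtis requires non-negative data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(X, metric="braycurtis"))
    if np.isnan(D).any():
        warnings.warn("all-zero sample pair: Bray–Curtis defined as 0", stacklevel=2)
        D = np.nan_to_num(D, nan=0.0)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # cluster id per majority sample
    n_clusters: int
    method: str  # "affinity_propagation" | "kmeans_fallback" | "single"

    def cluster_indices(self) -> dict[int, np.ndarray]:
        return {c: np.nonzero(self.labels == c)[0] for c in np.unique(self.labels)}


def cluster_majority(
    D: np.ndarray,
    cfg: ForestConfig,
    X: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterAssignment:
    """Cluster majority samples by AP on similarity = -D, K-means fallback.

    AP is swept over damping {0.5, 0.7, 0.9} x preference {median, min} of
    the similarities; the first convergent run whose cluster count lies in
    [2, ap_target_clusters] wins.  If no run qualifies, K-means with
    k = min(ap_target_clusters, n) on the raw feature matrix is used.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = D.shape[0]
    if n < 2:
        return ClusterAssignment(np.zeros(n, dtype=int), max(n, 1), "single")
    S = -np.asarray(D, dtype=float)
    off = S[~np.eye(n, dtype=bool)]
    for damping in (0.5, 0.7, 0.9):
        for pref in (np.median(off), off.min()):
            ap = AffinityPropagation(
                affinity="precomputed",
                damping=damping,
                preference=pref,
                max_iter=cfg.ap_max_iter,
                random_state=sklearn_seed(rng),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ap.fit(S)
            converged = (
                ap.n_iter_ < cfg.ap_max_iter and len(ap.cluster_centers_indices_) > 0
            )
            k = len(np.unique(ap.labels_)) if converged else 0
            if converged and 2 <= k <= cfg.ap_target_clusters:
                labels = rankdata(ap.labels_, method="dense") - 1
                return ClusterAssignment(labels.astype(int), k, "affinity_propagation")
    k = min(cfg.ap_target_clusters, n)
    if X is None:
        raise ValueError("K-means fallback requires the raw feature matrix")
    km = KMeans(n_clusters=k, n_init=5, random_state=sklearn_seed(rng))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = km.fit_predict(X)
    labels = rankdata(labels, method="dense") - 1
    return ClusterAssignment(labels.astype(int), len(np.unique(labels)), "kmeans_fallback")


# ----------------------------------------------------------------------
# balanced subset construction


@dataclass
class BalancedTrainingSet:
    majority_idx: np.ndarray  # without replacement, cluster-stratified
    minority_idx: np.ndarray  # bootstrap, with replacement

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.majority_idx, self.minority_idx])

    def slice(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = self.indices
        return X[idx], y[idx]


def _allocate_quota(sizes: np.ndarray, m: int) -> np.ndarray:
    """Largest-remainder allocation of m draws across clusters.

    Quotas are capped by cluster size; every non-empty cluster gets >= 1
    when m >= number of clusters.
    """
    k = len(sizes)
    exact = m * sizes / sizes.sum()
    quota = np.floor(exact).astype(int)
    if m >= k:
        quota = np.maximum(quota, 1)
    quota = np.minimum(quota, sizes)
    # settle the remainder by largest fractional part, respecting caps
    order = np.argsort(-(exact - np.floor(exact)), kind="stable")
    i = 0
    while quota.sum() < m:
        c = order[i % k]
        if quota[c] < sizes[c]:
            quota[c] += 1
        i += 1
    while quota.sum() > m:
        c = order[(i := i + 1) % k]
        floor = 1 if (m >= k and sizes[c] > 0) else 0
        if quota[c] > floor:
            quota[c] -= 1
    return quota


def build_balanced_sets(
    X: np.ndarray,
    y: np.ndarray,
    clusters: ClusterAssignment,
    cfg: ForestConfig,
    rng: np.random.Generator,
    majority_class: int | None = None,
) -> list[BalancedTrainingSet]:
    """Create N class-balanced subsets by pairwise sampling.

    Per subset, m = round(u * n_majority) majority samples are drawn
    without replacement, allocated across clusters proportionally to
    cluster size, and paired with m minority bootstrap draws.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if majority_class is None:
        majority_class = int(classes[np.argmax(counts)])
    maj = np.nonzero(y == majority_class)[0]
    mino = np.nonzero(y != majority_class)[0]
    m = int(np.floor(cfg.undersampling_ratio * len(maj) + 0.5))
    if m == 0:
        raise ValueError("undersampling ratio too small: empty majority subset")
    cluster_idx = clusters.cluster_indices()
    sizes = np.array([len(v) for v in cluster_idx.values()])
    keys = list(cluster_idx.keys())
    quota = _allocate_quota(sizes, m)
    sets: list[BalancedTrainingSet] = []
    for _ in range(cfg.n_subsets):
        picked: list[np.ndarray] = []
        for c, q in zip(keys, quota):
            within = cluster_idx[c]
            sel = rng.choice(len(within), size=q, replace=False)
            picked.append(maj[within[sel]])
        maj_sel = np.concatenate(picked)
        min_sel = rng.choice(mino, size=m, replace=True)
        sets.append(BalancedTrainingSet(maj_sel, min_sel))
    return sets


# ----------------------------------------------------------------------
# RF-CUS unit


@dataclass
class RFCUSUnit:
    forests: list[RandomForestClassifier]
    clusters: ClusterAssignment
    classes_: np.ndarray
    config: ForestConfig

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return rf_cus_proba(self, X)


def fit_rf_cus(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ForestConfig,
    rng: np.random.Generator | None = None,
) -> RFCUSUnit:
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("RF-CUS requires both classes in the training data")
    majority_class = int(classes[np.argmax(counts)])
    maj_mask = y == majority_class
    D = bray_curtis(X[maj_mask])
    clusters = cluster_majority(D, cfg, X=X[maj_mask], rng=rng)
    sets = build_balanced_sets(X, y, clusters, cfg, rng, majority_class=majority_class)
    forests = []
    for s in sets:
        Xs, ys = s.slice(X, y)
        rf = RandomForestClassifier(
            n_estimators=cfg.n_trees, random_state=sklearn_seed(rng), n_jobs=1
        )
        rf.fit(Xs, ys)
        forests.append(rf)
    return RFCUSUnit(forests, clusters, np.array([0, 1]), cfg)


def _align_proba(est, X: np.ndarray) -> np.ndarray:
    """Probability columns in fixed (class 0, class 1) order."""
    p = est.predict_proba(X)
    out = np.zeros((X.shape[0], 2))
    for j, c in enumerate(est.classes_):
        out[:, int(c)] = p[:, j]
    return out


def rf_cus_proba(unit: RFCUSUnit, X: np.ndarray) -> np.ndarray:
    """Unweighted mean of the N forests' class-probability votes."""
    p = np.mean([_align_proba(rf, X) for rf in unit.forests], axis=0)
    return p / p.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# LDA effect ranking (LEfSe-style) and wrapper selection


def kruskal_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-group Kruskal–Wallis p-value per feature (vectorized, tie-corrected)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    ranks = rankdata(X, axis=0)
    groups = [y == 0, y == 1]
    h = np.zeros(X.shape[1])
    for g in groups:
        ng = g.sum()
        rsum = ranks[g].sum(axis=0)
        h += rsum**2 / ng
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction: per feature, 1 - sum(t^3 - t) / (n^3 - n)
    Xs = np.sort(X, axis=0)
    same = np.vstack([np.zeros((1, X.shape[1]), dtype=bool), Xs[1:] == Xs[:-1]])
    corr = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        runs = np.flatnonzero(~same[:, j])
        lengths = np.diff(np.append(runs, n))
        ties = lengths[lengths > 1]
        corr[j] = 1 - np.sum(ties**3 - ties) / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(corr > 0, h / corr, 0.0)
    return np.where(corr > 0, chi2.sf(h, df=1), 1.0)


def lda_effect_scores(X: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """LDA effect score per feature, used only to rank differential taxa.

    Features passing a Kruskal–Wallis screen (p < alpha) receive
    log10(1 + |Δ|), where Δ is the class-mean difference after rescaling
    each sample to a per-million total (the counts-per-million convention
    of LDA-effect-size analysis); screened-out and constant features
    score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    if np.any(X < 0):
        raise ValueError("effect scores require non-negative features")
    scores = np.zeros(X.shape[1])
    constant = X.max(axis=0) == X.min(axis=0)
    pvals = kruskal_pvalues(X, y)
    survive = (pvals < alpha) & ~constant
    if not survive.any():
        return scores
    sums = X.sum(axis=1, keepdims=True)
    Xm = np.divide(X, sums, out=np.zeros_like(X), where=sums > 0) * 1e6
    delta = np.abs(Xm[y == 1].mean(axis=0) - Xm[y == 0].mean(axis=0))
    scores[survive] = np.log10(1.0 + delta[survive])
    return scores


def rank_features(scores: np.ndarray, names: list[str] | None = None) -> list[int]:
    """Indices sorted by descending score; ties broken by feature name."""
    names = names if names is not None else [f"f{i:06d}" for i in range(len(scores))]
    return sorted(range(len(scores)), key=lambda i: (-scores[i], names[i]))


def _wrapper_score(
    X: np.ndarray, y: np.ndarray, cols: list[int], cfg: ForestConfig, seed: int
) -> float:
    """Internal k-fold balanced accuracy of a small ERT on the candidate columns."""
    folds = min(cfg.sfs_folds, int(np.min(np.bincount(y))))
    if folds < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        ert = ExtraTreesClassifier(
            n_estimators=cfg.sfs_trees, random_state=seed, n_jobs=1
        )
        ert.fit(X[np.ix_(tr, cols)], y[tr])
        scores.append(balanced_accuracy_score(y[te], ert.predict(X[np.ix_(te, cols)])))
    return float(np.mean(scores))


def sequential_forward_select(
    ranked: list[int],
    X: np.ndarray,
    y: np.ndarray,
    cfg: ForestConfig,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Greedy forward selection over the ranked features.

    Seeded with the top-ranked feature; a candidate is kept iff it improves
    the wrapper score by more than `sfs_tol`; the scan stops after
    `sfs_patience` consecutive non-improvements, at `sfs_max_candidates`
    scanned features, or when the ranking is exhausted.  Never empty.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if not ranked:
        raise ValueError("empty feature ranking")
    seed = sklearn_seed(rng)
    candidates = ranked[: cfg.sfs_max_candidates]
    selected = [candidates[0]]
    best = _wrapper_score(X, y, selected, cfg, seed)
    misses = 0
    for f in candidates[1:]:
        trial = _wrapper_score(X, y, selected + [f], cfg, seed)
        if trial > best + cfg.sfs_tol:
            selected.append(f)
            best = trial
            misses = 0
        else:
            misses += 1
            if misses >= cfg.sfs_patience:
                break
    return sorted(selected)


# ----------------------------------------------------------------------
# ERT unit


@dataclass
class ERTUnit:
    forest: ExtraTreesClassifier
    selected: list[int]  # columns of the layer input the forest was trained on
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return erts_proba(self, X)


def fit_erts(
    X: np.ndarray,
    y: np.ndarray,
    selected: list[int],
    cfg: ForestConfig,
    rng: np.random.Generator | None = None,
) -> ERTUnit:
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if not selected:
        raise ValueError("selected feature list must be non-empty")
    if max(selected) >= X.shape[1] or min(selected) < 0:
        raise IndexError("selected features out of range")
    ert = ExtraTreesClassifier(
        n_estimators=cfg.n_trees, random_state=sklearn_seed(rng), n_jobs=1
    )
    ert.fit(X[:, selected], y)
    return ERTUnit(ert, list(selected))


def erts_proba(unit: ERTUnit, X: np.ndarray) -> np.ndarray:
    p = _align_proba(unit.forest, X[:, unit.selected])
    return p / p.sum(axis=1, keepdims=True)


def fit_ert_unit(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ForestConfig,
    rng: np.random.Generator | None = None,
    feature_names: list[str] | None = None,
) -> ERTUnit:
    """Rank features, select a subset by SFS, fit the restricted ERT ensemble."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    scores = lda_effect_scores(X, y)
    ranked = rank_features(scores, feature_names)
    selected = sequential_forward_select(ranked, X, y, cfg, rng)
    return fit_erts(X, y, selected, cfg, rng)
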