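"""Weighted ensemble of random-(k) k-means (WKM) consensus clustering.

Each ensemble member clusters a random subset of features and samples with
a random number of clusters k.  Member weight combines the mean silhouette
with the clustering- and cluster-level consistencies against fuzzy
must-link / must-not-link constraints:

    w = ((silhouette + 1) / 2) * Q * geometric_mean(q_c)

The weighted co-association evidence is accumulated pairwise over
co-sampled pairs only, giving a consensus matrix C in [0, 1].  Consensus
partitions for each k are average-linkage cuts of 1 - C, scored on the
input space with BIC (lower is better) and the Calinski-Harabasz index
(higher is better).

The weight combination is deliberately isolated in
:func:`combine_weight` so alternative non-linear forms can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

__all__ = [
    "ConstraintSet",
    "WkmConfig",
    "ConsensusModel",
    "constraint_consistency",
    "combine_weight",
    "run_wkm_ensemble",
    "consensus_partition",
]


@dataclass
class ConstraintSet:
    """Fuzzy pairwise constraints, weights in (0, 1]."""

    must_link: set[tuple[int, int, float]] = field(default_factory=set)
    must_not_link: set[tuple[int, int, float]] = field(default_factory=set)

    def __post_init__(self) -> None:
        ml_pairs = {frozenset((a, b)) for a, b, _ in self.must_link}
        mnl_pairs = {frozenset((a, b)) for a, b, _ in self.must_not_link}
        overlap = ml_pairs & mnl_pairs
        if overlap:
            raise ValueError(f"pairs in both constraint sets: {sorted(map(tuple, overlap))}")
        for _, _, w in list(self.must_link) + list(self.must_not_link):
            if not 0 < w <= 1:
                raise ValueError(f"constraint weight {w} outside (0, 1]")

    @classmethod
    def from_taxon_map(
        cls,
        labels: list[str],
        taxon_of: dict[str, str],
        must_link_taxa: list[str],
        must_not_link_pairs: list[tuple[str, str]] | None = None,
        weight: float = 1.0,
    ) -> "ConstraintSet":
        """Must-link all sample pairs within each listed taxon; must-not-link
        all cross pairs of each listed taxon pair."""
        import itertools

        ml: set[tuple[int, int, float]] = set()
        mnl: set[tuple[int, int, float]] = set()
        for taxon in must_link_taxa:
            idx = [i for i, s in enumerate(labels) if taxon_of.get(s) == taxon]
            for a, b in itertools.combinations(idx, 2):
                ml.add((a, b, weight))
        for ta, tb in must_not_link_pairs or []:
            ia = [i for i, s in enumerate(labels) if taxon_of.get(s) == ta]
            ib = [i for i, s in enumerate(labels) if taxon_of.get(s) == tb]
            for a in ia:
                for b in ib:
                    mnl.add((min(a, b), max(a, b), weight))
        return cls(must_link=ml, must_not_link=mnl)


@dataclass
class WkmConfig:
    n_runs: int = 5000
    feature_fraction: float = 0.60
    sample_fraction: float = 0.80
    k_min: int = 2
    k_max: int = 14
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.feature_fraction <= 1 and 0 < self.sample_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


@dataclass
class ConsensusModel:
    C: np.ndarray
    co_sample_counts: np.ndarray
    config: WkmConfig
    weight_formula: str = "((s+1)/2) * Q * geomean(q_c)"
    per_k: dict[int, tuple[np.ndarray, float, float]] = field(default_factory=dict)
    k_best_bic: int | None = None
    k_best_ch: int | None = None

    def labels_at(self, k: int) -> np.ndarray:
        return self.per_k[k][0]


def constraint_consistency(
    labels: np.ndarray,
    sample_indices: np.ndarray,
    constraints: ConstraintSet,
) -> tuple[float, dict[int, float]]:
    """Clustering-level and per-cluster consistency with fuzzy constraints.

    Q = 1 - (sum of violated weights) / (sum of applicable weights), with
    Q = 1 when no constraint is applicable; q_c restricts both sums to
    constraints touching cluster c.  Only constraints whose both samples
    were co-sampled in this run are applicable.
    """
    pos = {int(s): i for i, s in enumerate(sample_indices)}
    applicable = 0.0
    violated = 0.0
    per_cluster_app: dict[int, float] = {}
    per_cluster_vio: dict[int, float] = {}

    def tally(a: int, b: int, w: float, is_violation: bool) -> None:
        nonlocal applicable, violated
        applicable += w
        if is_violation:
            violated += w
        for c in {int(labels[pos[a]]), int(labels[pos[b]])}:
            per_cluster_app[c] = per_cluster_app.get(c, 0.0) + w
            if is_violation:
                per_cluster_vio[c] = per_cluster_vio.get(c, 0.0) + w

    for a, b, w in constraints.must_link:
        if a in pos and b in pos:
            tally(a, b, w, labels[pos[a]] != labels[pos[b]])
    for a, b, w in constraints.must_not_link:
        if a in pos and b in pos:
            tally(a, b, w, labels[pos[a]] == labels[pos[b]])

    if applicable == 0:
        return 1.0, {int(c): 1.0 for c in np.unique(labels)}
    Q = 1.0 - violated / applicable
    q = {}
    for c in np.unique(labels):
        c = int(c)
        app = per_cluster_app.get(c, 0.0)
        q[c] = 1.0 if app == 0 else 1.0 - per_cluster_vio.get(c, 0.0) / app
    return Q, q


def combine_weight(silhouette: float, Q: float, q_per_cluster: dict[int, float]) -> float:
    """Non-linear combination of quality terms into a run weight in [0, 1]."""
    qs = np.array(list(q_per_cluster.values()))
    geo = float(np.exp(np.mean(np.log(np.clip(qs, 1e-300, None))))) if np.all(qs > 0) else 0.0
    return ((silhouette + 1.0) / 2.0) * Q * geo


def run_wkm_ensemble(
    X: np.ndarray,
    constraints: ConstraintSet | None = None,
    cfg: WkmConfig | None = None,
    weight_fn: Callable[[float, float, dict[int, float]], float] = combine_weight,
) -> ConsensusModel:
    """Build the weighted co-association consensus matrix.

    Every run draws ``ceil(feature_fraction * d)`` features and
    ``ceil(sample_fraction * n)`` samples without replacement, a uniform
    k (capped so the silhouette stays defined), fits k-means (k-means++
    init, <= 300 iterations), and adds its weighted co-assignment evidence
    for the co-sampled pairs.  C_ij = M_ij / N_ij with diagonal 1.
    """
    cfg = cfg or WkmConfig()
    constraints = constraints or ConstraintSet()
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if d < 1 or n < 3:
        raise ValueError("need >= 3 samples and >= 1 feature")
    rng = np.random.default_rng(cfg.seed)
    n_feat = max(1, int(np.ceil(cfg.feature_fraction * d)))
    n_samp = max(3, int(np.ceil(cfg.sample_fraction * n)))
    k_cap = min(cfg.k_max, n_samp - 1)
    if k_cap < cfg.k_min:
        raise ValueError("sample subset too small for k_min clusters")

    M = np.zeros((n, n))
    N = np.zeros((n, n))
    for _ in range(cfg.n_runs):
        feats = rng.choice(d, size=n_feat, replace=False)
        samples = rng.choice(n, size=n_samp, replace=False)
        k = int(rng.integers(cfg.k_min, k_cap + 1))
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1, max_iter=300,
            random_state=int(rng.integers(2**31 - 1)),
        )
        sub = X[np.ix_(samples, feats)]
        labels = km.fit_predict(sub)
        if len(np.unique(labels)) < 2:
            continue
        try:
            sil = float(silhouette_score(sub, labels))
        except ValueError:
            continue
        Q, q = constraint_consistency(labels, samples, constraints)
        w = weight_fn(sil, Q, q)
        same = labels[:, None] == labels[None, :]
        idx = np.ix_(samples, samples)
        M[idx] += w * same
        N[idx] += w
    never = (N + np.eye(n) == 0).any(axis=1)
    if never.any():
        raise RuntimeError(
            f"samples never co-sampled with a positive-weight run: "
            f"{np.where(never)[0].tolist()}; increase n_runs"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(N > 0, M / np.where(N == 0, 1, N), 0.0)
    np.fill_diagonal(C, 1.0)
    return ConsensusModel(C=C, co_sample_counts=N, config=cfg)


def hard_cluster_bic(X: np.ndarray, labels: np.ndarray) -> float:
    """Spherical-Gaussian BIC for a hard partition (lower is better).

    X-means-style formulation: shared maximum-likelihood variance
    ``sigma^2 = SS_w / (d (n - k))``, log-likelihood including the cluster
    assignment term ``sum_c n_c ln(n_c / n)``, and ``k (d + 1)`` free
    parameters (centroids plus mixing weights).  The naive
    ``n d ln(SS_w/(n d)) + k d ln n`` variant is monotone decreasing in k
    on well-separated low-dimensional score configurations and cannot
    recover a planted cluster number, so this standard form is used.
    """
    n, d = X.shape
    ks = np.unique(labels)
    k = len(ks)
    if n - k <= 0:
        return float("inf")
    ss_w = 0.0
    ll = 0.0
    for c in ks:
        sub = X[labels == c]
        ss_w += ((sub - sub.mean(axis=0)) ** 2).sum()
        ll += len(sub) * np.log(len(sub) / n)
    sigma2 = max(ss_w / (d * (n - k)), 1e-300)
    ll -= 0.5 * n * d * np.log(2 * np.pi * sigma2)
    ll -= 0.5 * d * (n - k)
    return float(-2.0 * ll + k * (d + 1) * np.log(n))


def consensus_partition(model: ConsensusModel, X: np.ndarray) -> ConsensusModel:
    """Cut the consensus dendrogram at each k and score the cuts.

    Average-linkage hierarchical clustering on dissimilarity 1 - C; for
    each k in [k_min, k_max] the partition is scored on X by BIC and CH;
    ties in the arg-optima resolve toward smaller k (parsimony).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    diss = 1.0 - model.C
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    cfg = model.config
    per_k: dict[int, tuple[np.ndarray, float, float]] = {}
    import warnings as _warnings

    for k in range(cfg.k_min, cfg.k_max + 1):
        if k > n - 1:
            _warnings.warn(f"k={k} > n-1={n - 1}; skipped", stacklevel=2)
            continue
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) != k:
            _warnings.warn(f"dendrogram cut at k={k} yields fewer clusters; skipped",
                           stacklevel=2)
            continue
        bic = hard_cluster_bic(X, labels)
        ch = float(calinski_harabasz_score(X, labels))
        per_k[k] = (labels, bic, ch)
    if not per_k:
        raise RuntimeError("no valid k produced a partition")
    ks = sorted(per_k)
    model.per_k = per_k
    model.k_best_bic = min(ks, key=lambda k: (per_k[k][1], k))
    model.k_best_ch = max(ks, key=lambda k: (per_k[k][2], -k))
    return model
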