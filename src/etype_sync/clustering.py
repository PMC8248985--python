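"""E-type identification by k-means meta-clustering consensus.

Stages
------
1. ``preprocess_features`` — drop one member of any feature pair with
   |Spearman rho| >= 0.9, z-score and rescale each kept feature to [0, 1],
   rank features by share of total variance and drop those beyond the 90%
   cumulative cutoff.
2. ``kmeans_scan`` — 50-replicate k-means for k = 1..40 (best replicate by
   within-cluster squared-Euclidean inertia) with nine validity indices
   per k.  Rand, Mirkin and Hubert need two partitions; here they are
   replicate-stability indices: the mean pairwise value across the
   replicate partitions at each k.
3. ``meta_cluster`` — n realizations of the best-of-50 k-means for each
   k in 5..15; pairwise co-assignment probabilities across realizations;
   reliable clusters = single-linkage connected components of the
   co-assignment graph thresholded at p >= 0.9, keeping components with
   at least five units; the final k maximizes the proportion of units in
   reliable clusters, cross-checked by AIC/BIC of a spherical Gaussian
   mixture at each k-means solution.
4. ``validate_classes`` — randomization validation: per-class distinctness
   of associated vs non-associated cluster centroids against shuffled
   association, and consistency of unit assignment against random labels.

Class names follow the field convention: narrow-spiking classes N1..Nk and
broad-spiking classes B1..Bm, ordered by ascending local variation (LV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "FeatureMatrix",
    "ConsensusResult",
    "preprocess_features",
    "kmeans_scan",
    "meta_cluster",
    "validate_classes",
    "name_classes",
]


@dataclass
class FeatureMatrix:
    """Preprocessed unit-by-feature matrix for clustering."""

    X: pd.DataFrame  # kept features, each z-scored then rescaled to [0, 1]
    kept: list
    dropped: dict  # feature -> reason
    variance_share: pd.Series


@dataclass
class ConsensusResult:
    """Meta-clustering consensus output."""

    labels: np.ndarray  # final class index per unit (nearest-centroid filled)
    reliable: np.ndarray  # True when the unit sits in a reliable cluster
    coassignment: np.ndarray  # units x units co-assignment probability at best k
    best_k: int
    fraction_reliable: pd.Series  # per k
    ic_table: pd.DataFrame  # AIC/BIC per k
    class_sizes: pd.Series = field(default=None)


def preprocess_features(
    raw: pd.DataFrame,
    corr_threshold: float = 0.9,
    variance_cutoff: float = 0.9,
) -> FeatureMatrix:
    """Decorrelate, scale and variance-rank the per-unit metrics."""
    if raw.shape[1] < 2 or len(raw) < 20:
        raise ValueError("need at least 2 features and 20 units")
    raw = raw.astype(float)
    dropped: dict = {}

    # z-score and rescale first (variance shares are computed on this scale)
    z = (raw - raw.mean()) / raw.std(ddof=0)
    if z.isna().any().any():
        bad = z.columns[z.isna().any()].tolist()
        raise ValueError(f"zero-variance feature(s): {bad}")
    scaled = (z - z.min()) / (z.max() - z.min())

    # drop one member of each highly correlated pair (keep higher variance)
    keep = list(scaled.columns)
    rho = spearmanr(raw.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    var = scaled.var(ddof=0)
    for i, a in enumerate(raw.columns):
        for j in range(i + 1, raw.shape[1]):
            b = raw.columns[j]
            if a in keep and b in keep and abs(rho[i, j]) >= corr_threshold:
                victim = a if var[a] < var[b] else b
                keep.remove(victim)
                dropped[victim] = f"|Spearman rho|>= {corr_threshold} with {a if victim == b else b}"
    if len(keep) < 2:
        raise ValueError("all features collinear")

    share = var[keep] / var[keep].sum()
    order = share.sort_values(ascending=False)
    cum = order.cumsum()
    kept = []
    for name, c in cum.items():
        kept.append(name)
        if c >= variance_cutoff:
            break
    for name in order.index:
        if name not in kept:
            dropped[name] = "beyond 90% cumulative variance"
    return FeatureMatrix(
        X=scaled[kept], kept=kept, dropped=dropped, variance_share=order
    )


def _best_kmeans(X: np.ndarray, k: int, n_rep: int, rng: np.random.Generator) -> KMeans:
    km = KMeans(
        n_clusters=k,
        n_init=n_rep,
        init="random",
        random_state=int(rng.integers(2**31)),
    )
    km.fit(X)
    return km


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Rand, Mirkin and Hubert indices between two partitions (pair counting)."""
    n = a.size
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, 1)
    sa, sb = same_a[iu], same_b[iu]
    agree = np.mean(sa == sb)
    rand = float(agree)
    mirkin = float(1.0 - agree)  # normalized pair-disagreement distance
    # Hubert's gamma: correlation of the co-membership indicators
    sa_f, sb_f = sa.astype(float), sb.astype(float)
    denom = sa_f.std() * sb_f.std()
    hubert = float(np.corrcoef(sa_f, sb_f)[0, 1]) if denom > 0 else np.nan
    return rand, mirkin, hubert


def kmeans_scan(
    fm: FeatureMatrix,
    k_range=range(1, 41),
    n_rep: int = 50,
    n_stability: int = 10,
    seed=0,
) -> pd.DataFrame:
    """Validity indices of best-of-``n_rep`` k-means over a range of k."""
    rng = np.random.default_rng(seed)
    X = fm.X.to_numpy()
    n = X.shape[0]
    rows = []
    inertia_by_k = {}
    for k in k_range:
        if k > n:
            break
        km = _best_kmeans(X, k, n_rep, rng)
        labels = km.labels_
        inertia_by_k[k] = km.inertia_
        row = {"k": k, "inertia": km.inertia_}
        if k >= 2 and len(np.unique(labels)) >= 2:
            row["silhouette"] = silhouette_score(X, labels)
            row["calinski_harabasz"] = calinski_harabasz_score(X, labels)
            row["davies_bouldin"] = davies_bouldin_score(X, labels)
        else:
            row["silhouette"] = row["calinski_harabasz"] = row["davies_bouldin"] = np.nan
        # homogeneity: mean distance to own centroid; separation: weighted
        # mean pairwise centroid distance
        d_own = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
        row["homogeneity"] = float(d_own.mean())
        if k >= 2:
            cd = cdist(km.cluster_centers_, km.cluster_centers_)
            sizes = np.bincount(labels, minlength=k).astype(float)
            w = sizes[:, None] * sizes[None, :]
            np.fill_diagonal(w, 0.0)
            row["separation"] = float((cd * w).sum() / w.sum())
        else:
            row["separation"] = np.nan
        # replicate-stability indices over small best-of-5 partitions
        if k >= 2:
            parts = [
                KMeans(
                    n_clusters=k, n_init=5, init="random", random_state=int(rng.integers(2**31))
                )
                .fit(X)
                .labels_
                for _ in range(n_stability)
            ]
            vals = [
                _pair_counts(parts[i], parts[j])
                for i in range(len(parts))
                for j in range(i + 1, len(parts))
            ]
            row["rand"], row["mirkin"], row["hubert"] = np.nanmean(vals, axis=0)
        else:
            row["rand"], row["mirkin"], row["hubert"] = 1.0, 0.0, np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("k")
    # Hartigan's rule: (W_k / W_{k+1} - 1) * (n - k - 1)
    hart = {}
    for k in df.index:
        if k + 1 in inertia_by_k and inertia_by_k[k + 1] > 0:
            hart[k] = (inertia_by_k[k] / inertia_by_k[k + 1] - 1.0) * (n - k - 1)
    df["hartigan"] = pd.Series(hart)
    return df


def _spherical_gmm_ic(X: np.ndarray, km: KMeans) -> tuple[float, float]:
    """AIC/BIC of a spherical Gaussian mixture evaluated at the k-means solution."""
    n, d = X.shape
    k = km.n_clusters
    labels = km.labels_
    resid = X - km.cluster_centers_[labels]
    sigma2 = max(np.mean(resid**2), 1e-12)
    sizes = np.bincount(labels, minlength=k).astype(float)
    pi = np.clip(sizes / n, 1e-12, None)
    # classification log-likelihood at the hard assignment
    ll = float(
        np.sum(np.log(pi[labels]))
        - 0.5 * n * d * np.log(2 * np.pi * sigma2)
        - 0.5 * np.sum(resid**2) / sigma2
    )
    p = k * d + 1 + (k - 1)
    aic = -2 * ll + 2 * p
    bic = -2 * ll + p * np.log(n)
    return aic, bic


def meta_cluster(
    fm: FeatureMatrix,
    k_range=range(5, 16),
    n_real: int = 500,
    n_rep: int = 50,
    p_thresh: float = 0.9,
    min_size: int = 5,
    seed=0,
) -> ConsensusResult:
    """Consensus e-type classes from repeated k-means realizations."""
    rng = np.random.default_rng(seed)
    X = fm.X.to_numpy()
    n = X.shape[0]
    per_k = {}
    frac = {}
    ic_rows = []
    for k in k_range:
        if k > n:
            break
        co = np.zeros((n, n))
        last_km = None
        for _ in range(n_real):
            km = _best_kmeans(X, k, n_rep, rng)
            same = km.labels_[:, None] == km.labels_[None, :]
            co += same
            last_km = km
        co /= n_real
        graph = csr_matrix(co >= p_thresh)
        n_comp, comp = connected_components(graph, directed=False)
        sizes = np.bincount(comp)
        reliable_comp = np.nonzero(sizes >= min_size)[0]
        reliable = np.isin(comp, reliable_comp)
        frac[k] = float(reliable.mean())
        aic, bic = _spherical_gmm_ic(X, last_km)
        ic_rows.append({"k": k, "aic": aic, "bic": bic})
        per_k[k] = (co, comp, reliable, bic)
    if not per_k:
        raise ValueError("no k in range fits the data size")
    # best k maximizes the reliable fraction; ties broken by minimum BIC of
    # the spherical mixture at the k-means solution (the validation the
    # procedure prescribes)
    max_frac = max(frac.values())
    tied = [k for k in per_k if frac[k] >= max_frac - 1e-12]
    k_star = min(tied, key=lambda k: per_k[k][3])
    co, comp, reliable, _ = per_k[k_star]
    if not reliable.any():
        raise ValueError(
            f"no reliable cluster of >= {min_size} units at p >= {p_thresh}; "
            f"fractions per k: {frac}"
        )
    # relabel reliable components 0..C-1; fill unreliable units by nearest
    # reliable-class centroid (flagged via `reliable`)
    comp_ids = np.unique(comp[reliable])
    remap = {c: i for i, c in enumerate(comp_ids)}
    labels = np.full(n, -1)
    for c, i in remap.items():
        labels[comp == c] = i
    centroids = np.stack([X[labels == i].mean(axis=0) for i in range(len(comp_ids))])
    missing = labels < 0
    if missing.any():
        d = cdist(X[missing], centroids)
        labels[missing] = np.argmin(d, axis=1)
    sizes = pd.Series(labels).value_counts().sort_index()
    return ConsensusResult(
        labels=labels,
        reliable=reliable,
        coassignment=co,
        best_k=k_star,
        fraction_reliable=pd.Series(frac).sort_index(),
        ic_table=pd.DataFrame(ic_rows).set_index("k"),
        class_sizes=sizes,
    )


def validate_classes(
    fm: FeatureMatrix,
    labels: np.ndarray,
    n_real: int = 200,
    n_rep: int = 50,
    min_size: int = 5,
    seed=0,
) -> pd.DataFrame:
    """Randomization validation of the final classes.

    For each realization a fresh best-of-``n_rep`` k-means (k = number of
    classes) is matched to the reference classes by centroid proximity.
    Per class the report gives (a) distinctness: mean distance between
    associated and non-associated realization centroids, against the same
    quantity with shuffled association, and (b) consistency: proportion of
    the class's units assigned to the matched cluster, against shuffled
    reference labels.
    """
    rng = np.random.default_rng(seed)
    X = fm.X.to_numpy()
    classes = [c for c in np.unique(labels) if np.sum(labels == c) >= min_size]
    ref_centroids = np.stack([X[labels == c].mean(axis=0) for c in classes])
    k = len(classes)
    if k < 2:
        raise ValueError("need at least two classes of min_size units")
    # pool realization centroids per class across realizations: with
    # proximity association the pooled associated mean hugs the class
    # centroid, far from the pooled non-associated mean; under random
    # association both pools collapse onto the grand mean
    assoc_pool = {c: [] for c in classes}
    nonassoc_pool = {c: [] for c in classes}
    assoc_pool_null = {c: [] for c in classes}
    nonassoc_pool_null = {c: [] for c in classes}
    cons_obs = {c: [] for c in classes}
    cons_null = {c: [] for c in classes}
    for _ in range(n_real):
        km = _best_kmeans(X, k, n_rep, rng)
        cents = km.cluster_centers_
        assoc = np.argmin(cdist(cents, ref_centroids), axis=1)  # cluster -> class idx
        shuffled = rng.permutation(assoc)
        perm_labels = rng.permutation(labels)
        for ci, c in enumerate(classes):
            assoc_pool[c].extend(cents[assoc == ci])
            nonassoc_pool[c].extend(cents[assoc != ci])
            assoc_pool_null[c].extend(cents[shuffled == ci])
            nonassoc_pool_null[c].extend(cents[shuffled != ci])
            in_class = labels == c
            matched = np.isin(km.labels_, np.nonzero(assoc == ci)[0])
            cons_obs[c].append(np.mean(matched[in_class]))
            cons_null[c].append(np.mean(matched[perm_labels == c]))

    def pooled_distance(a, b):
        if not a or not b:
            return np.nan
        return float(np.linalg.norm(np.mean(a, axis=0) - np.mean(b, axis=0)))

    rows = []
    for c in classes:
        rows.append(
            {
                "class": c,
                "distinctness": pooled_distance(assoc_pool[c], nonassoc_pool[c]),
                "distinctness_null": pooled_distance(
                    assoc_pool_null[c], nonassoc_pool_null[c]
                ),
                "consistency": float(np.mean(cons_obs[c])),
                "consistency_null": float(np.mean(cons_null[c])),
            }
        )
    df = pd.DataFrame(rows).set_index("class")
    df["distinct_exceeds_null"] = df["distinctness"] > df["distinctness_null"]
    df["consistent_exceeds_null"] = df["consistency"] > df["consistency_null"]
    return df


def name_classes(labels: np.ndarray, narrow: np.ndarray, lv: np.ndarray) -> dict:
    """Map class indices to N1..Nk / B1..Bm names.

    A class is "narrow" when the majority of its units are narrow-spiking;
    within each waveform group classes are numbered by ascending mean LV.
    """
    names = {}
    for is_narrow, prefix in ((True, "N"), (False, "B")):
        cls = [
            c
            for c in np.unique(labels)
            if (np.mean(narrow[labels == c]) > 0.5) == is_narrow
        ]
        order = np.argsort([np.mean(lv[labels == c]) for c in cls])
        for rank, idx in enumerate(order):
            names[cls[idx]] = f"{prefix}{rank + 1}"
    return names
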