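"""Cluster-number estimation by recursive Gap-statistic partitioning.

The Gap statistic compares the log within-cluster dispersion of the
observed data, clustered at each candidate k, with its expectation under
a structureless reference distribution (uniform over the data range in
the principal-component frame). The selected k is the smallest one whose
gap is within one simulation standard error of the next gap.

PART (partitioning by recursive thresholding) applies the Gap statistic
recursively: when k > 1 clusters are found, each cluster is re-tested on
its own subset, which uncovers sub-clusters nested inside top-level
structure. Recursion stops on subsets smaller than ``2 * min_size``. A
subset judged homogeneous (k = 1) is additionally probed with a
*tentative* binary split: if one side is smaller than ``min_size`` those
cases are set aside as outliers, the remainder is re-tested, and the
outliers are finally attached to the nearest resulting cluster — this
keeps a few extreme cases from masking genuine structure.

Two base clustering engines are supported, mirroring common practice:
``"hclust"`` (Ward agglomeration cut at k) and ``"kmeans"`` (Lloyd's
algorithm with seeded restarts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

__all__ = [
    "GapProfile",
    "Partition",
    "within_dispersion",
    "gap_statistic",
    "part_recursive",
]

ENGINES = ("hclust", "kmeans")
#: Lloyd restarts for the observed data / for each reference draw.
KMEANS_RESTARTS = 25
KMEANS_RESTARTS_REFERENCE = 5


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Log pooled within-cluster dispersion.

    W = Σ_r D_r / (2 n_r), with D_r the sum of squared pairwise
    Euclidean distances inside cluster r — algebraically the total
    squared deviation from cluster centroids. Returns log W, with
    ``-inf`` as the sentinel for W = 0 (singleton/duplicate clusters).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match the number of observations")
    w = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        if sub.shape[0] == 0:
            raise ValueError(f"empty cluster {lab!r}")
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return float(np.log(w)) if w > 0 else -np.inf


def _cluster_at_ks(X, ks, engine, rng, restarts):
    """labels[k] for each k in ks, computed by the chosen engine."""
    out = {}
    if engine == "hclust":
        if X.shape[0] > 1:
            Z = linkage(X, method="ward")
        for k in ks:
            out[k] = (
                np.zeros(X.shape[0], dtype=int)
                if k == 1
                else fcluster(Z, t=k, criterion="maxclust") - 1
            )
    elif engine == "kmeans":
        for k in ks:
            if k == 1:
                out[k] = np.zeros(X.shape[0], dtype=int)
            else:
                km = KMeans(
                    n_clusters=k,
                    n_init=restarts,
                    random_state=int(rng.integers(2**31)),
                )
                out[k] = km.fit_predict(X)
    else:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    return out


@dataclass
class GapProfile:
    k_values: np.ndarray
    log_W: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    B: int
    engine: str
    chosen_k: int


def _choose_k(
    gap: np.ndarray, se: np.ndarray, k_values: np.ndarray, selection: str
) -> int:
    """k-selection rule applied to a gap profile.

    ``"tibshirani"`` (default): smallest k with gap(k) >= gap(k+1) - se(k+1),
    else the largest k. ``"first-max"``: smallest k whose gap exceeds both
    neighbors (global argmax when the profile is monotone).
    """
    if selection == "tibshirani":
        for i in range(len(k_values) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                return int(k_values[i])
        return int(k_values[-1])
    if selection == "first-max":
        for i in range(len(k_values)):
            left_ok = i == 0 or gap[i] >= gap[i - 1]
            right_ok = i == len(k_values) - 1 or gap[i] >= gap[i + 1]
            if left_ok and right_ok:
                return int(k_values[i])
        return int(k_values[int(np.argmax(gap))])
    raise ValueError(f"unknown selection rule {selection!r}")


def gap_statistic(
    X: np.ndarray,
    k_max: int = 10,
    B: int = 500,
    engine: str = "hclust",
    seed: int = 0,
    selection: str = "tibshirani",
) -> GapProfile:
    """Gap profile over k = 1..k_max with B reference draws.

    Reference datasets are sampled uniformly over the range of the data
    in its principal-axes frame (rotation-aware uniform box), then
    rotated back. The simulation standard error carries the
    sqrt(1 + 1/B) correction for using an estimated reference mean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if B < 2:
        raise ValueError("need B >= 2 reference datasets (se undefined for B=1)")
    if k_max >= n:
        warnings.warn(f"k_max={k_max} >= n={n}; clipped to {n - 1}")
        k_max = n - 1
    k_max = max(k_max, 1)
    ks = np.arange(1, k_max + 1)
    rng = np.random.default_rng(seed)

    labels_obs = _cluster_at_ks(X, ks, engine, rng, KMEANS_RESTARTS)
    log_w = np.array([within_dispersion(X, labels_obs[k]) for k in ks])

    mean = X.mean(axis=0)
    Xc = X - mean
    # principal-axes frame of the observed data
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)

    log_w_ref = np.empty((B, len(ks)))
    for b in range(B):
        Zp = rng.uniform(lo, hi, size=Xp.shape)
        Z = Zp @ Vt + mean
        labels_ref = _cluster_at_ks(Z, ks, engine, rng, KMEANS_RESTARTS_REFERENCE)
        log_w_ref[b] = [within_dispersion(Z, labels_ref[k]) for k in ks]

    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return GapProfile(ks, log_w, gap, se, B, engine, _choose_k(gap, se, ks, selection))


@dataclass
class Partition:
    labels: dict[str, int]
    engine: str
    B: int
    min_size: int
    seed: int
    tree: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def label_array(self, ids) -> np.ndarray:
        return np.array([self.labels[str(i)] for i in ids])


def part_recursive(
    X: np.ndarray,
    engine: str = "hclust",
    B: int = 500,
    min_size: int = 3,
    k_max: int = 10,
    seed: int = 0,
    ids: list[str] | None = None,
    selection: str = "tibshirani",
) -> Partition:
    """Recursive Gap-statistic partitioning with outlier isolation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    ids = [str(i) for i in (ids if ids is not None else range(n))]
    if len(ids) != n:
        raise ValueError("ids length must match the number of observations")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A7]))
    final = np.full(n, -1, dtype=int)
    next_label = [0]

    def assign_leaf(idx):
        lab = next_label[0]
        final[idx] = lab
        next_label[0] += 1
        return lab

    def profile_summary(p: GapProfile) -> dict:
        return {
            "chosen_k": p.chosen_k,
            "k_values": p.k_values.tolist(),
            "gap": np.round(p.gap, 6).tolist(),
            "se": np.round(p.se, 6).tolist(),
        }

    def recurse(idx: np.ndarray) -> dict:
        node: dict = {"n": int(len(idx))}
        if len(idx) < 2 * min_size:
            node["leaf"] = assign_leaf(idx)
            node["stop"] = "fewer than 2*min_size cases"
            return node
        sub = X[idx]
        prof = gap_statistic(
            sub,
            k_max=min(k_max, len(idx) - 1),  # silent clip inside the recursion
            B=B,
            engine=engine,
            seed=int(rng.integers(2**31)),
            selection=selection,
        )
        node["profile"] = profile_summary(prof)
        if prof.chosen_k > 1:
            labels = _cluster_at_ks(
                sub, [prof.chosen_k], engine, rng, KMEANS_RESTARTS
            )[prof.chosen_k]
            node["children"] = [
                recurse(idx[labels == lab]) for lab in np.unique(labels)
            ]
            return node
        # tentative binary split to isolate outliers
        two = _cluster_at_ks(sub, [2], engine, rng, KMEANS_RESTARTS)[2]
        sizes = np.bincount(two, minlength=2)
        small = int(np.argmin(sizes))
        if 0 < sizes[small] < min_size and sizes[1 - small] >= 2:
            out_idx = idx[two == small]
            rest_idx = idx[two != small]
            node["outliers_set_aside"] = [ids[i] for i in out_idx]
            node["children"] = [recurse(rest_idx)]
            # reattach each outlier to the nearest resulting cluster centroid
            labs = np.unique(final[rest_idx])
            cents = np.vstack([X[final == lab].mean(axis=0) for lab in labs])
            for i in out_idx:
                d = ((cents - X[i]) ** 2).sum(axis=1)
                final[i] = labs[int(np.argmin(d))]
            return node
        node["leaf"] = assign_leaf(idx)
        node["stop"] = "gap statistic selected k=1"
        return node

    tree = recurse(np.arange(n))
    # relabel to consecutive ids in observation order
    remap: dict[int, int] = {}
    labels_out: dict[str, int] = {}
    for i, sid in enumerate(ids):
        lab = int(final[i])
        remap.setdefault(lab, len(remap))
        labels_out[sid] = remap[lab]
    return Partition(labels_out, engine, B, min_size, seed, tree)
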