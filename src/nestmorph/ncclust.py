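"""Nest-centroid clustering: discriminant morphospace + dendrogram.

Step one of the delimitation protocol reduces dimensionality with a
linear discriminant analysis that uses *nest samples* as groups: workers
from one nest are close kin, so the pooled within-nest scatter estimates
pure measurement + within-colony variation, and the discriminant axes
maximize everything else (i.e. between-nest, and therefore between-
species, differences). Raw μm values are used — LDA needs no
standardization because the within-scatter whitening absorbs linear
reparameterizations.

Step two averages specimen scores per nest (the *nest centroid*),
computes pairwise Euclidean distances between centroids in the full
retained morphospace, and displays them as an agglomerative dendrogram
(Ward linkage by default). The dendrogram is a visualization of phenetic
distance, not a phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _linkage, to_tree
from scipy.linalg import eigh
from sklearn.covariance import ledoit_wolf_shrinkage

from .io import NestGrouping, SpecimenTable

__all__ = [
    "LDModel",
    "LDScores",
    "Dendrogram",
    "fit_nest_lda",
    "project_scores",
    "nest_centroids",
    "build_dendrogram",
]

EIGENVALUE_TOL = 1e-10


@dataclass
class LDModel:
    trait_order: tuple[str, ...]
    axis_loadings: np.ndarray      # traits × retained axes
    grand_mean: np.ndarray         # trait means of the training table
    group_ids: list[str]
    group_means: np.ndarray        # nests × retained axes (score space)
    eigenvalues: np.ndarray        # non-increasing
    regularization: str

    @property
    def n_axes(self) -> int:
        return self.axis_loadings.shape[1]


@dataclass
class LDScores:
    ids: list[str]
    scores: np.ndarray             # observations × axes

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim == 1:
            self.scores = self.scores[:, None]
        if len(self.ids) != self.scores.shape[0]:
            raise ValueError("score row count must equal observation count")

    def frame(self) -> pd.DataFrame:
        cols = [f"LD{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def _scatter_matrices(X: np.ndarray, labels: np.ndarray):
    groups, inv = np.unique(labels, return_inverse=True)
    g = len(groups)
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = np.empty((g, p))
    for j in range(g):
        sub = X[inv == j]
        means[j] = sub.mean(axis=0)
        dev = sub - means[j]
        Sw += dev.T @ dev
        dm = means[j] - grand
        Sb += len(sub) * np.outer(dm, dm)
    return groups, means, grand, Sw, Sb


def _canonical_signs(A: np.ndarray) -> np.ndarray:
    """Fix each axis so its largest-magnitude loading is positive."""
    for j in range(A.shape[1]):
        if A[np.argmax(np.abs(A[:, j])), j] < 0:
            A[:, j] = -A[:, j]
    return A


def fit_nest_lda(
    table: SpecimenTable,
    grouping: NestGrouping,
    regularization: str | float = "auto",
) -> LDModel:
    """Discriminant axes of the between/within-nest generalized eigenproblem.

    Solves ``Sb a = λ Sw a`` on raw μm traits and retains every axis with
    eigenvalue above ``EIGENVALUE_TOL`` relative to the leading one (at
    most min(#traits, #nests − 1)). The pooled within-nest scatter is
    near-singular when most nests are singletons; ``regularization``
    controls the conditioning of ``Sw``:

    - ``"auto"`` (default): shrink the within-nest *correlation* matrix
      toward the identity with a Ledoit–Wolf-style intensity, but only
      when ``Sw`` is rank-deficient or ill-conditioned. Shrinking toward
      the diagonal (rather than a raw identity) keeps scores invariant
      under per-trait rescaling.
    - ``"none"``: raise on a singular within-scatter, advising shrinkage.
    - a float in (0, 1]: fixed shrinkage intensity.
    """
    if len(grouping) < 2:
        raise ValueError("need at least 2 nest groups for a discriminant analysis")
    X = table.trait_matrix()
    labels = grouping.labels_for(table.specimen_ids)
    groups, means, grand, Sw, Sb = _scatter_matrices(X, labels)
    n, p = X.shape
    g = len(groups)
    dof = max(n - g, 1)
    W = Sw / dof

    d = np.sqrt(np.diag(W))
    zero_var = d <= 0
    d_safe = np.where(zero_var, 1.0, d)
    R = W / np.outer(d_safe, d_safe)

    lam = 0.0
    if isinstance(regularization, (int, float)) and not isinstance(regularization, bool):
        lam = float(regularization)
        if not 0.0 < lam <= 1.0:
            raise ValueError("fixed shrinkage intensity must lie in (0, 1]")
        reg_desc = f"diagonal shrinkage, fixed intensity {lam:g}"
    elif regularization == "none":
        reg_desc = "none"
    elif regularization == "auto":
        eigs = np.linalg.eigvalsh((R + R.T) / 2)
        ill = (n - g) < p or zero_var.any() or eigs[0] < 1e-8 * max(eigs[-1], 1.0)
        if ill:
            resid = (X - means[np.searchsorted(groups, labels)]) / d_safe
            lam = float(np.clip(ledoit_wolf_shrinkage(resid, assume_centered=True), 1e-6, 1.0))
            reg_desc = f"diagonal shrinkage, Ledoit-Wolf intensity {lam:.4g}"
        else:
            reg_desc = "none (within-scatter well-conditioned)"
    else:
        raise ValueError(f"unknown regularization {regularization!r}")

    R_reg = (1.0 - lam) * R + lam * np.eye(p)
    Sw_solve = dof * (R_reg * np.outer(d_safe, d_safe))
    try:
        evals, evecs = eigh((Sb + Sb.T) / 2, (Sw_solve + Sw_solve.T) / 2)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "within-nest scatter is singular; enable shrinkage "
            "(regularization='auto' or a fixed intensity)"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    k_max = min(p, g - 1)
    keep = evals > EIGENVALUE_TOL * max(evals[0], 1.0)
    keep[k_max:] = False
    A = _canonical_signs(evecs[:, keep].copy())
    group_scores = (means - grand) @ A
    return LDModel(
        trait_order=table.trait_codes,
        axis_loadings=A,
        grand_mean=grand,
        group_ids=[str(gid) for gid in groups],
        group_means=group_scores,
        eigenvalues=evals[keep],
        regularization=reg_desc,
    )


def project_scores(model: LDModel, table: SpecimenTable) -> LDScores:
    """Map specimens into the discriminant morphospace of ``model``."""
    if table.trait_codes != model.trait_order:
        raise ValueError("table traits do not match the model's trait order")
    X = table.trait_matrix()
    return LDScores(table.specimen_ids, (X - model.grand_mean) @ model.axis_loadings)


def nest_centroids(scores: LDScores, grouping: NestGrouping) -> LDScores:
    """Arithmetic mean of member scores, one row per nest."""
    index = {sid: i for i, sid in enumerate(scores.ids)}
    ids, rows = [], []
    for nest, members in grouping.groups.items():
        try:
            idx = [index[m] for m in members]
        except KeyError as exc:
            raise ValueError(f"specimen {exc} has no score row") from exc
        ids.append(nest)
        rows.append(scores.scores[idx].mean(axis=0))
    return LDScores(ids, np.vstack(rows))


@dataclass
class Dendrogram:
    leaves: list[str]              # observation ids, input order
    labels: list[str]              # display labels, same order
    merges: np.ndarray             # scipy linkage matrix, (n-1) × 4
    linkage_method: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def newick(self) -> str:
        """Newick string with branch lengths derived from merge heights.

        Read as an ultrametric display tree: leaves sit at height 0, an
        internal node at its merge height, and each branch length is the
        parent height minus the child height.
        """
        root = to_tree(self.merges)

        def height(node):
            return 0.0 if node.is_leaf() else float(node.dist)

        def rec(node, parent_height):
            bl = parent_height - height(node)
            if node.is_leaf():
                name = self.labels[node.id].replace(" ", "_").replace(",", "_")
                return f"{name}:{bl:.10g}"
            left = rec(node.left, height(node))
            right = rec(node.right, height(node))
            return f"({left},{right}):{bl:.10g}"

        h = height(root)
        return f"({rec(root.left, h)},{rec(root.right, h)});"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        )


def build_dendrogram(
    centroids: LDScores,
    linkage_method: str = "ward",
    label_map: dict[str, str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of centroid scores (Euclidean distances)."""
    if len(centroids.ids) < 2:
        raise ValueError("need at least 2 observations to build a dendrogram")
    Z = _linkage(centroids.scores, method=linkage_method)
    labels = [
        (label_map or {}).get(i, str(i)) for i in centroids.ids
    ]
    return Dendrogram(list(centroids.ids), labels, Z, linkage_method)
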