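"""Multivariate ratio analysis: isometric size, shape, best diagnostic ratios.

On the log scale a trait ratio is a difference, and overall (isometric)
body size is the component along the unit diagonal of log-trait space.
This module decomposes log-trait vectors into that isometric size axis
and its orthogonal complement ("shape"), and implements the ratio
extractor: an exhaustive scan of all ordered trait pairs scoring how
well each log-ratio separates two (or more) taxa, so that the single
most diagnostic ratio can go into an identification key with an explicit
threshold and error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .io import SpecimenTable

__all__ = [
    "RatioCandidate",
    "MRAResult",
    "isosize",
    "shape_projection",
    "lda_ratio_extract",
    "optimal_threshold",
]


def isosize(table: SpecimenTable) -> pd.Series:
    """Isometric size per specimen: the mean of its log trait values.

    This is the projection onto the isometric axis (unit diagonal) up to
    the constant factor 1/sqrt(p), which is irrelevant for ordering and
    group contrasts. Scaling every trait of a specimen by f adds log f.
    """
    X = table.trait_matrix()
    if (X <= 0).any():
        raise ValueError("isometric size requires strictly positive traits")
    return pd.Series(np.log(X).mean(axis=1), index=table.specimen_ids, name="isosize")


def shape_projection(table: SpecimenTable, n_components: int | None = None) -> pd.DataFrame:
    """Shape scores: principal components orthogonal to isometric size.

    Log traits are column-centered and projected onto the orthogonal
    complement of the isometric axis; the principal components of that
    projection are returned (specimens × components). By construction
    every component has zero covariance with isometric size.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 specimens for shape analysis")
    X = table.trait_matrix()
    if (X <= 0).any():
        raise ValueError("shape analysis requires strictly positive traits")
    L = np.log(X)
    L = L - L.mean(axis=0)
    p = L.shape[1]
    u = np.full(p, 1.0 / np.sqrt(p))
    shape = L - np.outer(L @ u, u)
    # principal components of the size-free residual
    _, s, Vt = np.linalg.svd(shape, full_matrices=False)
    k = n_components or max(min(shape.shape) - 1, 1)
    scores = shape @ Vt[:k].T
    # canonical sign: largest-magnitude loading positive per component
    for j in range(scores.shape[1]):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"shape{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=table.specimen_ids, columns=cols)


@dataclass(frozen=True)
class RatioCandidate:
    numerator: str
    denominator: str
    score: float               # standardized group separation of the log-ratio
    error: float               # optimal-threshold misclassification fraction
    threshold: float           # decision boundary on the plain ratio scale
    loocv_error: float

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"


@dataclass
class MRAResult:
    candidates: list[RatioCandidate]   # ranked by score desc, ties lexicographic
    groups: tuple
    isosize: pd.Series

    @property
    def best(self) -> RatioCandidate:
        return self.candidates[0]

    @property
    def plotting_pair(self) -> tuple[RatioCandidate, RatioCandidate]:
        return self.candidates[0], self.candidates[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ratio": c.name,
                    "score": c.score,
                    "error": c.error,
                    "loocv_error": c.loocv_error,
                    "threshold": c.threshold,
                }
                for c in self.candidates
            ]
        )


def optimal_threshold(values: np.ndarray, is_first: np.ndarray):
    """Best single-threshold rule for a 1-D two-group variable.

    Returns ``(threshold, error)`` minimizing resubstitution error over
    all mid-point cuts, orienting the rule so the group with the larger
    mean lies above the threshold. Error is in [0, 0.5].
    """
    order = np.argsort(values, kind="stable")
    v, f = values[order], is_first[order]
    n = len(v)
    n1 = int(f.sum())
    n0 = n - n1
    first_high = v[f].mean() >= v[~f].mean()
    # cumulative counts strictly below each cut position i (between i-1, i)
    cum1 = np.concatenate([[0], np.cumsum(f)])
    cum0 = np.concatenate([[0], np.cumsum(~f)])
    errs = (
        cum1 + (n0 - cum0)       # predict "first" above the cut
        if first_high
        else cum0 + (n1 - cum1)  # predict "first" below the cut
    )
    i = int(np.argmin(errs))
    if i == 0:
        cut = v[0] - 1.0
    elif i == n:
        cut = v[-1] + 1.0
    else:
        cut = (v[i - 1] + v[i]) / 2.0
    return float(cut), float(errs[i] / n)


def _two_group_score(r: np.ndarray, is_first: np.ndarray) -> float:
    a, b = r[is_first], r[~is_first]
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled <= 0:
        return np.nan
    return abs(a.mean() - b.mean()) / np.sqrt(pooled)


def _multi_group_score(r: np.ndarray, labels: np.ndarray) -> float:
    groups = np.unique(labels)
    grand = r.mean()
    ssb = sum(
        (labels == g).sum() * (r[labels == g].mean() - grand) ** 2 for g in groups
    )
    ssw = sum(((r[labels == g] - r[labels == g].mean()) ** 2).sum() for g in groups)
    if ssw <= 0:
        return np.nan
    return float(ssb / ssw)


def _loocv_threshold_error(r: np.ndarray, is_first: np.ndarray) -> float:
    n = len(r)
    wrong = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        cut, _ = optimal_threshold(r[mask], is_first[mask])
        first_high = r[mask][is_first[mask]].mean() >= r[mask][~is_first[mask]].mean()
        pred_first = (r[i] > cut) if first_high else (r[i] <= cut)
        wrong += pred_first != bool(is_first[i])
    return wrong / n


def lda_ratio_extract(
    table: SpecimenTable,
    labels,
    top_n: int = 10,
    compute_loocv: bool = True,
) -> MRAResult:
    """Scan all ordered trait pairs for the most diagnostic ratio.

    Two groups: each log-ratio is scored by the standardized group-mean
    difference (pooled-SD units); more groups: by the one-dimensional
    between/within discriminant criterion. The per-candidate error is
    the resubstitution error of the optimal single-threshold rule on the
    ratio scale (a leave-one-out error is reported alongside). Only one
    orientation per unordered pair is kept — the one in which the first
    group has the larger mean log-ratio — so errors are in [0, 0.5].
    Ranking is by score descending, ties broken lexicographically.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != len(table):
        raise ValueError("labels length must match the table")
    groups = tuple(sorted(set(labels)))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    X = table.trait_matrix()
    if (X <= 0).any():
        raise ValueError("ratio analysis requires strictly positive traits")
    L = np.log(X)
    codes = table.trait_codes
    two_group = len(groups) == 2
    is_first = labels == groups[0]

    cands: list[RatioCandidate] = []
    p = len(codes)
    for i in range(p):
        for j in range(i + 1, p):
            r = L[:, i] - L[:, j]   # log(codes[i]/codes[j])
            if two_group:
                score = _two_group_score(r, is_first)
            else:
                score = _multi_group_score(r, labels)
            if not np.isfinite(score):
                warnings.warn(
                    f"degenerate ratio {codes[i]}/{codes[j]} excluded "
                    "(zero pooled variance)"
                )
                continue
            if two_group:
                # orient so the first group has the larger mean log-ratio
                num, den, rr = (
                    (codes[i], codes[j], r)
                    if r[is_first].mean() >= r[~is_first].mean()
                    else (codes[j], codes[i], -r)
                )
                cut, err = optimal_threshold(rr, is_first)
                cands.append(
                    RatioCandidate(num, den, float(score), err, float(np.exp(cut)), np.nan)
                )
            else:
                cands.append(
                    RatioCandidate(codes[i], codes[j], float(score), np.nan, np.nan, np.nan)
                )
    cands.sort(key=lambda c: (-c.score, c.numerator, c.denominator))
    if two_group and compute_loocv:
        code_idx = {c: k for k, c in enumerate(codes)}
        for rank in range(min(top_n, len(cands))):
            c = cands[rank]
            rr = L[:, code_idx[c.numerator]] - L[:, code_idx[c.denominator]]
            cands[rank] = RatioCandidate(
                c.numerator, c.denominator, c.score, c.error, c.threshold,
                _loocv_threshold_error(rr, is_first),
            )
    return MRAResult(cands, groups, isosize(table))
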