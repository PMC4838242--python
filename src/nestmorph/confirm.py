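"""From two engine partitions to a confirmed species hypothesis.

The two partitioning engines (Ward agglomeration and k-means under the
recursive Gap procedure) rarely disagree on well-separated clusters, but
borderline specimens can land in different clusters. Specimens the two
engines classify *congruently* (after optimally matching the two label
sets) become the prior classes; incongruent specimens are *wildcards* —
no prior hypothesis is imposed on them and they are excluded from all
classifier training.

Cluster separability is then confirmed by leave-one-out cross-validated
linear discriminant analysis on raw μm traits: every non-wildcard
specimen is predicted by a model trained on all others. Wildcards are
finally assigned the class with the highest posterior under the full
model. Cluster pairs whose mutual confusion drags per-class success
below a threshold are judged unconfirmed and lumped, mirroring how
over-split clusters are collapsed back into one species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import SpecimenTable
from .part import Partition

__all__ = [
    "SpeciesHypothesis",
    "ClassificationResult",
    "align_partitions",
    "prior_hypothesis",
    "loocv_lda",
    "merge_unconfirmed",
]

WILDCARD = None


@dataclass
class SpeciesHypothesis:
    """Per-specimen prior (None = wildcard) and confirmed final label."""

    prior: dict[str, object]
    final: dict[str, object] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def wildcards(self) -> list[str]:
        return [s for s, lab in self.prior.items() if lab is WILDCARD]

    @property
    def classes(self) -> list:
        seen = []
        for lab in self.prior.values():
            if lab is not WILDCARD and lab not in seen:
                seen.append(lab)
        return seen

    def frame(self) -> pd.DataFrame:
        sids = list(self.prior)
        return pd.DataFrame(
            {
                "specimen_id": sids,
                "prior_label": [
                    "<wildcard>" if self.prior[s] is WILDCARD else self.prior[s]
                    for s in sids
                ],
                "final_label": [self.final.get(s) for s in sids],
                "note": [self.notes.get(s, "") for s in sids],
            }
        )


@dataclass
class ClassificationResult:
    confusion: pd.DataFrame        # true prior × LOOCV-predicted
    per_class: pd.Series           # diagonal / row sum
    overall: float                 # trace / total
    misclassified: list[str]


def align_partitions(p1: Partition, p2: Partition):
    """Optimal label matching between two partitions of the same set.

    Returns ``(bijection, congruent, wildcards)``: the label mapping from
    p1-clusters to p2-clusters maximizing total agreement (solved as an
    assignment problem on the contingency table), the ids on which the
    matched labels agree, and the incongruent rest.
    """
    ids = list(p1.labels)
    if set(ids) != set(p2.labels):
        raise ValueError("partitions cover different observation sets")
    labs1 = sorted(set(p1.labels.values()))
    labs2 = sorted(set(p2.labels.values()))
    cont = np.zeros((len(labs1), len(labs2)))
    i1 = {lab: i for i, lab in enumerate(labs1)}
    i2 = {lab: i for i, lab in enumerate(labs2)}
    for sid in ids:
        cont[i1[p1.labels[sid]], i2[p2.labels[sid]]] += 1
    rows, cols = linear_sum_assignment(cont, maximize=True)
    bijection = {labs1[r]: labs2[c] for r, c in zip(rows, cols)}
    congruent = [
        sid for sid in ids if bijection.get(p1.labels[sid]) == p2.labels[sid]
    ]
    wild = [sid for sid in ids if sid not in set(congruent)]
    return bijection, congruent, wild


def prior_hypothesis(p1: Partition, p2: Partition) -> SpeciesHypothesis:
    """Prior classes from congruent specimens; wildcards elsewhere."""
    _, congruent, wild = align_partitions(p1, p2)
    congruent_set = set(congruent)
    prior = {
        sid: (p1.labels[sid] if sid in congruent_set else WILDCARD)
        for sid in p1.labels
    }
    notes = {sid: "incongruent between engines -> wildcard" for sid in wild}
    return SpeciesHypothesis(prior, notes=notes)


def _lda(X, y, priors: str):
    kwargs = {}
    if priors == "equal":
        classes = np.unique(y)
        kwargs["priors"] = np.full(len(classes), 1.0 / len(classes))
    elif priors != "proportional":
        raise ValueError("priors must be 'proportional' or 'equal'")
    return LinearDiscriminantAnalysis(**kwargs).fit(X, y)


def loocv_lda(
    table: SpecimenTable,
    hypothesis: SpeciesHypothesis,
    priors: str = "proportional",
) -> tuple[ClassificationResult, SpeciesHypothesis]:
    """Confirm prior classes by leave-one-out cross-validated LDA.

    Per-class and overall classification success are computed over
    non-wildcard specimens with their LOOCV predictions. Final labels:
    LOOCV-misclassified specimens keep their prior (the prediction is
    recorded in the notes); wildcards receive the class with the highest
    posterior under the model trained on all non-wildcard specimens.
    """
    sids = table.specimen_ids
    prior = hypothesis.prior
    labeled = [s for s in sids if prior.get(s) is not WILDCARD]
    wild = [s for s in sids if prior.get(s) is WILDCARD]
    classes = sorted({str(prior[s]) for s in labeled})
    if len(classes) < 2:
        raise ValueError("need at least 2 prior classes")
    counts = pd.Series([str(prior[s]) for s in labeled]).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"prior class of size 1: {small.index[0]!r}")

    X = table.trait_matrix()
    row = {s: i for i, s in enumerate(sids)}
    Xl = X[[row[s] for s in labeled]]
    yl = np.array([str(prior[s]) for s in labeled])

    pred = np.empty_like(yl)
    for i in range(len(labeled)):
        mask = np.ones(len(labeled), dtype=bool)
        mask[i] = False
        model = _lda(Xl[mask], yl[mask], priors)
        pred[i] = model.predict(Xl[i][None, :])[0]

    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(yl, pred):
        confusion.loc[t, p] += 1
    diag = np.diag(confusion.to_numpy())
    row_sums = confusion.sum(axis=1).to_numpy()
    per_class = pd.Series(diag / row_sums, index=classes)
    overall = float(diag.sum() / row_sums.sum())
    mis = [s for s, t, p in zip(labeled, yl, pred) if t != p]

    updated = SpeciesHypothesis(dict(prior), notes=dict(hypothesis.notes))
    for s, t, p in zip(labeled, yl, pred):
        updated.final[s] = t
        if t != p:
            updated.notes[s] = (
                updated.notes.get(s, "")
                + f" LOOCV-misclassified as {p!r}, prior retained"
            ).strip()
    if wild:
        full = _lda(Xl, yl, priors)
        Xw = X[[row[s] for s in wild]]
        for s, p in zip(wild, full.predict(Xw)):
            updated.final[s] = p
            updated.notes[s] = (
                updated.notes.get(s, "") + f" assigned {p!r} by LDA posterior"
            ).strip()
    result = ClassificationResult(confusion, per_class, overall, mis)
    return result, updated


def merge_unconfirmed(
    result: ClassificationResult,
    hypothesis: SpeciesHypothesis,
    table: SpecimenTable,
    threshold: float = 0.90,
    priors: str = "proportional",
) -> tuple[ClassificationResult, SpeciesHypothesis]:
    """Lump cluster pairs whose separation the LOOCV does not confirm.

    While any class scores below ``threshold`` and its errors concentrate
    in a single partner class, the pair is merged (label "a+b") and the
    LOOCV is re-run, until every class clears the threshold or only one
    class remains.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    current = hypothesis
    res = result
    while True:
        failing = res.per_class[res.per_class < threshold]
        if failing.empty:
            break
        merged = False
        for cls in failing.sort_values().index:
            errors = res.confusion.loc[cls].drop(cls)
            if errors.sum() == 0:
                continue
            partner = errors.idxmax()
            # concentrated confusion: the partner absorbs the majority of errors
            if errors[partner] / errors.sum() < 0.5:
                continue
            new_label = f"{cls}+{partner}"
            prior = {
                s: (
                    new_label
                    if (lab is not WILDCARD and str(lab) in (cls, partner))
                    else lab
                )
                for s, lab in current.prior.items()
            }
            notes = dict(current.notes)
            for s, lab in current.prior.items():
                if lab is not WILDCARD and str(lab) in (cls, partner):
                    notes[s] = (
                        notes.get(s, "") + f" merged cluster pair {cls}|{partner}"
                    ).strip()
            current = SpeciesHypothesis(prior, notes=notes)
            if len(set(map(str, current.classes))) < 2:
                # nothing left to cross-validate: finalize from the priors,
                # keeping earlier posterior assignments for wildcards
                for s, lab in prior.items():
                    current.final[s] = (
                        lab if lab is not WILDCARD else hypothesis.final.get(s)
                    )
                return res, current
            res, current = loocv_lda(table, current, priors=priors)
            merged = True
            break
        if not merged:
            break
    return res, current
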