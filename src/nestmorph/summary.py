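"""Per-species summary statistics and annotated dendrogram exports.

The summary mirrors the standard layout of morphometric revisions: per
species, absolute cephalic size in μm plus the diagnostic ratio set
(PoOC/CL, CL/CW, CL/CWb and trait/CS for the remaining traits), each as
mean ± SD with min/max. The dendrogram annotation attaches one label
track per partition (e.g. the two engine priors and the final species
hypothesis) to the leaf order of the display tree, which is how
delimitation results are conventionally mapped onto the tree as colored
bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list

from .io import SpecimenTable
from .ncclust import Dendrogram

__all__ = ["SpeciesSummary", "species_summary", "annotate_dendrogram"]

#: Ratios of the standard summary layout, in display order.
SUMMARY_RATIOS = (
    "PoOC/CL", "CL/CW", "CL/CWb", "FRS/CS", "SL/CS", "EL/CS", "MW/CS",
    "PSTI/CS", "PEW/CS", "PPW/CS", "SPBA/CS", "SPTI/CS", "ML/CS",
    "PEL/CS", "NOL/CS", "MPST/CS", "PEH/CS", "NOH/CS", "PPH/CS",
    "SPST/CS", "PPL/CS",
)


@dataclass
class SpeciesSummary:
    """Long-format statistics: one row per species × statistic."""

    stats: pd.DataFrame   # columns: species, statistic, mean, sd, min, max, n

    def display(self) -> pd.DataFrame:
        """Rounded view: ratios to 3 decimals, CS to integer μm."""
        out = self.stats.copy()
        is_cs = out["statistic"] == "CS"
        for col in ("mean", "sd", "min", "max"):
            out.loc[is_cs, col] = out.loc[is_cs, col].round(0)
            out.loc[~is_cs, col] = out.loc[~is_cs, col].round(3)
        return out

    def lookup(self, species: str, statistic: str) -> pd.Series:
        m = (self.stats["species"] == species) & (self.stats["statistic"] == statistic)
        if not m.any():
            raise KeyError((species, statistic))
        return self.stats.loc[m].iloc[0]


def _ratio_values(table: SpecimenTable, name: str) -> pd.Series:
    if name == "CS":
        return table.cs()
    num, den = name.split("/")
    numv = table.cs() if num == "CS" else table.data[num]
    denv = table.cs() if den == "CS" else table.data[den]
    return numv / denv


def species_summary(table: SpecimenTable, labels) -> SpeciesSummary:
    """Per-species mean/SD/min/max/n of CS and the summary ratio set.

    ``labels`` is one label per specimen (row order); specimens with a
    missing label are excluded with a warning. SD is the sample (n − 1)
    standard deviation; single-specimen species report SD = 0.
    """
    labels = pd.Series(list(labels), index=table.data.index, dtype=object)
    unlabeled = labels.isna() | (labels.astype(str).str.len() == 0)
    if unlabeled.any():
        warnings.warn(f"{int(unlabeled.sum())} unlabeled specimens excluded")
    rows = []
    for name in ("CS",) + SUMMARY_RATIOS:
        values = _ratio_values(table, name)
        for sp in sorted(labels[~unlabeled].astype(str).unique()):
            v = values[(~unlabeled) & (labels.astype(str) == sp)]
            rows.append(
                {
                    "species": sp,
                    "statistic": name,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                    "min": float(v.min()),
                    "max": float(v.max()),
                    "n": int(len(v)),
                }
            )
    return SpeciesSummary(pd.DataFrame(rows))


@dataclass
class AnnotatedDendrogram:
    dendrogram: Dendrogram
    tracks: pd.DataFrame   # index: leaf ids in display order; one col/partition

    def newick(self) -> str:
        return self.dendrogram.newick()

    def merge_table(self) -> pd.DataFrame:
        return self.dendrogram.merge_table()


def annotate_dendrogram(
    dendrogram: Dendrogram, partitions: dict[str, dict[str, object]]
) -> AnnotatedDendrogram:
    """Attach one label track per partition, aligned to display leaf order.

    ``partitions`` maps a track name (e.g. ``part-hclust``, ``part-kmeans``,
    ``final``) to a leaf-id → label mapping covering every leaf.
    """
    order = leaves_list(dendrogram.merges)
    leaf_ids = [dendrogram.leaves[i] for i in order]
    data = {}
    for name, mapping in partitions.items():
        missing = [l for l in leaf_ids if l not in mapping]
        if missing:
            raise ValueError(f"track {name!r}: leaf {missing[0]!r} has no label")
        data[name] = [mapping[l] for l in leaf_ids]
    return AnnotatedDendrogram(dendrogram, pd.DataFrame(data, index=leaf_ids))
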