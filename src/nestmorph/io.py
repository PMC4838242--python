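"""Reading, validating and grouping specimen-level morphometric tables.

The on-disk dialect is a UTF-8 comma-separated table with metadata columns
``casent`` (unique specimen identifier), ``species`` (may be empty for
undetermined material), ``long``, ``lat``, ``dendro-name``, followed by
the 22 trait columns in μm. Two optional columns are recognized when
present: ``nest`` (collection code grouping specimens from one nest) and
``alt`` (elevation in m a.s.l.); any further columns are carried along
untouched.

Nest identity drives the whole downstream analysis: individuals collected
from the same nest are assumed closely related (often sisters) and are
used as the grouping unit of the discriminant analysis. When no ``nest``
column is present the specimen identifier is used (specimens sharing a
pin code share a nest; otherwise each specimen is a singleton nest).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import DEFAULT_REGISTRY, METADATA_COLUMNS, TraitRegistry, derive_cs

__all__ = [
    "SpecimenTable",
    "NestGrouping",
    "read_specimen_table",
    "write_specimen_table",
    "group_by_nest",
    "icc_repeatability",
    "screen_trait_correlations",
]


@dataclass
class SpecimenTable:
    """Validated specimen-by-trait table.

    ``data`` holds one row per specimen, indexed by position, with columns
    ``specimen_id``, ``nest_id``, ``species`` (may be NA), ``longitude``,
    ``latitude``, ``elevation_m`` (may be NA), ``dendro_name`` plus the
    trait columns of ``registry`` in canonical order.
    """

    data: pd.DataFrame
    registry: TraitRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.data)

    @property
    def trait_codes(self) -> tuple[str, ...]:
        return self.registry.codes

    def trait_matrix(self) -> np.ndarray:
        """Specimens × traits matrix of raw μm values."""
        return self.data.loc[:, list(self.trait_codes)].to_numpy(dtype=float)

    def cs(self) -> pd.Series:
        """Absolute cephalic size per specimen (mean of CL and CWb)."""
        return (self.data["CL"] + self.data["CWb"]) / 2.0

    @property
    def specimen_ids(self) -> list[str]:
        return self.data["specimen_id"].tolist()

    def subset(self, mask) -> "SpecimenTable":
        return SpecimenTable(
            self.data.loc[mask].reset_index(drop=True),
            registry=self.registry,
            provenance=self.provenance + " [subset]",
        )


@dataclass(frozen=True)
class NestGrouping:
    """Partition of the specimen set into nest samples."""

    groups: dict[str, list[str]]

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def n_specimens(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def labels_for(self, specimen_ids) -> np.ndarray:
        lookup = {s: nest for nest, members in self.groups.items() for s in members}
        return np.array([lookup[s] for s in specimen_ids])


def _validate_frame(df: pd.DataFrame, registry: TraitRegistry, source: str) -> None:
    for code in registry.codes:
        if code not in df.columns:
            raise ValueError(f"{source}: missing trait column {code!r}")
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise ValueError(f"{source}: duplicate specimen_id {dup!r}")
    def exact_float(v):
        try:
            return float(v)  # exact round-trip parse
        except (TypeError, ValueError):
            return np.nan

    for code in registry.codes:
        col = df[code].map(exact_float)
        bad = col.isna() | (col <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{source}: non-numeric or non-positive value in column "
                f"{code!r}, row {row} (specimen "
                f"{df['specimen_id'].iloc[row]!r})"
            )
        df[code] = col


def read_specimen_table(
    path, registry: TraitRegistry | None = None
) -> SpecimenTable:
    """Read and validate a specimen CSV in the standard dialect.

    Raises ``ValueError`` naming the offending column/row on a missing
    trait column, a non-numeric or non-positive trait value, or a
    duplicated specimen identifier.
    """
    registry = registry or DEFAULT_REGISTRY
    src = str(path)
    if isinstance(path, (str, Path)):
        raw = pd.read_csv(path, dtype=str)
    else:  # file-like
        raw = pd.read_csv(path, dtype=str)
        src = "<stream>"
    raw.columns = [c.strip() for c in raw.columns]
    if "casent" not in raw.columns:
        raise ValueError(f"{src}: missing identifier column 'casent'")

    df = pd.DataFrame()
    df["specimen_id"] = raw["casent"].astype(str)
    if "nest" in raw.columns:
        nest = raw["nest"].astype(str)
        nest = nest.where(nest.str.len() > 0, df["specimen_id"])
    else:
        nest = df["specimen_id"]
    df["nest_id"] = nest
    df["species"] = raw["species"] if "species" in raw.columns else pd.NA
    for out, col in (("longitude", "long"), ("latitude", "lat")):
        df[out] = pd.to_numeric(raw[col], errors="coerce") if col in raw.columns else np.nan
    df["elevation_m"] = (
        pd.to_numeric(raw["alt"], errors="coerce") if "alt" in raw.columns else np.nan
    )
    df["dendro_name"] = raw["dendro-name"] if "dendro-name" in raw.columns else pd.NA
    for code in registry.codes:
        if code in raw.columns:
            df[code] = raw[code]
    known = set(METADATA_COLUMNS) | set(registry.codes) | {"nest", "alt"}
    for col in raw.columns:
        if col not in known:
            df[f"extra:{col}"] = raw[col]
    _validate_frame(df, registry, src)
    return SpecimenTable(df, registry=registry, provenance=src)


def write_specimen_table(table: SpecimenTable, path) -> None:
    """Write a table back to the standard CSV dialect (lossless roundtrip)."""
    out = pd.DataFrame()
    out["casent"] = table.data["specimen_id"]
    out["species"] = table.data["species"]
    out["long"] = table.data["longitude"]
    out["lat"] = table.data["latitude"]
    out["dendro-name"] = table.data["dendro_name"]
    out["nest"] = table.data["nest_id"]
    out["alt"] = table.data["elevation_m"]
    for code in table.trait_codes:
        # shortest-roundtrip float formatting is bit-exact on re-read
        out[code] = table.data[code].map(lambda v: repr(float(v)))
    for col in table.data.columns:
        if col.startswith("extra:"):
            out[col[len("extra:"):]] = table.data[col]
    if isinstance(path, (str, Path)):
        out.to_csv(path, index=False)
    else:
        out.to_csv(path, index=False)


def table_to_csv_text(table: SpecimenTable) -> str:
    buf = _io.StringIO()
    write_specimen_table(table, buf)
    return buf.getvalue()


def group_by_nest(table: SpecimenTable) -> NestGrouping:
    """Group specimens into nest samples by their ``nest_id``."""
    if len(table) == 0:
        raise ValueError("cannot group an empty table")
    groups: dict[str, list[str]] = {}
    for sid, nid in zip(table.data["specimen_id"], table.data["nest_id"]):
        groups.setdefault(str(nid), []).append(str(sid))
    return NestGrouping(groups)


def icc_repeatability(first, second) -> float:
    """Average-measure intraclass correlation of a double measurement.

    Two-way random-effects, average-measure form computed from the ANOVA
    mean squares of the specimen × session table: with row (specimen)
    mean square MSR, column (session) mean square MSC and residual MSE,

        ICC = (MSR - MSE) / (MSR + (MSC - MSE) / n).

    Negative estimates are clamped to 0; the result is capped at 1.
    """
    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired measurement vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 specimens for a repeatability estimate")
    data = np.column_stack([x, y])
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: repeatability undefined")
    k = 2
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if denom <= 0:
        return 0.0
    return float(min(1.0, max(0.0, (msr - mse) / denom)))


@dataclass(frozen=True)
class CorrelationReport:
    """Advisory error-variance screen: per-trait max |Pearson r|."""

    max_abs_r: pd.Series       # index: trait codes; NaN for constant columns
    flagged: tuple[str, ...]   # traits whose max |r| falls below threshold
    undefined: tuple[str, ...] # constant traits (correlation undefined)
    threshold: float


def screen_trait_correlations(
    table: SpecimenTable, threshold: float = 0.5
) -> CorrelationReport:
    """Screen traits for error variance via pairwise Pearson correlation.

    A trait whose absolute correlation with every other trait stays below
    ``threshold`` lacks the positive within-class correlation expected of
    a size-linked character, which may indicate poor repeatability or a
    morphological artifact. The report is advisory: no rows are dropped.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 specimens to screen correlations")
    traits = table.data.loc[:, list(table.trait_codes)].astype(float)
    constant = tuple(c for c in table.trait_codes if traits[c].nunique() == 1)
    corr = traits.corr()  # pandas yields NaN for constant columns
    np.fill_diagonal(corr.values, np.nan)
    max_abs = corr.abs().max(axis=0)
    flagged = tuple(
        c for c in table.trait_codes
        if c not in constant and max_abs[c] < threshold
    )
    return CorrelationReport(max_abs, flagged, constant, threshold)
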