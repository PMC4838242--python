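"""Registry of the 22 continuous morphometric traits of the worker caste.

All traits are linear distances recorded in μm under a stereomicroscope.
``CS`` (absolute cephalic size, the arithmetic mean of ``CL`` and ``CWb``)
is a derived quantity, never a measured column; it is the denominator of
most diagnostic ratios and is computed on demand by :func:`derive_cs`.

The per-trait repeatability values stored here are published reference
points (average-measure intraclass correlations from a double-measurement
trial on 14 specimens); the raw repeated measurements are not deposited,
so these numbers are metadata, not reproducible targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Canonical column order for the 22 measured traits.
TRAIT_CODES: tuple[str, ...] = (
    "CL", "CW", "CWb", "PoOC", "SL", "EL", "FRS", "MW", "PSTI", "PEW",
    "PPW", "SPBA", "SPTI", "ML", "MPST", "NOH", "NOL", "PPL", "SPST",
    "PEH", "PEL", "PPH",
)

_DESCRIPTIONS: dict[str, str] = {
    "CL": "maximum cephalic length in median line",
    "CW": "maximum head width including compound eyes",
    "CWb": "maximum head capsule width excluding compound eyes",
    "PoOC": "postocular distance",
    "SL": "maximum straight-line scape length",
    "EL": "maximum compound-eye diameter",
    "FRS": "frontal carina distance",
    "MW": "mesosoma (pronotum) width",
    "PSTI": "apical distance of pronotal spines",
    "PEW": "maximum petiole width in dorsal view",
    "PPW": "maximum postpetiole width in dorsal view",
    "SPBA": "minimum propodeal spine distance at base",
    "SPTI": "apical propodeal spine distance",
    "ML": "mesosoma length (Weber's length)",
    "MPST": "propodeal spiracle to metapleural corner distance",
    "NOH": "maximum petiolar node height",
    "NOL": "petiolar node length",
    "PPL": "postpetiole length",
    "SPST": "propodeal spine length from spiracle center",
    "PEH": "maximum petiole height",
    "PEL": "diagonal petiole length in lateral view",
    "PPH": "maximum postpetiole height",
}

#: Published average-measure ICC repeatability per trait (reference only).
_REPEATABILITY: dict[str, float] = {
    "CL": 0.998, "CW": 0.999, "CWb": 0.998, "PoOC": 0.997, "SL": 0.998,
    "EL": 0.929, "FRS": 0.982, "MW": 0.998, "PSTI": 0.994, "PEW": 0.996,
    "PPW": 0.994, "SPBA": 0.993, "SPTI": 0.994, "ML": 0.998, "MPST": 0.989,
    "NOH": 0.958, "NOL": 0.981, "PPL": 0.975, "SPST": 0.994, "PEH": 0.989,
    "PEL": 0.991, "PPH": 0.991,
}

#: Metadata columns of the specimen-table CSV dialect, in order.
METADATA_COLUMNS: tuple[str, ...] = ("casent", "species", "long", "lat", "dendro-name")


@dataclass(frozen=True)
class TraitEntry:
    code: str
    description: str
    repeatability_R: float | None = None


@dataclass(frozen=True)
class TraitRegistry:
    """Ordered registry of measured trait codes.

    The default registry holds the canonical 22 codes; custom registries
    (e.g. for simulations on a trait subset) keep the same interface.
    """

    entries: tuple[TraitEntry, ...] = field(
        default_factory=lambda: tuple(
            TraitEntry(c, _DESCRIPTIONS[c], _REPEATABILITY.get(c)) for c in TRAIT_CODES
        )
    )

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("trait codes must be unique")
        if "CS" in codes:
            raise ValueError("CS is derived, never a measured trait")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.codes


DEFAULT_REGISTRY = TraitRegistry()


def derive_cs(traits) -> float:
    """Absolute cephalic size: the arithmetic mean of CL and CWb.

    ``traits`` is any mapping with ``CL`` and ``CWb`` keys (a dict, a
    pandas row, ...). Symmetric in its two operands.
    """
    try:
        cl = traits["CL"]
        cwb = traits["CWb"]
    except KeyError as exc:  # pragma: no cover - message detail
        raise ValueError(f"cannot derive CS: missing operand {exc}") from exc
    if cl is None or cwb is None:
        raise ValueError("cannot derive CS: missing operand")
    return (cl + cwb) / 2.0
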