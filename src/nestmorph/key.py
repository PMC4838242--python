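"""Dichotomous identification key for the *sikorai*-group worker caste.

The published key separates the eight species in seven couplets, each
decided by a morphometric ratio threshold; sculpture/color characters
and an elevation band accompany some couplets as corroborating field
evidence. This engine walks the couplet tree evaluating the quantitative
predicates; qualitative and elevation predicates are consulted only when
the caller provides them, and a disagreement with the quantitative arm
is reported as a warning, never an override — only the ratios are
machine-checkable from a measurement table.

Tie policy at a printed threshold: where the published wording is
non-strict the tie follows it (PSTI/SPTI ≤ 2.5 keys to *sikorai*);
where both arms are printed strict or ambiguous (0.73 in couplet 1,
1.84 in couplet 7) a tie routes to the second arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .io import SpecimenTable

__all__ = [
    "RatioPredicate",
    "KeyArm",
    "KeyCouplet",
    "KeyResult",
    "build_sikorai_key",
    "apply_key",
    "key_consistency",
    "key_to_text",
    "key_from_text",
]

_OPS = {
    "<": lambda v, t: v < t,
    ">": lambda v, t: v > t,
    "<=": lambda v, t: v <= t,
    ">=": lambda v, t: v >= t,
}


@dataclass(frozen=True)
class RatioPredicate:
    ratio: str            # e.g. "SL/CS"; CS is derived as (CL + CWb)/2
    op: str               # one of <, >, <=, >=
    threshold: float

    def value(self, traits) -> float:
        num, den = self.ratio.split("/")

        def get(code):
            if code == "CS":
                return (traits["CL"] + traits["CWb"]) / 2.0
            return traits[code]

        try:
            return float(get(num)) / float(get(den))
        except KeyError as exc:
            raise ValueError(f"ratio {self.ratio} not computable: missing {exc}") from exc

    def holds(self, traits) -> bool:
        return _OPS[self.op](self.value(traits), self.threshold)

    def __str__(self) -> str:
        return f"{self.ratio} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class KeyArm:
    quantitative: tuple[RatioPredicate, ...]   # first entry is decisive
    outcome: int | str                         # next couplet id or species
    qualitative: tuple[tuple[str, str], ...] = ()
    elevation: tuple[str, float] | None = None  # (op, meters), advisory


@dataclass(frozen=True)
class KeyCouplet:
    id: int
    arms: tuple[KeyArm, KeyArm]


@dataclass
class KeyResult:
    species: str
    path: list[tuple[int, int]]                 # (couplet id, arm index)
    evaluated: list[tuple[int, str, float, bool]]  # couplet, predicate, value, holds
    warnings: list[str] = field(default_factory=list)


def build_sikorai_key() -> list[KeyCouplet]:
    """The published seven-couplet key, thresholds verbatim."""
    q = RatioPredicate
    return [
        KeyCouplet(1, (
            KeyArm((q("SL/CS", "<", 0.73), q("NOL/CS", "<", 0.3)), "reticulatus"),
            KeyArm((q("SL/CS", ">=", 0.73), q("NOL/CS", ">=", 0.3)), 2),
        )),
        KeyCouplet(2, (
            KeyArm((q("SPST/CS", ">", 0.36),), 3),
            KeyArm((q("SPST/CS", "<=", 0.36),), 4),
        )),
        KeyCouplet(3, (
            KeyArm((q("PoOC/CL", ">", 0.455),), "retusispinosus",
                   qualitative=(("vertex_sculpture", "rugose"),)),
            KeyArm((q("PoOC/CL", "<=", 0.455),), "tamatavensis",
                   qualitative=(("vertex_sculpture", "smooth"),)),
        )),
        KeyCouplet(4, (
            KeyArm((q("CW/ML", ">", 0.73),), 5,
                   qualitative=(("body_color", "black"),
                                ("eye_protrusion", "protuberant"))),
            KeyArm((q("CW/ML", "<=", 0.73),), 7,
                   qualitative=(("body_color", "yellow_to_brown"),
                                ("eye_protrusion", "non_protuberant"))),
        )),
        KeyCouplet(5, (
            KeyArm((q("CL/CW", ">", 1.09),), "modestus",
                   qualitative=(("vertex_main_sculpture", "inconspicuous"),)),
            KeyArm((q("CL/CW", "<=", 1.09),), 6,
                   qualitative=(("vertex_main_sculpture", "coarse"),)),
        )),
        KeyCouplet(6, (
            KeyArm((q("PSTI/SPTI", "<=", 2.5),), "sikorai",
                   qualitative=(("vertex_main_sculpture", "areolate"),
                                ("petiole_dorsum", "dull"))),
            KeyArm((q("PSTI/SPTI", ">", 2.5),), "striatus",
                   qualitative=(("vertex_main_sculpture", "costate"),
                                ("petiole_dorsum", "smooth"))),
        )),
        KeyCouplet(7, (
            KeyArm((q("PSTI/PPW", "<", 1.84),), "excelsior",
                   elevation=(">", 500.0)),
            KeyArm((q("PSTI/PPW", ">=", 1.84),), "rugosus",
                   elevation=("<", 500.0)),
        )),
    ]


def apply_key(
    traits,
    key: list[KeyCouplet] | None = None,
    qualitative: dict[str, str] | None = None,
    elevation_m: float | None = None,
) -> KeyResult:
    """Walk the key for one specimen's trait mapping.

    ``traits`` is any mapping of trait code → μm value covering the
    ratios along the taken path. Terminates at a species leaf in at most
    as many steps as there are couplets.
    """
    key = key or build_sikorai_key()
    couplets = {c.id: c for c in key}
    result = KeyResult("", [], [])
    node: int | str = key[0].id
    for _ in range(len(key) + 1):
        if isinstance(node, str):
            result.species = node
            return result
        couplet = couplets[node]
        try:
            decisive = couplet.arms[0].quantitative[0]
            value = decisive.value(traits)
        except ValueError as exc:
            raise ValueError(f"couplet {couplet.id}: {exc}") from exc
        take = 0 if decisive.holds(traits) else 1
        arm = couplet.arms[take]
        result.path.append((couplet.id, take))
        result.evaluated.append((couplet.id, str(decisive), value, take == 0))
        # secondary quantitative predicates of the chosen arm are advisory
        for pred in arm.quantitative[1:]:
            try:
                v = pred.value(traits)
            except ValueError:
                result.warnings.append(
                    f"couplet {couplet.id}: secondary predicate {pred} skipped "
                    "(missing data)"
                )
                continue
            ok = pred.holds(traits)
            result.evaluated.append((couplet.id, str(pred), v, ok))
            if not ok:
                result.warnings.append(
                    f"couplet {couplet.id}: secondary predicate {pred} "
                    f"disagrees (value {v:.3f})"
                )
        if qualitative:
            for char, expected in arm.qualitative:
                got = qualitative.get(char)
                if got is not None and got != expected:
                    result.warnings.append(
                        f"couplet {couplet.id}: qualitative character "
                        f"{char}={got!r} disagrees with expected {expected!r}"
                    )
        if elevation_m is not None and arm.elevation is not None:
            op, thr = arm.elevation
            if not _OPS[op](elevation_m, thr):
                result.warnings.append(
                    f"couplet {couplet.id}: elevation {elevation_m:.0f} m "
                    f"disagrees with expected {op} {thr:.0f} m"
                )
        node = arm.outcome
    raise RuntimeError("key did not terminate (cyclic outcomes?)")


def key_consistency(
    table: SpecimenTable,
    labels,
    key: list[KeyCouplet] | None = None,
) -> pd.DataFrame:
    """Per-species agreement between key outcome and assigned label.

    One row per species with the fraction of its specimens keying to it;
    mismatching specimens are listed with their couplet paths.
    """
    key = key or build_sikorai_key()
    labels = [str(l) for l in labels]
    rows = []
    for sid, lab, (_, rec) in zip(
        table.specimen_ids, labels, table.data.iterrows()
    ):
        elev = rec.get("elevation_m")
        res = apply_key(
            rec,
            key,
            elevation_m=None if pd.isna(elev) else float(elev),
        )
        rows.append((sid, lab, res.species, res.path))
    out = []
    for sp in sorted(set(labels)):
        sub = [r for r in rows if r[1] == sp]
        agree = [r for r in sub if r[2] == sp]
        mism = [
            {"specimen_id": r[0], "keyed_as": r[2], "path": r[3]}
            for r in sub
            if r[2] != sp
        ]
        out.append(
            {
                "species": sp,
                "n": len(sub),
                "agreement": len(agree) / len(sub) if sub else float("nan"),
                "mismatches": mism,
            }
        )
    return pd.DataFrame(out)


def key_to_text(key: list[KeyCouplet]) -> str:
    """Serialize a key as structured text (JSON) for external editing."""
    payload = [
        {
            "id": c.id,
            "arms": [
                {
                    "quantitative": [
                        {"ratio": p.ratio, "op": p.op, "threshold": p.threshold}
                        for p in arm.quantitative
                    ],
                    "qualitative": [list(qv) for qv in arm.qualitative],
                    "elevation": list(arm.elevation) if arm.elevation else None,
                    "outcome": arm.outcome,
                }
                for arm in c.arms
            ],
        }
        for c in key
    ]
    return json.dumps(payload, indent=2)


def key_from_text(text: str) -> list[KeyCouplet]:
    payload = json.loads(text)
    out = []
    for c in payload:
        arms = tuple(
            KeyArm(
                quantitative=tuple(
                    RatioPredicate(p["ratio"], p["op"], float(p["threshold"]))
                    for p in arm["quantitative"]
                ),
                outcome=arm["outcome"],
                qualitative=tuple(tuple(qv) for qv in arm.get("qualitative", [])),
                elevation=tuple(arm["elevation"]) if arm.get("elevation") else None,
            )
            for arm in c["arms"]
        )
        out.append(KeyCouplet(int(c["id"]), arms))  # type: ignore[arg-type]
    return out
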