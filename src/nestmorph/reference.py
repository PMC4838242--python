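"""Published per-species reference statistics for the *sikorai* group.

Eight species, each summarized by absolute cephalic size (CS, μm) and the
standard ratio set (mostly trait/CS, plus PoOC/CL, CL/CW, CL/CWb) as
printed in the revision's summary table. These means parameterize the
study-like default of the synthetic generator and let the key engine be
exercised on each species' typical morphology without the raw data.

``SPECIES_N`` / ``SPECIES_NESTS`` are the published per-species specimen
and nest-sample counts (227 individuals in total).
"""

from __future__ import annotations

import math

import numpy as np

from .registry import TRAIT_CODES

SPECIES = (
    "excelsior", "modestus", "reticulatus", "retusispinosus",
    "rugosus", "sikorai", "striatus", "tamatavensis",
)

SPECIES_N = {
    "excelsior": 83, "modestus": 18, "reticulatus": 7, "retusispinosus": 9,
    "rugosus": 24, "sikorai": 36, "striatus": 9, "tamatavensis": 41,
}

SPECIES_NESTS = {
    "excelsior": 58, "modestus": 18, "reticulatus": 7, "retusispinosus": 9,
    "rugosus": 23, "sikorai": 28, "striatus": 9, "tamatavensis": 32,
}

#: Mean CS in μm per species.
CS_MEAN = {
    "excelsior": 736.0, "modestus": 796.0, "reticulatus": 511.0,
    "retusispinosus": 812.0, "rugosus": 732.0, "sikorai": 822.0,
    "striatus": 842.0, "tamatavensis": 699.0,
}

#: Ratio means per species, keyed by the ratio name used in the summary table.
#: Order of values follows SPECIES.
RATIO_MEANS: dict[str, tuple[float, ...]] = {
    "PoOC/CL":  (0.458, 0.453, 0.462, 0.483, 0.473, 0.488, 0.460, 0.433),
    "CL/CW":    (1.169, 1.131, 1.105, 1.089, 1.155, 1.041, 1.048, 1.107),
    "CL/CWb":   (1.271, 1.216, 1.151, 1.170, 1.237, 1.169, 1.155, 1.155),
    "FRS/CS":   (0.291, 0.295, 0.320, 0.294, 0.289, 0.292, 0.288, 0.329),
    "SL/CS":    (0.822, 0.771, 0.704, 0.838, 0.811, 0.828, 0.794, 0.798),
    "EL/CS":    (0.230, 0.234, 0.241, 0.237, 0.228, 0.212, 0.219, 0.258),
    "MW/CS":    (0.625, 0.647, 0.639, 0.679, 0.639, 0.675, 0.671, 0.705),
    "PSTI/CS":  (0.611, 0.657, 0.629, 0.659, 0.648, 0.665, 0.666, 0.739),
    "PEW/CS":   (0.231, 0.223, 0.235, 0.240, 0.236, 0.269, 0.243, 0.243),
    "PPW/CS":   (0.354, 0.341, 0.370, 0.390, 0.335, 0.370, 0.362, 0.363),
    "SPBA/CS":  (0.225, 0.236, 0.254, 0.240, 0.218, 0.253, 0.242, 0.244),
    "SPTI/CS":  (0.252, 0.251, 0.266, 0.322, 0.261, 0.299, 0.244, 0.303),
    "ML/CS":    (1.379, 1.308, 1.252, 1.362, 1.346, 1.352, 1.379, 1.422),
    "PEL/CS":   (0.528, 0.499, 0.441, 0.543, 0.511, 0.516, 0.513, 0.544),
    "NOL/CS":   (0.357, 0.332, 0.266, 0.352, 0.340, 0.361, 0.339, 0.369),
    "MPST/CS":  (0.419, 0.404, 0.391, 0.420, 0.409, 0.423, 0.416, 0.427),
    "PEH/CS":   (0.296, 0.309, 0.327, 0.319, 0.297, 0.306, 0.304, 0.312),
    "NOH/CS":   (0.172, 0.179, 0.132, 0.185, 0.173, 0.173, 0.173, 0.181),
    "PPH/CS":   (0.272, 0.297, 0.280, 0.271, 0.268, 0.271, 0.288, 0.267),
    "SPST/CS":  (0.279, 0.236, 0.233, 0.430, 0.287, 0.269, 0.241, 0.388),
    "PPL/CS":   (0.253, 0.235, 0.246, 0.263, 0.235, 0.239, 0.241, 0.246),
}

#: Typical elevation (m a.s.l.) per species, midpoint of the published
#: occurrence band; used only as the advisory covariate in simulations.
SPECIES_ELEVATION_M = {
    "excelsior": 1007.0, "modestus": 514.0, "reticulatus": 94.0,
    "retusispinosus": 1000.0, "rugosus": 390.0, "sikorai": 360.0,
    "striatus": 1054.0, "tamatavensis": 600.0,
}


def species_mean_traits(species: str) -> dict[str, float]:
    """Reconstruct the full 22-trait mean vector (μm) of one species.

    Inverts the summary-table parameterization: CS and CL/CWb give CL and
    CWb (CS is their arithmetic mean), CL/CW gives CW, PoOC/CL gives
    PoOC, and every remaining trait is its trait/CS ratio times CS.
    """
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}")
    i = SPECIES.index(species)
    cs = CS_MEAN[species]
    r_cl_cwb = RATIO_MEANS["CL/CWb"][i]
    cwb = 2.0 * cs / (1.0 + r_cl_cwb)
    cl = r_cl_cwb * cwb
    traits = {
        "CL": cl,
        "CWb": cwb,
        "CW": cl / RATIO_MEANS["CL/CW"][i],
        "PoOC": cl * RATIO_MEANS["PoOC/CL"][i],
    }
    for code in TRAIT_CODES:
        if code in traits:
            continue
        traits[code] = cs * RATIO_MEANS[f"{code}/CS"][i]
    return {code: traits[code] for code in TRAIT_CODES}


def species_mean_log_traits() -> np.ndarray:
    """Log-scale species-by-trait mean matrix (8 × 22), SPECIES order."""
    return np.array(
        [[math.log(v) for v in species_mean_traits(s).values()] for s in SPECIES]
    )
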