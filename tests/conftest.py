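import numpy as np
import pandas as pd
import pytest

from nestmorph.io import SpecimenTable
from nestmorph.registry import DEFAULT_REGISTRY, TRAIT_CODES, TraitEntry, TraitRegistry
from nestmorph.simulate import (
    SimulationConfig,
    simulate_dataset,
    study_like_config,
    tight_study_config,
)


def make_table(traits: np.ndarray, nests=None, species=None, ids=None) -> SpecimenTable:
    """Build a SpecimenTable straight from a traits matrix (n × 22)."""
    traits = np.asarray(traits, dtype=float)
    n = traits.shape[0]
    if traits.shape[1] != len(TRAIT_CODES):
        raise ValueError("expected 22 trait columns")
    ids = ids or [f"S{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "specimen_id": ids,
            "nest_id": nests or ids,
            "species": species if species is not None else pd.NA,
            "longitude": np.nan,
            "latitude": np.nan,
            "elevation_m": np.nan,
            "dendro_name": pd.NA,
        }
    )
    for j, code in enumerate(TRAIT_CODES):
        df[code] = traits[:, j]
    return SpecimenTable(df, registry=DEFAULT_REGISTRY, provenance="fixture")


def make_narrow_table(traits: np.ndarray, codes, nests=None) -> SpecimenTable:
    """SpecimenTable over a reduced trait registry (for small oracles)."""
    traits = np.asarray(traits, dtype=float)
    registry = TraitRegistry(tuple(TraitEntry(c, c, None) for c in codes))
    n = traits.shape[0]
    df = pd.DataFrame(
        {
            "specimen_id": [f"S{i:03d}" for i in range(n)],
            "nest_id": nests or [f"S{i:03d}" for i in range(n)],
            "species": pd.NA,
            "longitude": np.nan,
            "latitude": np.nan,
            "elevation_m": np.nan,
            "dendro_name": pd.NA,
        }
    )
    for j, code in enumerate(codes):
        df[code] = traits[:, j]
    return SpecimenTable(df, registry=registry, provenance="fixture")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160420)


@pytest.fixture(scope="session")
def small_dataset():
    """4 well-separated species, 6 nests × 2 workers each."""
    return simulate_dataset(
        SimulationConfig(
            n_species=4,
            nests_per_species=6,
            workers_per_nest=2,
            separation_d=10.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def study_dataset():
    """Realistic 8-species study-like dataset (227 specimens)."""
    return simulate_dataset(study_like_config(seed=5))


@pytest.fixture(scope="session")
def tiny_noise_dataset():
    """8 species at published means with near-negligible noise."""
    return simulate_dataset(tight_study_config(seed=5))


# deterministic hypothesis runs (no example database, fixed derivation)
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, database=None)
_hyp_settings.load_profile("deterministic")
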