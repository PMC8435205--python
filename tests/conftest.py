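import numpy as np
import pandas as pd
import pytest

from moonjelly.simulate import (
    FeatureSim,
    LocalitySim,
    SeqSimSpec,
    TraitSimSpec,
    simulate_alignment,
    simulate_traits,
)
from moonjelly.traits import TraitMatrix


@pytest.fixture(scope="session")
def small_trait_spec():
    """Compact study conditions: 4 localities x 12, 6 features, 15% MCAR."""
    return TraitSimSpec(
        localities=[
            LocalitySim("BRA", -23.8, -45.4, np.log(14.0), 0.2),
            LocalitySim("USA", 41.5, -70.7, np.log(17.0), 0.2),
            LocalitySim("JPN", 34.7, 135.2, np.log(13.0), 0.2),
            LocalitySim("DNK", 55.7, 12.6, np.log(16.0), 0.2),
        ],
        features=[
            FeatureSim("f3", a=0.6, b_true=1.2, sigma=0.06),
            FeatureSim("f5", a=1.5, b_true=0.8, sigma=0.08),
            FeatureSim("f9", a=0.9, b_true=1.0, sigma=0.05),
            FeatureSim("f11", a=2.0, b_true=1.1, sigma=0.07),
            FeatureSim("f40", a=1.0, sigma=0.3, size_independent=True),
            FeatureSim("f8", kind="categorical"),
        ],
        n_per_locality=12,
        missing_rate=0.15,
        geo_gradient=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_traits(small_trait_spec):
    return simulate_traits(small_trait_spec)


@pytest.fixture(scope="session")
def planted_alignment():
    """Noiseless (rate 0) alignment whose only variable columns are planted."""
    spec = SeqSimSpec(
        species_tree="(((spA:0.1,spB:0.1):0.1,spC:0.15):0.1,out:0.3);",
        planted=[
            ("spA", "unique_nonhomoplastic", 3),
            ("spA", "unique_homoplastic", 2),
            ("spA", "nonunique_homoplastic", 1),
            ("spB", "unique_nonhomoplastic", 2),
            ("spB", "ambiguous", 1),
        ],
        length=60,
        rate=0.0,
        n_per_species=4,
        seed=5,
    )
    return spec, simulate_alignment(spec)


def toy_matrix(values: dict, f1, locality, coords=None, **kw) -> TraitMatrix:
    """Hand-built TraitMatrix from plain dicts/lists."""
    df = pd.DataFrame(values)
    df.index = [f"s{i+1}" for i in range(len(df))]
    idx = df.index
    return TraitMatrix(
        values=df,
        size=pd.Series(f1, index=idx, dtype=float),
        locality=pd.Series(locality, index=idx),
        coords=None if coords is None else pd.DataFrame(coords, index=idx, columns=["lat", "lon"]),
        **kw,
    )
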