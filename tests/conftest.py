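import numpy as np
import pandas as pd
import pytest

from mutamosaic.simulate import SimConfig, make_reference, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small seeded experiment: 2 animals/dose, clonal pools, one artifact.

    Position 7 of the seed-11 reference is a G, so a T artifact there is a
    genuine non-reference systematic error present in every library.
    """
    cfg = SimConfig(
        seed=11,
        animals_per_dose=2,
        n_plaques_pooled=60,
        clonal_fraction=1.0,
        reference_length=1500,
        coverage=20_000,
        error_rate=0.001,
    )
    ref = make_reference(cfg)
    pos = next(p for p in range(1, len(ref) + 1) if ref[p - 1] == "G")
    cfg = SimConfig(
        **{
            **{f: getattr(cfg, f) for f in (
                "seed", "animals_per_dose", "n_plaques_pooled", "clonal_fraction",
                "reference_length", "coverage", "error_rate",
            )},
            "artifact_sites": ((pos, "T", 0.04),),
        }
    )
    exp = simulate_experiment(cfg)
    exp.artifact_position = pos
    return exp


@pytest.fixture
def worked_counts():
    """Control [2,3,4] vs treated [20,30,40] with equal totals."""
    return pd.DataFrame(
        {
            "animal_id": list("abcdef"),
            "tissue": "bone_marrow",
            "dose": [0, 0, 0, 40, 40, 40],
            "mutants": [2, 3, 4, 20, 30, 40],
            "total": [100_000] * 6,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
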