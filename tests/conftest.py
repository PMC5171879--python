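import numpy as np
import pytest

from stasiscope.synthetic_data import (
    MorphSimConfig,
    PopGenSimConfig,
    PopulationSpec,
    gen_microsatellites,
    gen_morphometry,
    random_tree,
)


def make_morph_config(
    n_pops: int = 3,
    nests: int = 4,
    workers: int = 20,
    residual_sd: dict | None = None,
    slopes: dict | None = None,
    seed: int = 0,
) -> MorphSimConfig:
    residual_sd = residual_sd or {"HTL": 0.01, "FTSL": 0.02, "HTSL": 0.04}
    chars = list(residual_sd)
    pops = []
    for i in range(n_pops):
        pops.append(
            PopulationSpec(
                id=f"P{i + 1}",
                latitude=35.0 + i,
                slopes=slopes or {ch: 1.0 + 0.05 * i for ch in chars},
                intercepts={ch: -0.5 for ch in chars},
                residual_sd=residual_sd,
            )
        )
    return MorphSimConfig(
        populations=tuple(pops),
        nests_per_population=nests,
        workers_per_nest=workers,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_morph_table():
    return gen_morphometry(make_morph_config(seed=11))


@pytest.fixture(scope="session")
def small_genotypes():
    return gen_microsatellites(
        PopGenSimConfig(
            n_populations=3,
            loci=(("L1", 6), ("L2", 6), ("L3", 6), ("L4", 6)),
            target_fst=0.15,
            individuals_per_nest=8,
            nests_per_population=3,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def ten_tip_tree():
    return random_tree(10, seed=42, unit_height=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
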