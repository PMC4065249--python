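import numpy as np
import pandas as pd
import pytest

from condmap import (
    InteractionCall,
    ScreenTensor,
    SimulationConfig,
    build_network,
    generate_screen,
    read_interaction_calls,
)
from condmap.types import SCORE_COLUMNS


@pytest.fixture(scope="session")
def curated_calls() -> list[InteractionCall]:
    """The packaged curated table of significant conditional interactions."""
    return read_interaction_calls()


@pytest.fixture(scope="session")
def curated_network(curated_calls):
    return build_network(curated_calls)


@pytest.fixture
def tiny_tensor() -> ScreenTensor:
    """Two queries x three arrays, UNT + CPT at two concentrations, 2 reps."""
    rows = []
    rng = np.random.default_rng(42)
    for q in ["Q1", "Q2"]:
        for a in ["A1", "A2", "A3"]:
            for drug, concs in [("UNT", ["ctrl1", "ctrl2"]), ("CPT", ["10ug", "15ug"])]:
                for conc in concs:
                    for rep in (1, 2):
                        rows.append(
                            (q, a, drug, conc, rep, round(float(rng.normal()), 3))
                        )
    return ScreenTensor(pd.DataFrame(rows, columns=SCORE_COLUMNS))


@pytest.fixture(scope="session")
def small_screen():
    """A modest synthetic screen with planted effects, shared across tests."""
    cfg = SimulationConfig(
        n_queries=3, n_arrays=300, noise_sd=1.0, effect_size=6.0,
        planted_fraction=0.02, seed=7,
    )
    return generate_screen(cfg)
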