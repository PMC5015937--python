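"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from htgp.relationships import genomic_relationship
from htgp.simulate import scenario_presets, simulate_dataset


@pytest.fixture(scope="session")
def small_early_heat():
    """One small early-heat environment: markers, pedigree, truth, plots."""
    cfg = scenario_presets("early_heat", n_lines=84, n_markers=400, seed=11)
    markers, ped, truth, plots = simulate_dataset(cfg)
    return dict(cfg=cfg, markers=markers, pedigree=ped, truth=truth, plots=plots)


@pytest.fixture(scope="session")
def small_kernel(small_early_heat):
    return genomic_relationship(small_early_heat["markers"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def balanced_oneway(rng):
    """30 genotypes x 3 replicates with known variance components."""
    g = rng.normal(0, np.sqrt(2.0), 30)
    rows = [
        dict(line=f"L{i:02d}", replicate=str(r), value=5.0 + g[i] + rng.normal())
        for i in range(30)
        for r in range(3)
    ]
    return pd.DataFrame(rows)
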