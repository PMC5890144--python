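import numpy as np
import pandas as pd
import pytest

from tvanet.params import TVAParams
from tvanet.simulate import (FMRIScene, PopulationSpec, sample_population,
                             simulate_behavior, simulate_fmri)


@pytest.fixture(scope="session")
def ref_params() -> TVAParams:
    return TVAParams(C=25.89, K_mean=3.03, t0=10.0, mu=150.0,
                     alpha=0.52, w_lat=0.49)


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    return sample_population(PopulationSpec(n_subjects=12, seed=100))


@pytest.fixture(scope="session")
def small_trials(small_population) -> pd.DataFrame:
    return simulate_behavior(small_population, seed=101)


@pytest.fixture(scope="session")
def tiny_scene() -> FMRIScene:
    return FMRIScene(shape=(14, 14, 8), n_volumes=80, n_networks=3,
                     group_effects=[], template_seed=55)


@pytest.fixture(scope="session")
def tiny_sim(small_population, tiny_scene):
    return simulate_fmri(small_population, tiny_scene, seed=102)
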