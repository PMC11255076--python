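import numpy as np
import pytest
from hypothesis import settings

import ventltf as v

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_config() -> v.GeneratorConfig:
    return v.GeneratorConfig(subject_sd_lpm=0.0, noise_sd_lpm=0.0, pet_noise_sd_mmhg=0.0)


@pytest.fixture(scope="session")
def default_group():
    """One default 7-subject group (3% CO2) and its group average."""
    return v.generate_group(v.GeneratorConfig(seed=11))


def stable_pool_params(rng: np.random.Generator) -> v.PoolParams:
    """Draw random pool constants with K > 0 and positive damping."""
    while True:
        p = v.PoolParams(
            t1=rng.uniform(0.3, 3.0),
            t2=rng.uniform(0.3, 3.0),
            C11=rng.uniform(0.0, 1.8),
            C12=rng.uniform(0.3, 2.0),
            C21=rng.uniform(0.3, 2.0),
            C22=rng.uniform(0.0, 1.5),
            D=rng.uniform(0.5, 3.0),
        )
        if p.K > 0.05 and (p.t1 * (1 + p.C22) - p.t2 * (p.C11 - 1)) > 0.05:
            return p


def recovery_series(params: v.CanonicalParams):
    """A full-protocol series that is zero outside the recovery segment and
    follows the given step response inside it; returns (series, t, segments)."""
    grid = v.build_protocol(v.default_protocol())
    t, segs = grid.time_min, grid.labels
    y = np.zeros_like(t)
    rec = segs == "w40_2"
    y[rec] = v.step_response(params, t[rec] - t[rec][0])
    return y, t, segs
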