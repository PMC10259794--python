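import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gamma_movie():
    """A short rendered gamma-preset experiment shared across tests."""
    import rifdyn

    cfg = rifdyn.make_condition_preset("gamma", n_nuclei=3, n_frames=40, seed=2024)
    return cfg, rifdyn.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def gamma_detections(gamma_movie):
    """Detection pipeline run over the shared gamma movie."""
    from rifdyn import detect

    cfg, res = gamma_movie
    import pandas as pd
    nuc_frames, obs_frames = [], []
    for nid, stack in enumerate(res.movies):
        nuclei, obs = detect.process_movie(stack, res.metadata(nid))
        nuc_frames.append(nuclei)
        obs_frames.append(obs)
    return cfg, res, pd.concat(nuc_frames, ignore_index=True), pd.concat(
        obs_frames, ignore_index=True)
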