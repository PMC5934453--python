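"""Shared fixtures: small synthetic sessions built once per test run."""

import numpy as np
import pytest

import probreach as pr
from probreach import neurons


@pytest.fixture(scope="session")
def behavior_session():
    """Medium behavioral-only session for behavior analyses."""
    return pr.simulate_session(100, seed=11)


@pytest.fixture(scope="session")
def pmap_default():
    return neurons.estimate_probability_map(
        n_samples=4000, grid_spacing=1.0, rng=np.random.default_rng(100))


@pytest.fixture(scope="session")
def pr_session(pmap_default):
    """Session with a pure potential-response population and known PDs."""
    rng = np.random.default_rng(12)
    s = pr.simulate_session(120, seed=12)
    specs = neurons.make_population(n_pr=40, n_sr=0, n_m1=0, rng=rng)
    neurons.synthesize_spikes(specs, s, pmap_default, rng=rng)
    valid, _ = pr.filter_reaches(s)
    pds = {sp.neuron_id: sp.pd for sp in specs}
    return {"session": s, "valid": valid, "specs": specs, "pds": pds,
            "pmap": pmap_default}


@pytest.fixture(scope="session")
def mixed_session(pmap_default):
    """Small mixed PR/SR/M1 session for encoding-analysis unit tests."""
    rng = np.random.default_rng(13)
    s = pr.simulate_session(80, seed=13)
    specs = neurons.make_population(n_pr=4, n_sr=4, n_m1=3, rng=rng)
    neurons.synthesize_spikes(specs, s, pmap_default, rng=rng)
    valid, _ = pr.filter_reaches(s)
    return {"session": s, "valid": valid, "specs": specs,
            "pmap": pmap_default}
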