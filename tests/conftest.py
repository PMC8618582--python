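import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chromoca as cc
from chromoca.fitting import FitConfig, fit_potentials
from chromoca.fixtures import fixture_spec, generate_fixture
from chromoca.potentials import make_trial_potentials

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_fixture():
    """Forward-generated full pipeline dataset, N = 50, K = 120."""
    return generate_fixture("full-pipeline", "tiny", seed=7)


@pytest.fixture(scope="session")
def small_fixture():
    """Contact-map dataset at recovery scale, N = 120, K = 300."""
    return generate_fixture("contact-map", "small", seed=7)


@pytest.fixture(scope="session")
def small_refit(small_fixture):
    """Inverse fit of the small fixture's target map (the long run)."""
    cfg = FitConfig(ensemble_start=200, ensemble_max=300,
                    max_iters=20, patience=4)
    field, ens, hist = fit_potentials(small_fixture["spec"],
                                      small_fixture["target_map"].values,
                                      cfg, seed=11)
    return {"field": field, "ensemble": ens, "history": hist}


@pytest.fixture(scope="session")
def dense_ensemble():
    """Dense homopolymer globule of the tiny chain (9.34 kT attraction)."""
    spec = fixture_spec("tiny")
    field = make_trial_potentials("homopolymer", spec, u0=9.34)
    return spec, field, cc.sample_ensemble(spec, field, 60, seed=21)


@pytest.fixture(scope="session")
def loose_ensemble():
    """Self-avoiding coil ensemble of the tiny chain (no attraction)."""
    spec = fixture_spec("tiny")
    field = make_trial_potentials("coil", spec)
    return spec, field, cc.sample_ensemble(spec, field, 60, seed=22)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
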