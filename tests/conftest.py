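import pytest

from fluxprop import (
    NoiseModel,
    PropagationConfig,
    build_reference,
    builtin_dataset,
    load_toy_network,
    make_schedule,
    propagate,
)


@pytest.fixture(scope="session")
def toy_network():
    return load_toy_network()


@pytest.fixture(scope="session")
def k1par():
    return builtin_dataset("K1par-like")


@pytest.fixture(scope="session")
def hyher():
    return builtin_dataset("HYher-like")


@pytest.fixture(scope="session")
def k1par_ref(k1par, toy_network):
    return build_reference(k1par, toy_network)


@pytest.fixture(scope="session")
def hyher_ref(hyher, toy_network):
    return build_reference(hyher, toy_network)


@pytest.fixture(scope="session")
def sched6():
    return make_schedule("regular", 6.0)


@pytest.fixture(scope="session")
def prop_2pct(k1par_ref, k1par, toy_network, sched6):
    """Low-noise propagation shared across statistics tests."""
    cfg = PropagationConfig(schedule=sched6, noise=NoiseModel(0.02), n_draws=300, seed=101)
    return propagate(k1par_ref, k1par, toy_network, cfg)


@pytest.fixture(scope="session")
def prop_20pct(k1par_ref, k1par, toy_network, sched6):
    """High-noise propagation with the same seed (common random numbers)."""
    cfg = PropagationConfig(schedule=sched6, noise=NoiseModel(0.20), n_draws=300, seed=101)
    return propagate(k1par_ref, k1par, toy_network, cfg)
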