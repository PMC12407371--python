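"""Shared fixtures: synthetic libraries and trained generators.

Training fixtures are session-scoped because full-batch Adam runs of a
few thousand epochs, while only seconds each, add up across tests.
"""

import dataclasses

import numpy as np
import pytest

from leafplp import cvae, synthetic


@pytest.fixture(scope="session")
def honey_spec():
    return synthetic.get_spec("honey")


@pytest.fixture(scope="session")
def jsp_spec():
    return synthetic.get_spec("japanese")


@pytest.fixture(scope="session")
def jsp_noiseless_spec(jsp_spec):
    return dataclasses.replace(jsp_spec, noise_v_sd=0.0, noise_rwc_sd=0.0)


@pytest.fixture(scope="session")
def honey_noiseless_spec(honey_spec):
    return dataclasses.replace(honey_spec, noise_v_sd=0.0, noise_rwc_sd=0.0)


@pytest.fixture(scope="session")
def honey_library(honey_spec):
    return synthetic.generate_library(honey_spec, seed=11)


@pytest.fixture(scope="session")
def jsp_noiseless_library(jsp_noiseless_spec):
    return synthetic.generate_library(jsp_noiseless_spec, n=50, seed=5)


@pytest.fixture(scope="session")
def jsp_noiseless_holdout(jsp_noiseless_spec):
    return synthetic.generate_library(jsp_noiseless_spec, n=10, seed=77)


@pytest.fixture(scope="session")
def jsp_noiseless_generator(jsp_noiseless_library):
    gen, traces = cvae.train(
        jsp_noiseless_library, cvae.CVAEConfig(epochs=5000, seed=3)
    )
    return gen, traces


@pytest.fixture(scope="session")
def trained_cultivars():
    """Noisy default libraries for all three cultivars, trained at 2000
    epochs, plus 10/5/5 hold-out libraries -- the scaled-down study design."""
    out = {}
    for name, n_test in (("honey", 10), ("japanese", 5), ("orange", 5)):
        spec = synthetic.get_spec(name)
        lib = synthetic.generate_library(spec, seed=11)
        gen, traces = cvae.train(lib, cvae.CVAEConfig(epochs=2000, seed=3))
        holdout = synthetic.generate_library(spec, n=n_test, seed=99)
        out[name] = {
            "spec": spec,
            "library": lib,
            "generator": gen,
            "traces": traces,
            "holdout": holdout,
            "n_test": n_test,
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
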