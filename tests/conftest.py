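import numpy as np
import pytest

from csrevcorr import (
    NoiseSpec,
    generate_stimuli,
    make_letter_template,
    simulate_responses,
)


@pytest.fixture(scope="session")
def s50():
    """Canonical 50x50 letter-S template (shipped fixture)."""
    return make_letter_template("S", (50, 50))


@pytest.fixture(scope="session")
def s20():
    """Reduced 20x20 letter-S template for cheaper simulation tests."""
    return make_letter_template("S", (20, 20))


@pytest.fixture(scope="session")
def noiseless_10k(s50):
    """One noiseless 10,000-trial simulated session with the 50x50 S."""
    stim = generate_stimuli(10000, (50, 50), seed=21)
    resp = simulate_responses(s50, stim, NoiseSpec(0.0), seed=22)
    return stim, resp


def simulate_session(template, n, sigma=0.0, mechanism="flip", seed=0):
    """Convenience: one stimulus set + response vector under the given observer."""
    noise = NoiseSpec(sigma, mechanism) if sigma > 0 else NoiseSpec(0.0)
    stim = generate_stimuli(n, template.shape, seed=seed)
    resp = simulate_responses(template, stim, noise, seed=seed + 1)
    return stim, resp
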