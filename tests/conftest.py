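"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest
from scipy.special import expit

import dsschoice as d


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def gaussian_trials():
    """10k seven-sample trials with standard-normal evidence, no choices."""
    r = np.random.default_rng(101)
    S = r.normal(0.0, 1.0, size=(10_000, 7))
    return d.TrialTable(evidence=S, choice=np.zeros(10_000, dtype=int))


@pytest.fixture(scope="session")
def integration_dataset(gaussian_trials):
    """Choices simulated from a known integration model."""
    beta = np.array([1.0, 0.8, 0.6, 0.4, 0.3, 0.2, 0.1])
    params = d.IntegrationParams(beta0=0.2, beta=beta)
    y = d.simulate_choices(params, gaussian_trials, seed=202)
    return gaussian_trials.with_choices(y), params


@pytest.fixture(scope="session")
def ragged_trials():
    """Human-style ragged table, 5-10 samples per trial."""
    r = np.random.default_rng(55)
    lengths = r.integers(5, 11, size=400)
    seqs = [r.normal(0, 0.3, size=n) for n in lengths]
    return d.TrialTable.from_ragged(seqs, r.integers(0, 2, size=400))


def simulate_logistic(S, beta, beta0=0.0, seed=0):
    r = np.random.default_rng(seed)
    p = expit(beta0 + S @ beta)
    return (r.random(S.shape[0]) < p).astype(int)
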