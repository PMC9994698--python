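"""Shared fixtures and independent oracles.

The brute-force functions here enumerate latent death times / complete history
spaces directly from the generative story; they deliberately share no code
with the package's recursion-based likelihood, so agreement between the two is
an independent check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import jspopan as jp


@pytest.fixture(scope="session")
def design():
    """The published 23-group study design."""
    return jp.default_design()


@pytest.fixture(scope="session")
def best_spec():
    return jp.ModelSpec.parse("Phi(acc2019) p(t)")


@pytest.fixture(scope="session")
def sim_dataset(design):
    """One synthetic dataset at the default (published) study conditions."""
    scenario = jp.SimulationScenario(seed=20)
    histories, truth = jp.simulate_histories(scenario)
    data = jp.prepare_data(histories, design)
    return scenario, histories, data, truth


def brute_history_prob(det, release, phi, p):
    """P(history) by summing over the latent last-alive occasion."""
    T = len(p)
    det = list(det)
    idx = [t for t in range(T) if det[t]]
    min_alive = max(idx) if idx else release
    total = 0.0
    for a in range(min_alive, T):  # a = last occasion alive
        prob = 1.0
        for t in range(release, a):
            prob *= phi[t]
        if a < T - 1:
            prob *= 1.0 - phi[a]
        for t in range(release, a + 1):
            prob *= p[t] if det[t] else (1.0 - p[t])
        total += prob
    return total


def brute_group_loglik(group_data, phi, p):
    """Group log-likelihood via the brute-force per-history probability."""
    r = group_data.group.release_occasion
    ll = 0.0
    for row, c in zip(group_data.histories, group_data.counts):
        ll += c * np.log(brute_history_prob(row, r, phi, p))
    if group_data.n_unobserved:
        zero = [0] * len(p)
        ll += group_data.n_unobserved * np.log(brute_history_prob(zero, r, phi, p))
    return ll


def all_histories(release, T=jp.N_OCCASIONS):
    """Every binary history with no detection before release."""
    span = T - release
    for tail in itertools.product((0, 1), repeat=span):
        yield (0,) * release + tail
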