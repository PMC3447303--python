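"""Shared fixtures and the brute-force Boltzmann oracle used across the suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from isingnet import Connectome, IsingParams


@pytest.fixture
def two_spin() -> Connectome:
    """The smallest coupled system: two spins joined by a unit edge."""
    return Connectome(np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def two_spin_params() -> IsingParams:
    return IsingParams(W=1.0, theta=1.0, epsilon=1.0)


def random_graph(n: int, p_edge: float, seed: int, weighted: bool = False) -> Connectome:
    """Symmetric random test graph (Erdos-Renyi support, optional weights)."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.lognormal(0, 0.5) if weighted else 1.0
    return Connectome(w)


def brute_force_boltzmann(C: np.ndarray, W: float, theta: float, eps: float,
                          theta_coeff_half: bool = True):
    """Independent enumeration oracle: explicit per-state loops, no shared code.

    Returns (logZ, entropy, marginals, joint11, meanH) for the energy
    H = c_theta * sum_i S_i - W/2 * sum_{i,j} C_ij S_i S_j with
    c_theta = theta/2 (default) or theta.
    """
    n = C.shape[0]
    c_theta = theta / 2.0 if theta_coeff_half else theta
    energies = []
    states = []
    for mask in range(1 << n):
        s = [(mask >> i) & 1 for i in range(n)]
        lin = c_theta * sum(s)
        quad = 0.0
        for i in range(n):
            for j in range(n):
                quad += C[i, j] * s[i] * s[j]
        energies.append(lin - 0.5 * W * quad)
        states.append(s)
    energies = np.array(energies)
    m = (-eps * energies).max()
    w = np.exp(-eps * energies - m)
    Z_scaled = w.sum()
    logZ = m + math.log(Z_scaled)
    probs = w / Z_scaled
    entropy = float(-(probs[probs > 0] * np.log(probs[probs > 0])).sum())
    S = np.array(states, dtype=float)
    marginals = probs @ S
    joint11 = (S * probs[:, None]).T @ S
    meanH = float(probs @ energies)
    return logZ, entropy, marginals, joint11, meanH
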