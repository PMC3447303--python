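"""Stochastic single-site (Glauber / heat-bath) dynamics of the spin network.

Asynchronous updates: one uniformly random site per step, N steps per sweep;
the chosen site is resampled to 1 with probability

    paper_literal      g(W * sum_j C_ij S_j - theta)
    energy_consistent  g(W * sum_j C_ij S_j - theta / 2)

with g(x) = 1 / (1 + exp(-eps * x)).  The ``energy_consistent`` variant is the
heat-bath rule whose stationary distribution is exactly the Boltzmann-Gibbs law
of the half-theta energy used by the exact-enumeration module, which makes it
the default for cross-validation; ``paper_literal`` keeps the threshold
unhalved.  The two coincide when theta = 0.

This module exists purely as an independent validation path against exact
enumeration — the analytics never depend on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .connectome import Connectome
from .exact import IsingParams

_MODES = ("paper_literal", "energy_consistent")


@dataclass
class Trajectory:
    """A recorded Glauber chain: one state bitmask per single-site update step."""

    states: np.ndarray  # uint64 bitmasks, length sweeps * n
    n: int
    sweep_count: int
    burn_in: int
    seed: int
    mode: str

    def post_burn_in(self) -> np.ndarray:
        return self.states[self.burn_in * self.n:]

    def marginals(self) -> np.ndarray:
        """Per-node empirical P(S_i = 1) over post-burn-in steps."""
        s = self.post_burn_in()
        if s.size == 0:
            raise ValueError("no post-burn-in samples")
        shifts = np.arange(self.n, dtype=np.uint64)
        bits = (s[:, None] >> shifts[None, :]) & np.uint64(1)
        return bits.mean(axis=0)


def _threshold(p: IsingParams, mode: str) -> float:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    return p.theta if mode == "paper_literal" else p.theta / 2.0


def flip_probability(state, i: int, c: Connectome, p: IsingParams,
                     mode: str = "energy_consistent") -> float:
    """Probability that site ``i`` is set to 1 given the current state."""
    s = np.asarray(state, dtype=float)
    if not 0 <= i < c.n:
        raise IndexError(f"site {i} out of range for N={c.n}")
    x = p.W * float(c.weights[i] @ s) - _threshold(p, mode)
    return 1.0 / (1.0 + math.exp(-p.epsilon * x))


def run_chain(c: Connectome, p: IsingParams, sweeps: int, burn_in: int,
              seed: int, mode: str = "energy_consistent",
              init: Optional[np.ndarray] = None) -> Trajectory:
    """Run an asynchronous heat-bath chain, recording every single-site step.

    One RNG stream drives the whole chain; per sweep, the N site choices are
    drawn first and then the N uniform variates, in fixed order, so runs are
    bit-reproducible from the seed.
    """
    if burn_in < 0 or sweeps <= burn_in:
        raise ValueError(f"need sweeps > burn_in >= 0, got {sweeps}, {burn_in}")
    thr = _threshold(p, mode)
    n = c.n
    if n > 63:
        raise ValueError("bitmask trajectories support at most 63 nodes")
    rng = np.random.default_rng(seed)
    state = np.zeros(n) if init is None else np.asarray(init, dtype=float).copy()
    # local fields h_j = sum_k C_jk S_k maintained incrementally
    h = c.weights @ state
    neighbors = [np.nonzero(c.weights[j])[0] for j in range(n)]
    nbr_w = [c.weights[j][neighbors[j]] for j in range(n)]
    mask = 0
    for j in range(n):
        if state[j]:
            mask |= 1 << j
    eps, W = p.epsilon, p.W
    out = np.empty(sweeps * n, dtype=np.uint64)
    t = 0
    for _ in range(sweeps):
        sites = rng.integers(0, n, size=n)
        us = rng.random(n)
        for k in range(n):
            j = int(sites[k])
            pj = 1.0 / (1.0 + math.exp(-eps * (W * h[j] - thr)))
            new = 1.0 if us[k] < pj else 0.0
            if new != state[j]:
                delta = new - state[j]
                state[j] = new
                h[neighbors[j]] += delta * nbr_w[j]
                mask ^= 1 << j
            out[t] = mask
            t += 1
    return Trajectory(states=out, n=n, sweep_count=sweeps, burn_in=burn_in,
                      seed=seed, mode=mode)


def empirical_state_distribution(traj: Trajectory, thin: int = 1) -> dict[int, float]:
    """Post-burn-in state frequencies (bitmask -> frequency, summing to 1)."""
    if thin < 1:
        raise ValueError("thin must be >= 1")
    s = traj.post_burn_in()[::thin]
    if s.size == 0:
        raise ValueError("empty post-burn-in trajectory")
    vals, counts = np.unique(s, return_counts=True)
    total = counts.sum()
    return {int(v): cnt / total for v, cnt in zip(vals, counts)}
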