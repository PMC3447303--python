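"""Exact enumeration: energies, Boltzmann summaries, sweeps, bifurcation locator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isingnet import (Connectome, IsingParams, boltzmann_summary, energy,
                      entropy_sweep, find_edge_of_bifurcation,
                      independent_entropy)
from isingnet.exact import ENUMERATION_CAP, EnumerationError

from conftest import brute_force_boltzmann, random_graph


class TestEnergy:
    def test_all_zero_state_has_zero_energy(self, two_spin, two_spin_params):
        assert energy(0, two_spin, two_spin_params) == 0.0

    def test_hand_evaluated_two_spin_energies(self, two_spin, two_spin_params):
        # states (1,1) -> masks 0b11; (1,0) -> 0b01
        assert energy(0b11, two_spin, two_spin_params) == pytest.approx(0.0)
        assert energy(0b01, two_spin, two_spin_params) == pytest.approx(0.5)
        assert energy(0b10, two_spin, two_spin_params) == pytest.approx(0.5)

    def test_full_theta_convention_doubles_linear_term(self, two_spin):
        p = IsingParams(W=0.0, theta=1.0, energy_convention="full_theta")
        assert energy(0b01, two_spin, p) == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self, two_spin, two_spin_params):
        with pytest.raises(ValueError):
            energy(np.array([1.0, 0.0, 1.0]), two_spin, two_spin_params)


class TestBoltzmannSummary:
    def test_single_unbiased_spin(self):
        c = Connectome(np.zeros((1, 1)))
        s = boltzmann_summary(c, IsingParams(W=0.0, theta=0.0, epsilon=1.0))
        assert s.logZ == pytest.approx(math.log(2), abs=1e-12)
        assert s.entropy == pytest.approx(math.log(2), abs=1e-12)
        assert s.marginals[0] == pytest.approx(0.5, abs=1e-12)

    def test_two_spin_matches_brute_force(self, two_spin, two_spin_params):
        s = boltzmann_summary(two_spin, two_spin_params)
        logZ, ent, marg, joint, meanH = brute_force_boltzmann(
            two_spin.weights, 1.0, 1.0, 1.0)
        assert s.logZ == pytest.approx(logZ, abs=1e-12)
        assert s.entropy == pytest.approx(ent, abs=1e-12)
        assert np.abs(s.marginals - marg).max() < 1e-12
        assert np.abs(s.joint11 - joint).max() < 1e-12
        # frozen reference values from the oracle
        assert s.entropy == pytest.approx(1.3560, abs=5e-5)
        assert s.marginals == pytest.approx([0.5, 0.5], abs=1e-12)

    @pytest.mark.parametrize("n,seed", [(6, 0), (9, 1), (12, 2)])
    def test_chunked_streaming_equals_naive_enumeration(self, n, seed):
        c = random_graph(n, 0.35, seed, weighted=True)
        p = IsingParams(W=1.2, theta=3.0, epsilon=0.8)
        s = boltzmann_summary(c, p, chunk_size=37)  # force many ragged chunks
        logZ, ent, marg, joint, meanH = brute_force_boltzmann(
            c.weights, p.W, p.theta, p.epsilon)
        assert s.logZ == pytest.approx(logZ, abs=1e-10)
        assert s.entropy == pytest.approx(ent, abs=1e-10)
        assert np.abs(s.marginals - marg).max() < 1e-10
        assert np.abs(s.joint11 - joint).max() < 1e-10

    def test_zero_coupling_closed_form(self):
        p = IsingParams(W=0.0, theta=12.0, epsilon=1.0)
        for n, seed in ((5, 3), (12, 4)):
            c = random_graph(n, 0.4, seed)
            s = boltzmann_summary(c, p)
            assert s.entropy == pytest.approx(independent_entropy(n, p), abs=1e-9)

    def test_entropy_identity_and_bounds(self):
        c = random_graph(8, 0.4, 6)
        p = IsingParams(W=2.0, theta=4.0, epsilon=1.5)
        s = boltzmann_summary(c, p)
        assert s.entropy == pytest.approx(p.epsilon * s.meanH + s.logZ, abs=1e-9)
        assert 0.0 <= s.entropy <= c.n * math.log(2) + 1e-12
        assert np.all((s.marginals >= 0) & (s.marginals <= 1))
        iu = np.triu_indices(c.n, 1)
        cap = np.minimum(s.marginals[:, None], s.marginals[None, :])
        assert np.all(s.joint11[iu] <= cap[iu] + 1e-12)

    def test_probabilities_normalize(self):
        c = random_graph(10, 0.3, 7)
        p = IsingParams(W=1.0, theta=2.0)
        s = boltzmann_summary(c, p)
        total = sum(math.exp(-p.epsilon * energy(m, c, p) - s.logZ)
                    for m in range(1 << c.n))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_label_permutation_invariance(self):
        c = random_graph(8, 0.4, 8)
        p = IsingParams(W=1.5, theta=3.0)
        perm = np.random.default_rng(0).permutation(8)
        cp = Connectome(c.weights[np.ix_(perm, perm)])
        s, sp = boltzmann_summary(c, p), boltzmann_summary(cp, p)
        assert sp.logZ == pytest.approx(s.logZ, abs=1e-10)
        assert sp.entropy == pytest.approx(s.entropy, abs=1e-10)
        assert np.abs(sp.marginals - s.marginals[perm]).max() < 1e-10

    def test_enumeration_cap_enforced(self):
        c = Connectome(np.zeros((ENUMERATION_CAP + 1, ENUMERATION_CAP + 1)))
        with pytest.raises(EnumerationError, match="subsampl"):
            boltzmann_summary(c, IsingParams())


class TestEntropySweep:
    def test_single_point_equals_summary(self, two_spin, two_spin_params):
        t = entropy_sweep(two_spin, two_spin_params, [1.0])
        s = boltzmann_summary(two_spin, two_spin_params)
        assert len(t) == 1
        assert t["entropy"].iloc[0] == pytest.approx(s.entropy, abs=1e-12)

    def test_low_high_low_shape_and_decay(self):
        c = random_graph(12, 0.35, 11)
        p = IsingParams(theta=12.0, epsilon=1.0)
        grid = np.linspace(0, 12, 25)
        t = entropy_sweep(c, p, grid)
        e = t["entropy"].to_numpy()
        k = int(np.argmax(e))
        assert 0 < k < len(e) - 1  # interior maximum
        assert e[-1] < 0.05 * e.max()  # strong-coupling freeze-out

    def test_identity_holds_at_every_sweep_point(self):
        c = random_graph(10, 0.35, 12)
        p = IsingParams(theta=12.0, epsilon=1.0)
        t = entropy_sweep(c, p, np.linspace(0, 8, 9))
        resid = t["entropy"] - (p.epsilon * t["mean_energy"] + t["logZ"])
        assert np.abs(resid).max() < 1e-9

    def test_deterministic(self):
        c = random_graph(8, 0.4, 13)
        p = IsingParams()
        grid = np.linspace(0, 6, 13)
        a = entropy_sweep(c, p, grid)
        b = entropy_sweep(c.copy(), p, grid)
        assert np.array_equal(a["entropy"].to_numpy(), b["entropy"].to_numpy())

    def test_invalid_grids_rejected(self, two_spin, two_spin_params):
        with pytest.raises(ValueError):
            entropy_sweep(two_spin, two_spin_params, [])
        with pytest.raises(ValueError):
            entropy_sweep(two_spin, two_spin_params, [1.0, 0.5])


class TestEdgeOfBifurcation:
    def test_largest_rise_selected(self):
        sweep = pd.DataFrame({"W": [1, 2, 3, 4, 5, 6],
                              "entropy": [0, 0, 5, 9, 10, 2]})
        assert find_edge_of_bifurcation(sweep) == 2.0

    def test_tie_breaks_toward_smaller_W(self):
        sweep = pd.DataFrame({"W": [1, 2, 3, 4, 5],
                              "entropy": [0, 3, 6, 7, 1]})
        assert find_edge_of_bifurcation(sweep) == 1.0

    def test_flat_sweep_rejected(self):
        sweep = pd.DataFrame({"W": [1, 2, 3], "entropy": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            find_edge_of_bifurcation(sweep)

    def test_bifurcation_precedes_entropy_maximum(self):
        from isingnet import SynthConnectomeSpec, synth_connectome
        c = synth_connectome(SynthConnectomeSpec(seed=2))
        p = IsingParams()
        grid = np.linspace(0, 8, 33)
        t = entropy_sweep(c, p, grid)
        w_star = find_edge_of_bifurcation(t)
        assert w_star < grid[int(np.argmax(t["entropy"]))]


class TestPropertyInvariants:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_entropy_identity_for_arbitrary_parameters(self, draw):
        rng = np.random.default_rng(draw)
        n = int(rng.integers(2, 7))
        c = random_graph(n, 0.5, int(rng.integers(0, 2**31)), weighted=True)
        p = IsingParams(W=float(rng.uniform(0, 4)),
                        theta=float(rng.uniform(0, 12)),
                        epsilon=float(rng.uniform(0.2, 2.0)))
        s = boltzmann_summary(c, p)
        assert s.entropy == pytest.approx(p.epsilon * s.meanH + s.logZ, abs=1e-9)
        assert -1e-12 <= s.entropy <= n * math.log(2) + 1e-9
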