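"""Exact pairwise MI/correlation, pooled distributions, ensemble entropy curves."""

import math
from dataclasses import replace

import numpy as np
import pytest

from isingnet import (Connectome, EnsembleSpec, IsingParams,
                      ensemble_entropy_curves, generate_ensemble,
                      max_entropy_vs_size, pair_stats, pair_value_distribution)

from conftest import brute_force_boltzmann, random_graph


class TestPairStats:
    def test_isolated_spins_are_independent(self):
        c = Connectome(np.zeros((3, 3)))
        st = pair_stats(c, IsingParams(W=1.0, theta=2.0))
        iu = np.triu_indices(3, 1)
        assert np.abs(st.mi[iu]).max() < 1e-12
        assert np.abs(st.corr[iu]).max() < 1e-12

    def test_two_spin_mi_matches_brute_force(self, two_spin, two_spin_params):
        st = pair_stats(two_spin, two_spin_params)
        logZ, ent, marg, joint, _ = brute_force_boltzmann(two_spin.weights, 1, 1, 1)
        p11 = joint[0, 1]
        cells = [p11, marg[0] - p11, marg[1] - p11, 1 - marg[0] - marg[1] + p11]
        prods = [marg[0] * marg[1], marg[0] * (1 - marg[1]),
                 (1 - marg[0]) * marg[1], (1 - marg[0]) * (1 - marg[1])]
        mi = sum(c * math.log(c / pr) for c, pr in zip(cells, prods) if c > 0)
        assert st.mi[0, 1] == pytest.approx(mi, abs=1e-12)
        assert st.mi[0, 1] == pytest.approx(0.0303, abs=5e-5)

    def test_disconnected_components_factorize(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.5
        st = pair_stats(Connectome(w), IsingParams(W=1.0, theta=1.0))
        for i in (0, 1):
            for j in (2, 3):
                assert st.mi[i, j] < 1e-12
                assert abs(st.corr[i, j]) < 1e-9

    def test_mi_bounded_by_marginal_entropies(self):
        c = random_graph(8, 0.4, 21)
        st = pair_stats(c, IsingParams(W=2.0, theta=4.0))
        iu = np.triu_indices(8, 1)
        cap = np.minimum(st.mi.diagonal()[:, None], st.mi.diagonal()[None, :])
        assert np.all(st.mi[iu] <= cap[iu] + 1e-9)
        assert np.all(st.mi[iu] >= -1e-12)

    def test_symmetry_and_correlation_range(self):
        c = random_graph(7, 0.5, 22, weighted=True)
        st = pair_stats(c, IsingParams(W=1.5, theta=3.0))
        assert np.abs(st.mi - st.mi.T).max() < 1e-12
        assert np.abs(st.corr - st.corr.T).max() < 1e-12
        assert st.corr.min() >= -1 and st.corr.max() <= 1

    def test_degenerate_marginals_give_zero_correlation(self):
        # huge threshold freezes all spins at 0: zero variance -> corr 0, not NaN
        c = random_graph(5, 0.5, 23)
        st = pair_stats(c, IsingParams(W=1.0, theta=80.0, epsilon=2.0))
        assert np.all(np.isfinite(st.corr))
        assert np.abs(st.corr[np.triu_indices(5, 1)]).max() < 1e-12


class TestPooledDistribution:
    def test_single_instance_counts_pairs(self):
        c = random_graph(3, 0.9, 24)
        st = pair_stats(c, IsingParams(W=1.0, theta=2.0))
        d = pair_value_distribution([st], "mi")
        assert d.values.size == 3

    def test_pooling_over_instances(self):
        stats = [pair_stats(random_graph(5, 0.5, s), IsingParams(W=1.0, theta=2.0))
                 for s in range(4)]
        d = pair_value_distribution(stats, "mi")
        assert d.values.size == 4 * 10

    def test_survival_function_monotone(self):
        stats = [pair_stats(random_graph(6, 0.5, 25), IsingParams(W=1.0, theta=2.0))]
        d = pair_value_distribution(stats, "corr")
        assert np.all(np.diff(d.survival_p) <= 0)

    def test_identical_values_single_bin(self):
        c = Connectome(np.zeros((3, 3)))
        st = pair_stats(c, IsingParams(W=0.0, theta=2.0))
        st.mi[np.triu_indices(3, 1)] = 0.5
        st.mi[np.tril_indices(3, -1)] = 0.5
        d = pair_value_distribution([st], "mi")
        assert d.bin_counts.sum() == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pair_value_distribution([], "mi")


@pytest.fixture(scope="module")
def small_ensemble():
    spec = EnsembleSpec(topology="small-world", n=10, edges=19, instances=3, seed=3)
    return generate_ensemble(spec)


class TestEnsembleCurves:
    def test_single_instance_mean_is_its_sweep(self, small_ensemble):
        from isingnet import entropy_sweep
        grid = np.linspace(0, 6, 13)
        p = IsingParams()
        curve = ensemble_entropy_curves(small_ensemble[:1], p, grid)
        sweep = entropy_sweep(small_ensemble[0], p, grid)
        assert np.allclose(curve.mean, sweep["entropy"])
        assert np.all(curve.std == 0)

    def test_duplicated_instances_zero_std(self, small_ensemble):
        grid = np.linspace(0, 6, 7)
        curve = ensemble_entropy_curves([small_ensemble[0]] * 3, IsingParams(), grid)
        assert np.all(curve.std < 1e-12)

    def test_entropy_bounded_by_n_log2(self, small_ensemble):
        grid = np.linspace(0, 6, 7)
        curve = ensemble_entropy_curves(small_ensemble, IsingParams(), grid)
        assert curve.mean.max() <= 10 * math.log(2)

    def test_mismatched_sizes_rejected(self, small_ensemble):
        bad = small_ensemble + [random_graph(6, 0.5, 1)]
        with pytest.raises(ValueError):
            ensemble_entropy_curves(bad, IsingParams(), [0, 1, 2])


class TestMaxEntropyVsSize:
    def test_single_cell_matches_ensemble_curve(self):
        p = IsingParams()
        grid = np.linspace(0, 6, 13)
        tab = max_entropy_vs_size(["random"], [10], 3.8, p, grid, instances=2, seed=5)
        assert len(tab) == 1
        assert tab["edges"].iloc[0] == 19

    def test_reruns_are_identical(self):
        p = IsingParams()
        grid = np.linspace(0, 6, 7)
        a = max_entropy_vs_size(["random"], [8, 10], 3.8, p, grid, instances=2, seed=6)
        b = max_entropy_vs_size(["random"], [8, 10], 3.8, p, grid, instances=2, seed=6)
        assert np.array_equal(a["mean_max_entropy"], b["mean_max_entropy"])

    def test_sorted_by_size(self):
        p = IsingParams()
        tab = max_entropy_vs_size(["random"], [12, 8, 10], 3.8, p,
                                  np.linspace(0, 6, 7), instances=1, seed=7)
        assert list(tab["N"]) == [8, 10, 12]
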