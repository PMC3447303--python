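"""Exact pairwise statistics and ensemble-level entropy summaries.

Because the Boltzmann law of the spin network is known analytically, pairwise
mutual information and Pearson correlation between spins are computed *exactly*
from the enumerated marginals P(S_i = 1) and joints P(S_i = 1, S_j = 1) — no
sampling estimator is involved.  Pooled value distributions over ensembles and
entropy-vs-coupling curves per topology support the architecture comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .connectome import Connectome
from .ensembles import EnsembleSpec, generate_ensemble
from .exact import (BoltzmannSummary, IsingParams, boltzmann_summary,
                    entropy_sweep, DEFAULT_CHUNK)


@dataclass
class PairStats:
    """Exact N x N mutual-information (nats) and correlation matrices.

    ``mi`` diagonal holds each node's marginal entropy (a convenient normalizer,
    excluded from pooled distributions); ``corr`` diagonal is 1 where the node
    has nonzero variance, else 0.  ``W_at`` records the coupling used.
    """

    mi: np.ndarray
    corr: np.ndarray
    W_at: float
    marginals: np.ndarray

    @property
    def n(self) -> int:
        return self.mi.shape[0]


@dataclass
class EnsembleEntropyCurve:
    """Per-coupling mean/std entropy across ensemble instances, plus maxima."""

    topology: str
    W_grid: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    per_instance_max: np.ndarray


@dataclass
class PooledDistribution:
    """Pooled off-diagonal pair values with log-binned histogram and survival."""

    values: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    survival_x: np.ndarray
    survival_p: np.ndarray


def pair_stats_from_summary(summary: BoltzmannSummary) -> PairStats:
    """MI and correlation matrices from an exact Boltzmann summary."""
    m = np.clip(summary.marginals, 0.0, 1.0)
    n = m.shape[0]
    mi_, mj = m[:, None], m[None, :]
    # enforce Frechet bounds on the joint before deriving the 2x2 cells, so
    # round-off at saturated marginals cannot create negative cell masses
    p11 = np.clip(summary.joint11, 0.0, np.minimum(mi_, mj))
    p11 = np.maximum(p11, mi_ + mj - 1.0)
    p10 = np.clip(mi_ - p11, 0.0, 1.0)
    p01 = np.clip(mj - p11, 0.0, 1.0)
    p00 = np.clip(1.0 - mi_ - mj + p11, 0.0, 1.0)
    cells = (p11, p10, p01, p00)
    prods = (mi_ * mj, mi_ * (1 - mj), (1 - mi_) * mj, (1 - mi_) * (1 - mj))
    mi = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        for c_, pr in zip(cells, prods):
            term = rel_entr(c_, pr)
            mi += np.where(np.isfinite(term), term, 0.0)
    mi = np.where(mi < 0, 0.0, mi)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(m > 0, m * np.log(m), 0.0)
              + np.where(m < 1, (1 - m) * np.log(1 - m), 0.0))
    np.fill_diagonal(mi, h)
    var = np.clip(m * (1.0 - m), 0.0, None)
    denom = np.sqrt(var[:, None] * var[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, (p11 - mi_ * mj) / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, np.where(var > 0, 1.0, 0.0))
    return PairStats(mi=mi, corr=corr, W_at=summary.params.W, marginals=m.copy())


def pair_stats(c: Connectome, p: IsingParams,
               chunk_size: int = DEFAULT_CHUNK) -> PairStats:
    """Exact pairwise MI and correlation for one connectome and parameter set."""
    return pair_stats_from_summary(boltzmann_summary(c, p, chunk_size))


def pair_value_distribution(stats_list: Sequence[PairStats], measure: str = "mi",
                            n_bins: int = 30) -> PooledDistribution:
    """Pool upper-triangle pair values over instances; log-binned histogram.

    Only strictly positive values enter the logarithmic bins (MI is nonnegative;
    nonpositive correlations are excluded from the histogram but retained in
    ``values`` and the survival function).
    """
    if not stats_list:
        raise ValueError("empty stats list")
    if measure not in ("mi", "corr"):
        raise ValueError("measure must be 'mi' or 'corr'")
    vals = []
    for st in stats_list:
        mat = st.mi if measure == "mi" else st.corr
        iu = np.triu_indices(st.n, k=1)
        vals.append(mat[iu])
    values = np.concatenate(vals)
    pos = values[values > 0]
    if pos.size:
        lo, hi = pos.min(), pos.max()
        if hi <= lo:
            edges = np.array([lo * 0.999, hi * 1.001])
        else:
            edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
        counts, edges = np.histogram(pos, bins=edges)
    else:
        edges = np.array([1e-300, 1e-299])
        counts = np.array([0])
    sx = np.sort(values)
    sp = 1.0 - np.arange(sx.size) / sx.size  # P(X >= x), nonincreasing
    return PooledDistribution(values=values, bin_edges=edges, bin_counts=counts,
                              survival_x=sx, survival_p=sp)


def ensemble_entropy_curves(ensemble: Sequence[Connectome], p_base: IsingParams,
                            W_grid: Sequence[float], topology: str = "",
                            chunk_size: int = DEFAULT_CHUNK) -> EnsembleEntropyCurve:
    """Entropy sweep per instance; per-W mean and std, and per-instance maxima."""
    if not ensemble:
        raise ValueError("empty ensemble")
    ns = {c.n for c in ensemble}
    if len(ns) > 1:
        raise ValueError(f"instances have differing node counts: {sorted(ns)}")
    curves = np.array([
        entropy_sweep(c, p_base, W_grid, chunk_size)["entropy"].to_numpy()
        for c in ensemble
    ])
    return EnsembleEntropyCurve(
        topology=topology,
        W_grid=np.asarray(W_grid, dtype=float),
        mean=curves.mean(axis=0),
        std=curves.std(axis=0),
        per_instance_max=curves.max(axis=1),
    )


def max_entropy_vs_size(topologies: Sequence[str], N_list: Sequence[int],
                        mean_degree: float, p_base: IsingParams,
                        W_grid: Sequence[float], instances: int,
                        seed: int) -> pd.DataFrame:
    """Mean maximal entropy per (topology, N) at fixed mean degree.

    The edge count scales as round(mean_degree * N / 2), holding each node's
    typical number of connections fixed so sparsity does not drive the
    comparison.  Returns a DataFrame sorted by N with columns
    ``topology``, ``N``, ``edges``, ``mean_max_entropy``, ``std_max_entropy``.
    """
    rows = []
    for t_idx, topo in enumerate(topologies):
        for n in sorted(N_list):
            edges = int(round(mean_degree * n / 2.0))
            spec = EnsembleSpec(topology=topo, n=n, edges=edges,
                                instances=instances,
                                seed=int(np.random.SeedSequence(
                                    [seed, t_idx, n]).generate_state(1)[0] % (2**31)))
            curve = ensemble_entropy_curves(generate_ensemble(spec), p_base,
                                            W_grid, topology=topo)
            rows.append({
                "topology": topo, "N": n, "edges": edges,
                "mean_max_entropy": float(curve.per_instance_max.mean()),
                "std_max_entropy": float(curve.per_instance_max.std()),
            })
    return pd.DataFrame(rows).sort_values(["topology", "N"]).reset_index(drop=True)
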