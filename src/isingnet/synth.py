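"""Synthetic connectomes and synthetic "empirical" FC with known ground truth.

The generator emulates the salient organisation of a human cortical structural
connectivity matrix at desk scale: modular blocks (denser inside than between),
a mirrored two-hemisphere layout with homotopic counterparts (node i in the
left hemisphere mirrors node i + N/2 in the right, with identical intra-
hemisphere weights and weaker inter-hemispheric links), hub nodes of elevated
degree, and log-normal positive weights.  A noisy functional-connectivity
matrix is derived from the exact model FC of a known ground-truth structural
matrix by perturbing on the Fisher-z scale, so every pipeline stage can be
tested end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .connectome import Connectome
from .exact import IsingParams, DEFAULT_CHUNK
from .fc import FCMatrix, model_fc

#: Inter-hemispheric links are weaker than intra-hemispheric ones by this factor.
CROSS_HEMISPHERE_ATTENUATION = 0.5
#: Probability that a homotopic pair (i, i + N/2) is connected.
HOMOTOPIC_P = 0.9


class SynthError(ValueError):
    pass


@dataclass
class SynthConnectomeSpec:
    """Recipe for a modular, mirrored, hub-containing weighted connectome.

    Defaults give a "human-like" miniature small enough for exact enumeration:
    16 nodes, 4 modules (2 per hemisphere), 2 hubs (1 per hemisphere, mirrored),
    log-normal weights.
    """

    n: int = 16
    n_modules: int = 4
    p_intra: float = 0.9
    p_inter: float = 0.15
    n_hubs: int = 2
    hub_boost: float = 0.4
    weight_mu: float = 0.0
    weight_sigma: float = 0.5
    mirror: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or (self.mirror and self.n % 2):
            raise SynthError("mirrored connectomes need an even node count >= 2")
        if not self.p_intra > self.p_inter:
            raise SynthError(
                f"need p_intra > p_inter (modularity), got {self.p_intra} <= {self.p_inter}"
            )
        if not (0 <= self.p_inter and self.p_intra <= 1):
            raise SynthError("connection probabilities must lie in [0, 1]")
        if self.mirror and self.n_modules % 2:
            raise SynthError("mirrored connectomes need an even module count")
        if self.mirror and self.n_hubs % 2:
            raise SynthError("mirrored connectomes need an even hub count")
        if self.n_hubs < 0 or self.hub_boost < 0:
            raise SynthError("n_hubs and hub_boost must be nonnegative")


def _hemisphere_adjacency(h: int, modules: np.ndarray, hubs: np.ndarray,
                          spec: SynthConnectomeSpec, rng) -> np.ndarray:
    """Upper-triangle Bernoulli adjacency for one hemisphere of h nodes."""
    a = np.zeros((h, h), dtype=bool)
    for i in range(h):
        for j in range(i + 1, h):
            p = spec.p_intra if modules[i] == modules[j] else spec.p_inter
            if hubs[i] or hubs[j]:
                p = min(1.0, p + spec.hub_boost)
            a[i, j] = rng.random() < p
    return a


def synth_connectome(spec: SynthConnectomeSpec) -> Connectome:
    """Generate a weighted, symmetric, modular, hub-containing connectome.

    With ``mirror=True``, the right hemisphere (nodes N/2..N-1) is a
    weight-identical copy of the left: weights[i][j] == weights[i+N/2][j+N/2]
    for intra-hemisphere pairs.  Homotopic pairs are linked with probability
    :data:`HOMOTOPIC_P` and other cross-hemisphere pairs sparsely; both carry
    weights attenuated by :data:`CROSS_HEMISPHERE_ATTENUATION`.  Connectivity
    of the final graph is ensured by adding minimal bridging links.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    w = np.zeros((n, n))
    if spec.mirror:
        h = n // 2
        mods_h = np.sort(np.arange(h) % max(1, spec.n_modules // 2))
        hubs_h = np.zeros(h, dtype=bool)
        hubs_h[rng.choice(h, size=spec.n_hubs // 2, replace=False)] = True
        adj = _hemisphere_adjacency(h, mods_h, hubs_h, spec, rng)
        weights_h = np.zeros((h, h))
        weights_h[adj] = rng.lognormal(spec.weight_mu, spec.weight_sigma,
                                       size=int(adj.sum()))
        weights_h = weights_h + weights_h.T
        w[:h, :h] = weights_h
        w[h:, h:] = weights_h  # mirrored hemisphere, identical weights
        for i in range(h):
            if rng.random() < HOMOTOPIC_P:
                wt = rng.lognormal(spec.weight_mu, spec.weight_sigma)
                w[i, i + h] = w[i + h, i] = wt * CROSS_HEMISPHERE_ATTENUATION
        for i in range(h):
            for j in range(h):
                if j == i or w[i, j + h]:
                    continue
                if rng.random() < spec.p_inter * 0.5:
                    wt = rng.lognormal(spec.weight_mu, spec.weight_sigma)
                    w[i, j + h] = w[j + h, i] = wt * CROSS_HEMISPHERE_ATTENUATION
        hemi = ["left"] * h + ["right"] * h
    else:
        mods = np.sort(np.arange(n) % spec.n_modules)
        hubs = np.zeros(n, dtype=bool)
        if spec.n_hubs:
            hubs[rng.choice(n, size=spec.n_hubs, replace=False)] = True
        adj = _hemisphere_adjacency(n, mods, hubs, spec, rng)
        w[adj] = rng.lognormal(spec.weight_mu, spec.weight_sigma,
                               size=int(adj.sum()))
        w = w + w.T
        hemi = None
    np.fill_diagonal(w, 0.0)
    w = _ensure_connected(w, rng)
    return Connectome(w, hemisphere=hemi)


def _ensure_connected(w: np.ndarray, rng) -> np.ndarray:
    g = nx.from_numpy_array(w > 0)
    comps = list(nx.connected_components(g))
    if len(comps) <= 1:
        return w
    nz = w[w > 0]
    bridge = float(np.median(nz)) if nz.size else 1.0
    base = sorted(comps[0])
    for comp in comps[1:]:
        i = int(rng.choice(base))
        j = int(rng.choice(sorted(comp)))
        w[i, j] = w[j, i] = bridge
        base.extend(sorted(comp))
    return w


def rewire_connectome(c: Connectome, seed: int, swaps_per_edge: int = 10) -> Connectome:
    """Degree-preserving null: double-edge swaps on the support, weights permuted.

    The binary support undergoes ``swaps_per_edge * n_edges`` connectivity-
    preserving double-edge swaps; the original nonzero weight multiset is then
    randomly reassigned to the rewired edges.  Serves as the null structural
    matrix in ground-truth recovery experiments.
    """
    rng = np.random.default_rng(seed)
    g = nx.from_numpy_array((c.weights > 0).astype(int))
    m = g.number_of_edges()
    if m < 2:
        return c.copy()
    nswap = swaps_per_edge * m
    try:
        nx.connected_double_edge_swap(g, nswap=nswap,
                                      seed=int(rng.integers(2**31)))
    except nx.NetworkXError:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap,
                            seed=int(rng.integers(2**31)))
    weights = c.weights[np.triu_indices(c.n, k=1)]
    weights = weights[weights > 0]
    rng.shuffle(weights)
    w = np.zeros_like(c.weights)
    for (i, j), wt in zip(g.edges(), weights):
        w[i, j] = w[j, i] = wt
    return Connectome(w, list(c.labels),
                      None if c.hemisphere is None else list(c.hemisphere))


def synth_empirical_fc(true_sc: Connectome, p_base: IsingParams,
                       noise_sd: float, seed: int,
                       W_grid: Optional[Sequence[float]] = None,
                       chunk_size: int = DEFAULT_CHUNK,
                       model: Optional[FCMatrix] = None) -> FCMatrix:
    """Noisy FC derived from the exact model FC of a ground-truth connectome.

    Computes model FC at the edge of bifurcation (or uses a precomputed
    ``model``), adds Gaussian noise of sd ``noise_sd`` to each upper-triangle
    entry on the Fisher-z scale, back-transforms, symmetrizes, clips to
    [-0.999, 0.999] and sets the diagonal to 1.
    """
    if noise_sd < 0:
        raise SynthError(f"noise_sd must be >= 0, got {noise_sd}")
    if model is None:
        model, _ = model_fc(true_sc, p_base, W_grid, chunk_size)
    rng = np.random.default_rng(seed)
    v = model.values.copy()
    iu = np.triu_indices(v.shape[0], k=1)
    z = np.arctanh(np.clip(v[iu], -0.999, 0.999))
    z = z + rng.normal(0.0, noise_sd, size=z.shape)
    noisy = np.clip(np.tanh(z), -0.999, 0.999)
    out = np.eye(v.shape[0])
    out[iu] = noisy
    out = out + out.T - np.diag(np.diag(out))
    return FCMatrix(out, list(model.labels))
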