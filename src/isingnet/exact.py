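"""Exact Boltzmann-Gibbs statistics of the Ising-spin network by full enumeration.

Each node carries a binary unit S in {0, 1}.  A global state alpha is a bitmask
over the N units with energy

    H(S) = 1/2 theta * sum_i S_i  -  1/2 W * sum_{i,j} C_ij S_i S_j

(full double sum over ordered pairs; ``full_theta`` replaces the first term by
theta * sum_i S_i).  The equilibrium law is P(S) = exp(-eps * H(S)) / Z with
inverse temperature eps, and the attractor-landscape entropy is the Shannon
entropy of P, computed via the identity  entropy = eps * <H> + ln Z  (in nats).

Enumeration streams the 2^N bitmasks in chunks with a numerically stable
running-maximum (log-sum-exp) accumulation, so eps * H in the hundreds is safe.
The key economy for coupling sweeps: per state, the activity count
s = sum_i S_i and the quadratic form q = S^T C S depend only on the graph, so a
whole W grid reuses one enumeration pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome

#: Hard cap on exact enumeration; beyond this the caller must subsample nodes.
ENUMERATION_CAP = 28
#: Default number of states per streamed chunk.
DEFAULT_CHUNK = 1 << 16

_CONVENTIONS = ("half_theta", "full_theta")


class EnumerationError(ValueError):
    pass


@dataclass(frozen=True)
class IsingParams:
    """Global parameters of the spin model.

    W : global coupling scale on the connectivity matrix (dimensionless).
    theta : activation threshold (dimensionless); 12 in the reference setting.
    epsilon : inverse temperature, > 0.
    energy_convention : ``half_theta`` uses the 1/2*theta*sum(S) linear term
        (the analytical default); ``full_theta`` uses theta*sum(S), matching the
        literal single-site update rule, for sensitivity checks.
    """

    W: float = 1.0
    theta: float = 12.0
    epsilon: float = 1.0
    energy_convention: str = "half_theta"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.energy_convention not in _CONVENTIONS:
            raise ValueError(
                f"energy_convention must be one of {_CONVENTIONS}"
            )

    @property
    def theta_coeff(self) -> float:
        """Coefficient of sum_i S_i in the energy."""
        return 0.5 * self.theta if self.energy_convention == "half_theta" else self.theta


@dataclass
class BoltzmannSummary:
    """Exact equilibrium summary for one (Connectome, IsingParams) pair.

    All quantities are exact sums over the 2^N states: ``logZ`` the log partition
    function, ``entropy`` the Shannon entropy in nats, ``marginals[i]`` =
    P(S_i = 1), ``joint11[i, j]`` = P(S_i = 1, S_j = 1) and ``meanH`` = <H>.
    """

    logZ: float
    entropy: float
    marginals: np.ndarray
    joint11: np.ndarray
    meanH: float
    params: IsingParams

    @property
    def n(self) -> int:
        return self.marginals.shape[0]

    def entropy_bits(self) -> float:
        return self.entropy / math.log(2.0)


def state_bits(mask: int, n: int) -> np.ndarray:
    """Decode an integer bitmask into a length-n 0/1 vector (bit i = node i)."""
    if not 0 <= mask < (1 << n):
        raise ValueError(f"bitmask {mask} out of range for {n} spins")
    return np.array([(mask >> i) & 1 for i in range(n)], dtype=float)


def energy(state, c: Connectome, p: IsingParams) -> float:
    """Energy of one global state (bitmask int or 0/1 vector)."""
    if isinstance(state, (int, np.integer)):
        s = state_bits(int(state), c.n)
    else:
        s = np.asarray(state, dtype=float)
        if s.shape != (c.n,):
            raise ValueError(f"state has shape {s.shape}, expected ({c.n},)")
    return float(p.theta_coeff * s.sum() - 0.5 * p.W * s @ c.weights @ s)


def _iter_chunks(n: int, chunk_size: int) -> Iterator[np.ndarray]:
    total = 1 << n
    for start in range(0, total, chunk_size):
        stop = min(start + chunk_size, total)
        yield np.arange(start, stop, dtype=np.uint64)


def _chunk_bits(masks: np.ndarray, n: int) -> np.ndarray:
    shifts = np.arange(n, dtype=np.uint64)
    return ((masks[:, None] >> shifts[None, :]) & np.uint64(1)).astype(np.float64)


class _Accumulator:
    """Streaming log-sum-exp accumulator for Z, <H> and (optionally) moments.

    Maintains sums of w = exp(-eps*H - M) for a running maximum M of -eps*H,
    rescaling previous partial sums whenever a new chunk raises M.
    """

    def __init__(self, n: int, moments: bool) -> None:
        self.M = -np.inf
        self.sw = 0.0
        self.sH = 0.0
        self.n = n
        self.moments = moments
        if moments:
            self.sb = np.zeros(n)
            self.sbb = np.zeros((n, n))

    def update(self, H: np.ndarray, eps: float, B: Optional[np.ndarray]) -> None:
        logw = -eps * H
        m = float(logw.max())
        if m > self.M:
            scale = math.exp(self.M - m) if math.isfinite(self.M) else 0.0
            self.sw *= scale
            self.sH *= scale
            if self.moments:
                self.sb *= scale
                self.sbb *= scale
            self.M = m
        w = np.exp(logw - self.M)
        self.sw += float(w.sum())
        self.sH += float(w @ H)
        if self.moments:
            assert B is not None
            self.sb += w @ B
            self.sbb += (B * w[:, None]).T @ B

    def summarize(self, eps: float, params: IsingParams) -> BoltzmannSummary:
        logZ = self.M + math.log(self.sw)
        meanH = self.sH / self.sw
        entropy = eps * meanH + logZ
        if entropy < 0:  # float round-off near a frozen state
            if entropy < -1e-9:
                raise EnumerationError(f"negative entropy {entropy}: accumulation failure")
            entropy = 0.0
        if self.moments:
            marg = self.sb / self.sw
            joint = self.sbb / self.sw
            joint = (joint + joint.T) / 2.0
            np.fill_diagonal(joint, marg)
        else:
            marg = np.full(self.n, np.nan)
            joint = np.full((self.n, self.n), np.nan)
        return BoltzmannSummary(logZ=logZ, entropy=entropy, marginals=marg,
                                joint11=joint, meanH=meanH, params=params)


def _check_enumerable(c: Connectome, chunk_size: int) -> None:
    if c.n > ENUMERATION_CAP:
        raise EnumerationError(
            f"N={c.n} exceeds the enumeration cap {ENUMERATION_CAP}; "
            "subsample nodes before computing exact statistics"
        )
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")


def _stream_summaries(c: Connectome, params_list: Sequence[IsingParams],
                      chunk_size: int, moments: bool) -> list[BoltzmannSummary]:
    """One enumeration pass shared by all parameter sets (same connectome)."""
    _check_enumerable(c, chunk_size)
    n = c.n
    C = c.weights
    accs = [_Accumulator(n, moments) for _ in params_list]
    for masks in _iter_chunks(n, chunk_size):
        B = _chunk_bits(masks, n)
        s = B.sum(axis=1)
        q = np.einsum("si,si->s", B @ C, B)
        if not np.all(np.isfinite(q)):
            raise EnumerationError("non-finite energy encountered")
        for acc, p in zip(accs, params_list):
            H = p.theta_coeff * s - 0.5 * p.W * q
            acc.update(H, p.epsilon, B if moments else None)
    return [acc.summarize(p.epsilon, p) for acc, p in zip(accs, params_list)]


def boltzmann_summary(c: Connectome, p: IsingParams,
                      chunk_size: int = DEFAULT_CHUNK) -> BoltzmannSummary:
    """Exact partition function, entropy, marginals and pairwise joints."""
    return _stream_summaries(c, [p], chunk_size, moments=True)[0]


def entropy_sweep(c: Connectome, p_base: IsingParams, W_grid: Sequence[float],
                  chunk_size: int = DEFAULT_CHUNK) -> pd.DataFrame:
    """Entropy (and logZ, mean energy) at every coupling in an increasing W grid.

    Returns a DataFrame with columns ``W``, ``entropy``, ``logZ``, ``mean_energy``,
    one row per grid point.  A single enumeration pass serves the whole grid.
    """
    W_grid = np.asarray(W_grid, dtype=float)
    if W_grid.size == 0:
        raise ValueError("W grid is empty")
    if W_grid.size > 1 and not np.all(np.diff(W_grid) > 0):
        raise ValueError("W grid must be strictly increasing")
    params = [replace(p_base, W=float(w)) for w in W_grid]
    sums = _stream_summaries(c, params, chunk_size, moments=False)
    return pd.DataFrame({
        "W": W_grid,
        "entropy": [s.entropy for s in sums],
        "logZ": [s.logZ for s in sums],
        "mean_energy": [s.meanH for s in sums],
    })


def find_edge_of_bifurcation(sweep: pd.DataFrame) -> float:
    """Locate the coupling where entropy starts its rapid rise.

    Returns the grid W with the largest forward difference dE/dW on the rising
    flank (grid points at or below the entropy argmax); ties break toward
    smaller W.  Raises on flat or monotone-nonincreasing sweeps and when the
    maximum sits at the first grid point (no rising flank).
    """
    W = np.asarray(sweep["W"], dtype=float)
    E = np.asarray(sweep["entropy"], dtype=float)
    if W.size < 3:
        raise ValueError("need at least 3 grid points")
    if np.ptp(E) < 1e-12:
        raise ValueError("flat entropy sweep: no bifurcation structure")
    k_max = int(np.argmax(E))
    if k_max == 0:
        raise ValueError("entropy maximum at the first grid point: no rising flank")
    dE = np.diff(E[: k_max + 1]) / np.diff(W[: k_max + 1])
    k_star = int(np.argmax(dE))  # argmax returns the first (smallest-W) maximizer
    return float(W[k_star])


def independent_entropy(n: int, p: IsingParams) -> float:
    """Closed-form entropy at W = 0: n * h(p0), p0 = 1 / (1 + e^{eps*theta_coeff}).

    ``h`` is the binary entropy in nats.  Serves as an analytical check on the
    enumeration at zero coupling for any connectome.
    """
    x = p.epsilon * p.theta_coeff
    p0 = 1.0 / (1.0 + math.exp(x))
    if p0 in (0.0, 1.0):
        return 0.0
    h = -p0 * math.log(p0) - (1 - p0) * math.log(1 - p0)
    return n * h
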