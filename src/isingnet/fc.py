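"""Model functional connectivity at the edge of bifurcation, and FC comparison.

Model FC is the exact pairwise spin-correlation matrix evaluated at the coupling
W* where the attractor-landscape entropy starts its rapid rise (the edge of the
bifurcation) — the regime where resting-state correlation structure emerges.
Pattern similarity between two FC matrices is the Pearson (optionally Spearman)
correlation over strictly-upper-triangle entries only; the diagonal and lower
triangle never enter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .connectome import Connectome
from .exact import (DEFAULT_CHUNK, IsingParams, entropy_sweep,
                    find_edge_of_bifurcation)
from .observables import PairStats, pair_stats


class FCError(ValueError):
    pass


@dataclass
class FCMatrix:
    """Symmetric functional-connectivity matrix aligned with a node labelling."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    unit_diagonal: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FCError(f"FC matrix must be square, got {v.shape}")
        if np.abs(v - v.T).max(initial=0.0) > 1e-9:
            raise FCError("FC matrix asymmetric beyond 1e-9")
        v = (v + v.T) / 2.0
        iu = np.triu_indices(v.shape[0], k=1)
        if iu[0].size and (v[iu].max(initial=-1) > 1 or v[iu].min(initial=1) < -1):
            raise FCError("off-diagonal FC values must lie in [-1, 1]")
        np.fill_diagonal(v, 1.0 if self.unit_diagonal else 0.0)
        self.values = v
        if not self.labels:
            self.labels = [str(i) for i in range(v.shape[0])]
        if len(self.labels) != v.shape[0]:
            raise FCError("label count does not match FC dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]


DEFAULT_W_GRID = np.linspace(0.0, 8.0, 33)


def model_fc(c: Connectome, p_base: IsingParams,
             W_grid: Optional[Sequence[float]] = None,
             chunk_size: int = DEFAULT_CHUNK,
             w_offset: float = 0.0) -> tuple[FCMatrix, float]:
    """Exact spin-correlation FC at the edge of bifurcation.

    Sweeps entropy over ``W_grid`` (default 0..8, 33 points), locates W* via the
    steepest-rise criterion, optionally shifts it by ``w_offset``, and returns
    the exact correlation matrix at that coupling together with W*.
    """
    grid = DEFAULT_W_GRID if W_grid is None else np.asarray(W_grid, dtype=float)
    sweep = entropy_sweep(c, p_base, grid, chunk_size)
    w_star = find_edge_of_bifurcation(sweep) + w_offset
    stats = pair_stats(c, replace(p_base, W=float(w_star)), chunk_size)
    return FCMatrix(stats.corr.copy(), list(c.labels)), float(w_star)


def fc_pattern_correlation(model: FCMatrix, empirical: FCMatrix,
                           method: str = "pearson") -> float:
    """Correlation between two FC patterns over the strict upper triangle."""
    if model.n != empirical.n:
        raise FCError(f"dimension mismatch: {model.n} vs {empirical.n}")
    if model.labels != empirical.labels:
        raise FCError("node label order differs between the two FC matrices")
    iu = np.triu_indices(model.n, k=1)
    a, b = model.values[iu], empirical.values[iu]
    if a.size < 2:
        raise FCError("need at least 2 off-diagonal pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise FCError("zero variance in a vectorized upper triangle")
    if method == "pearson":
        r = sps.pearsonr(a, b).statistic
    elif method == "spearman":
        r = sps.spearmanr(a, b).statistic
    else:
        raise FCError("method must be 'pearson' or 'spearman'")
    return float(r)
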