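"""Structural / functional connectivity matrices: containers, validation, plain-text I/O.

The central object is :class:`Connectome`: a symmetric, non-negative, zero-diagonal
weighted adjacency matrix ``C`` over ``N`` labelled nodes, optionally carrying a
per-node hemisphere tag.  Symmetry is required because diffusion tractography cannot
resolve fibre directionality, and because the Boltzmann-Gibbs stationary law of the
spin model only holds for symmetric couplings.

Supported on-disk formats are deliberately plain text:

* ``matrix-csv`` / ``matrix-tsv`` — a square numeric matrix, optionally preceded by a
  single header row of node labels;
* ``edge-list`` — one undirected edge per line as ``i j weight`` (whitespace or
  comma separated; weight defaults to 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

#: Maximum tolerated |C_ij - C_ji| before a matrix is rejected as directed.
SYMMETRY_TOL = 1e-9

_FORMATS = ("matrix-csv", "matrix-tsv", "edge-list")


class ConnectomeError(ValueError):
    """Base class for connectivity-matrix validation failures."""


class NonSquareError(ConnectomeError):
    pass


class NonNumericError(ConnectomeError):
    pass


class NegativeWeightError(ConnectomeError):
    pass


class AsymmetryError(ConnectomeError):
    pass


class DiagonalError(ConnectomeError):
    pass


@dataclass
class Connectome:
    """A validated symmetric weighted graph over labelled nodes.

    Parameters
    ----------
    weights
        ``(N, N)`` non-negative real matrix; symmetrized as ``(A + A.T) / 2`` if the
        asymmetry is within :data:`SYMMETRY_TOL`, rejected otherwise.
    labels
        ``N`` node identifiers; defaults to 0-based indices as strings.
    hemisphere
        Optional per-node tag, each ``"left"`` or ``"right"``; must cover all nodes.
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)
    hemisphere: Optional[list[str]] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise NonNumericError(f"non-finite weight at row {i}, column {j}")
        asym = np.abs(w - w.T)
        if asym.size and asym.max() > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise AsymmetryError(
                f"asymmetry {asym[i, j]:.3g} at row {i}, column {j} "
                f"exceeds tolerance {SYMMETRY_TOL}"
            )
        w = (w + w.T) / 2.0
        if w.size and w.min() < 0:
            i, j = np.argwhere(w < 0)[0]
            raise NegativeWeightError(f"negative weight at row {i}, column {j}")
        diag = np.abs(np.diag(w))
        if diag.size and diag.max() > 0:
            i = int(np.argmax(diag))
            raise DiagonalError(f"nonzero diagonal entry at row {i}, column {i}")
        self.weights = w
        n = w.shape[0]
        if not self.labels:
            self.labels = [str(i) for i in range(n)]
        if len(self.labels) != n:
            raise ConnectomeError(
                f"{len(self.labels)} labels for {n} nodes"
            )
        if self.hemisphere is not None:
            if len(self.hemisphere) != n:
                raise ConnectomeError("hemisphere tags must cover all nodes")
            bad = set(self.hemisphere) - {"left", "right"}
            if bad:
                raise ConnectomeError(f"unknown hemisphere tags: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges (nonzero upper-triangle entries)."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def degree(self) -> np.ndarray:
        """Unweighted degree of each node."""
        return (self.weights > 0).sum(axis=1)

    def is_binary(self) -> bool:
        return bool(np.all((self.weights == 0) | (self.weights == 1)))

    def copy(self) -> "Connectome":
        return Connectome(
            self.weights.copy(),
            list(self.labels),
            None if self.hemisphere is None else list(self.hemisphere),
        )


def _parse_token(tok: str, row: int, col: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise NonNumericError(
            f"non-numeric cell {tok!r} at row {row}, column {col}"
        ) from None


def _split_line(line: str, delim: Optional[str]) -> list[str]:
    if delim is None:
        return line.replace(",", " ").split()
    return [t.strip() for t in line.split(delim)]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "matrix-tsv"
    if suffix == ".csv":
        return "matrix-csv"
    # Sniff: a square block of rows looks like a matrix, 2-3 columns like edges.
    with open(path) as fh:
        rows = [ln for ln in (l.strip() for l in fh) if ln and not ln.startswith("#")]
    if rows and len(_split_line(rows[0], None)) in (2, 3) and len(rows) != len(
        _split_line(rows[0], None)
    ):
        return "edge-list"
    return "matrix-csv"


def read_connectome(path, fmt: Optional[str] = None) -> Connectome:
    """Read a connectivity matrix from a plain-text file.

    Parameters
    ----------
    path
        File containing either a square numeric matrix (optional label header row)
        or a 3-column undirected edge list ``i j weight``.
    fmt
        One of ``matrix-csv``, ``matrix-tsv``, ``edge-list``; inferred from the file
        suffix / shape when omitted.

    Returns
    -------
    Connectome
        Validated; edge lists are symmetrized by mirroring each entry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    with open(path) as fh:
        lines = [ln for ln in (l.rstrip("\n") for l in fh) if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ConnectomeError(f"{path}: empty file")
    if fmt == "edge-list":
        return _read_edge_list(lines)
    delim = "\t" if fmt == "matrix-tsv" else ","
    rows = [_split_line(ln, delim) for ln in lines]
    labels: list[str] = []
    width = len([t for t in rows[0] if t != ""])
    # a label header row (numeric labels included) shows up as one extra row
    if len(rows) == width + 1 and all(
            len([t for t in r if t != ""]) == width for r in rows):
        labels = [t for t in rows[0] if t != ""]
        rows = rows[1:]
    n = len(rows)
    mat = np.empty((n, max(len(r) for r in rows)))
    for i, r in enumerate(rows):
        toks = [t for t in r if t != ""]
        if len(toks) != n:
            raise NonSquareError(
                f"row {i} has {len(toks)} entries but the matrix has {n} rows"
            )
        for j, tok in enumerate(toks):
            mat[i, j] = _parse_token(tok, i, j)
    mat = mat[:, :n]
    return Connectome(mat, labels=labels)


def _read_edge_list(lines: Sequence[str]) -> Connectome:
    entries: list[tuple[str, str, float]] = []
    names: dict[str, int] = {}
    all_int = True
    for k, ln in enumerate(lines):
        toks = _split_line(ln, None)
        if len(toks) not in (2, 3):
            raise ConnectomeError(
                f"edge-list row {k}: expected 'i j [weight]', got {len(toks)} tokens"
            )
        w = _parse_token(toks[2], k, 2) if len(toks) == 3 else 1.0
        i, j = toks[0], toks[1]
        all_int = all_int and i.lstrip("-").isdigit() and j.lstrip("-").isdigit()
        entries.append((i, j, w))
        for name in (i, j):
            if name not in names:
                names[name] = len(names)
    if all_int:
        idx = {name: int(name) for name in names}
        n = max(idx.values()) + 1
        labels = [str(i) for i in range(n)]
    else:
        idx = names
        n = len(names)
        labels = list(names)
    mat = np.zeros((n, n))
    for k, (i, j, w) in enumerate(entries):
        if w < 0:
            raise NegativeWeightError(f"negative weight at edge-list row {k}")
        a, b = idx[i], idx[j]
        mat[a, b] = w
        mat[b, a] = w
    np.fill_diagonal(mat, 0.0)
    return Connectome(mat, labels=labels)


def write_matrix(m: np.ndarray, path, fmt: str = "matrix-csv",
                 labels: Optional[Sequence[str]] = None) -> None:
    """Write a numeric matrix as CSV/TSV, round-tripping through ``read`` to 1e-12.

    Values are written with 17 significant digits so the round trip is exact for
    doubles.  ``labels`` adds a single header row.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite entries")
    delim = "\t" if fmt == "matrix-tsv" else ","
    path = Path(path)
    with open(path, "w") as fh:
        if labels is not None:
            fh.write(delim.join(str(l) for l in labels) + "\n")
        for row in np.atleast_2d(m):
            fh.write(delim.join(f"{v:.17g}" for v in row) + "\n")


def write_table(columns: dict[str, Sequence], path, fmt: str = "matrix-tsv") -> None:
    """Write named columns as a headed TSV/CSV table (e.g. an entropy sweep)."""
    delim = "\t" if fmt == "matrix-tsv" else ","
    keys = list(columns)
    n = len(columns[keys[0]])
    with open(path, "w") as fh:
        fh.write(delim.join(keys) + "\n")
        for i in range(n):
            fh.write(delim.join(f"{columns[k][i]:.17g}" if isinstance(columns[k][i], float)
                                else str(columns[k][i]) for k in keys) + "\n")


def binarize(c: Connectome, threshold: float = 0.0) -> Connectome:
    """Threshold weights to {0, 1}: 1 where weight > threshold, else 0."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    w = (c.weights > threshold).astype(float)
    np.fill_diagonal(w, 0.0)
    return Connectome(w, list(c.labels),
                      None if c.hemisphere is None else list(c.hemisphere))


def split_hemispheres(c: Connectome) -> tuple[Connectome, Connectome]:
    """Split into two intra-hemisphere Connectomes (left first).

    Uses hemisphere tags when present; otherwise assumes the center-symmetric
    ordering (first half = left, second half = right), which requires even ``N``.
    """
    if c.hemisphere is not None:
        left_idx = [i for i, h in enumerate(c.hemisphere) if h == "left"]
        right_idx = [i for i, h in enumerate(c.hemisphere) if h == "right"]
        if not left_idx or not right_idx:
            raise ConnectomeError("hemisphere tags do not bipartition the nodes")
    else:
        if c.n % 2:
            raise ConnectomeError(
                f"cannot split {c.n} nodes without hemisphere tags (odd N)"
            )
        half = c.n // 2
        left_idx = list(range(half))
        right_idx = list(range(half, c.n))

    def _sub(idx: list[int], tag: str) -> Connectome:
        w = c.weights[np.ix_(idx, idx)].copy()
        return Connectome(w, [c.labels[i] for i in idx], [tag] * len(idx))

    return _sub(left_idx, "left"), _sub(right_idx, "right")
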