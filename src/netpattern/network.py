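"""Regular cell-communication networks, balanced colorings, polysynchrony subspaces.

A *regular* network is a directed multigraph in which every node receives the
same number of input arrows (the valence, ``nu``).  Cells are nodes; arrows are
directed communication channels, and an arrow may be repeated to express a
stronger coupling (integer "connection strength").

Adjacency convention
--------------------
``A[i, j]`` counts arrows from node ``j`` *into* node ``i`` (row = target).
Many graph libraries use the transpose; every spectrum computed in this
package is of the matrix with this row-=-target orientation, so that the row
sums of ``A`` all equal the valence.

Node indices are 0-based in memory and 1-based in every file format and
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np


class NetworkError(ValueError):
    """Raised for structurally invalid network constructions."""


@dataclass(frozen=True)
class RegularNetwork:
    """A directed multigraph with integer arrow counts.

    Parameters
    ----------
    counts:
        Integer matrix with ``counts[i, j]`` = number of arrows ``j -> i``.
    node_labels:
        Optional human-readable node names (external reports use these or
        1-based indices).
    lattice_meta:
        ``(rows, cols, stencil)`` for lattice-built networks, else ``None``.
    """

    counts: np.ndarray
    node_labels: tuple[str, ...] | None = None
    lattice_meta: tuple | None = None
    strict: bool = field(default=True, repr=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise NetworkError("arrow-count matrix must be square")
        if (counts < 0).any():
            raise NetworkError("arrow counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        if self.strict:
            if np.any(np.diag(counts) != 0):
                raise NetworkError("self-arrows are not allowed")
            insum = counts.sum(axis=1)
            if not np.all(insum == insum[0]):
                raise NetworkError(
                    "network is not regular; input-arrow counts per node: "
                    f"{insum.tolist()}"
                )

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]

    @property
    def valence(self) -> int:
        """Common number of input arrows per node (row sum of the adjacency)."""
        return int(self.counts.sum(axis=1).max())

    @classmethod
    def from_adjacency(cls, A, strict: bool = True, **kw) -> "RegularNetwork":
        return cls(np.asarray(A, dtype=int), strict=strict, **kw)

    @classmethod
    def from_arrows(cls, n: int, arrows, strict: bool = True, **kw) -> "RegularNetwork":
        """Build from an iterable of ``(source, target[, count])`` 0-based tuples."""
        counts = np.zeros((n, n), dtype=int)
        for arrow in arrows:
            if len(arrow) == 2:
                s, t, c = *arrow, 1
            else:
                s, t, c = arrow
            counts[t, s] += int(c)
        return cls(counts, strict=strict, **kw)


def build_reflective_row(n: int, weight: int = 1) -> RegularNetwork:
    """A line of ``n`` cells with reflective ends.

    Interior cell ``i`` receives ``weight`` arrows from each of its two
    neighbours; each end cell receives ``2*weight`` arrows from its sole
    neighbour, so the network is regular with valence ``2*weight``.  This is
    the communication architecture of the six C. elegans vulval precursor
    cells under a let-23 mutation (every cell sees the same external signal).
    """
    if n < 2:
        raise NetworkError("a reflective row needs at least 2 cells")
    if weight < 1:
        raise NetworkError("weight must be a positive integer")
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        if i == 0:
            counts[i, 1] = 2 * weight
        elif i == n - 1:
            counts[i, n - 2] = 2 * weight
        else:
            counts[i, i - 1] = weight
            counts[i, i + 1] = weight
    return RegularNetwork(counts, node_labels=tuple(f"P{i+1}" for i in range(n)))


def build_torus_lattice(
    rows: int, cols: int, stencil: Mapping[tuple[int, int], int]
) -> RegularNetwork:
    """A ``rows x cols`` array of cells with periodic boundary conditions.

    ``stencil`` maps a relative offset ``(dr, dc) != (0, 0)`` to a positive
    arrow count: cell ``(r, c)`` receives ``stencil[(dr, dc)]`` arrows from
    cell ``((r+dr) % rows, (c+dc) % cols)``.  Node order is row-major.
    """
    if rows < 1 or cols < 1:
        raise NetworkError("lattice dimensions must be >= 1")
    if not stencil:
        raise NetworkError("stencil must be non-empty")
    n = rows * cols
    counts = np.zeros((n, n), dtype=int)
    for (dr, dc), w in stencil.items():
        if (dr % rows, dc % cols) == (0, 0):
            raise NetworkError(f"stencil offset {(dr, dc)} wraps to a self-arrow")
        if int(w) <= 0:
            raise NetworkError(f"stencil weight for {(dr, dc)} must be positive")
        for r in range(rows):
            for c in range(cols):
                src = ((r + dr) % rows) * cols + (c + dc) % cols
                counts[r * cols + c, src] += int(w)
    return RegularNetwork(
        counts, lattice_meta=(rows, cols, dict(stencil))
    )


def notch_lattice_stencil() -> dict[tuple[int, int], int]:
    """Nearest-neighbour weight 3, diagonal-neighbour weight 1 stencil.

    On any even-sided torus this stencil's smallest adjacency eigenvalue is
    simple with the checkerboard eigenvector, so lateral inhibition predicts
    a checkerboard fate pattern.  Valence 4*3 + 4*1 = 16.
    """
    stencil = {}
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        stencil[(dr, dc)] = 3
    for dr, dc in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        stencil[(dr, dc)] = 1
    return stencil


def adjacency_matrix(net: RegularNetwork) -> np.ndarray:
    """The integer adjacency matrix, ``A[i, j]`` = arrows ``j -> i``."""
    return net.counts.copy()


def validate_network(net: RegularNetwork) -> dict:
    """Report-only structural diagnostics.

    Strong connectivity is computed on the directed graph ignoring arrow
    multiplicities; a single-node network is vacuously strongly connected.
    """
    counts = net.counts
    insum = counts.sum(axis=1)
    g = nx.from_numpy_array(counts.T, create_using=nx.DiGraph)
    return {
        "n_nodes": net.n_nodes,
        "valence": int(insum.max()),
        "input_counts": insum.tolist(),
        "is_regular": bool(np.all(insum == insum[0])),
        "has_self_arrows": bool(np.any(np.diag(counts) != 0)),
        "is_strongly_connected": net.n_nodes == 1
        or nx.is_strongly_connected(g),
    }


@dataclass(frozen=True)
class Coloring:
    """Map node index -> color id in ``{1..k}`` (contiguous ids)."""

    assignment: tuple[int, ...]

    def __post_init__(self):
        assignment = tuple(int(c) for c in self.assignment)
        object.__setattr__(self, "assignment", assignment)
        k = max(assignment, default=0)
        if sorted(set(assignment)) != list(range(1, k + 1)):
            raise NetworkError("color ids must be contiguous starting at 1")

    @property
    def k(self) -> int:
        return max(self.assignment)

    @property
    def n_nodes(self) -> int:
        return len(self.assignment)


def is_balanced(net: RegularNetwork, coloring: Coloring) -> bool:
    """True iff same-colored nodes receive identical multisets of input colors.

    Balanced colorings are exactly those whose polysynchrony subspace is
    flow-invariant under every admissible ODE of the network.
    """
    if coloring.n_nodes != net.n_nodes:
        raise NetworkError(
            f"coloring covers {coloring.n_nodes} nodes, network has {net.n_nodes}"
        )
    colors = np.asarray(coloring.assignment)
    # signature[i, c-1] = number of input arrows to i from nodes of color c
    k = coloring.k
    member = np.zeros((net.n_nodes, k), dtype=int)
    member[np.arange(net.n_nodes), colors - 1] = 1
    signature = net.counts @ member
    for c in range(1, k + 1):
        sigs = signature[colors == c]
        if len(sigs) > 1 and np.any(sigs != sigs[0]):
            return False
    return True


def polysynchrony_basis(coloring: Coloring, node_dim: int = 1) -> np.ndarray:
    """Indicator basis of the polysynchrony subspace in ``R^(n*s)``.

    Returns ``(k*s, n*s)`` rows: one 0/1 indicator per (color, node-space
    coordinate), mutually orthogonal.  The total state is ordered node-major:
    coordinates ``i*s .. i*s+s-1`` belong to node ``i``.
    """
    if node_dim < 1:
        raise NetworkError("node dimension must be >= 1")
    n, s, k = coloring.n_nodes, node_dim, coloring.k
    colors = np.asarray(coloring.assignment)
    basis = np.zeros((k * s, n * s))
    for c in range(1, k + 1):
        nodes = np.flatnonzero(colors == c)
        for a in range(s):
            basis[(c - 1) * s + a, nodes * s + a] = 1.0
    return basis


def coloring_from_pattern_vector(v, tol: float = 1e-6) -> Coloring:
    """Group equal entries of a pattern vector into a coloring.

    Entries agreeing within ``tol * max|v|`` share a color; colors are
    numbered by decreasing entry value (color 1 = highest state).  This maps
    a critical eigenvector to the balanced coloring of the pattern it
    predicts.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise NetworkError("pattern vector must be finite")
    scale = np.max(np.abs(v)) if v.size else 0.0
    atol = tol * max(scale, 1e-300)
    order = np.argsort(-v)  # decreasing
    colors = np.empty(len(v), dtype=int)
    current = 0
    prev = None
    for idx in order:
        if prev is None or prev - v[idx] > atol:
            current += 1
        colors[idx] = current
        prev = v[idx]
    return Coloring(tuple(colors.tolist()))
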