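"""Eigen-analysis of adjacency matrices and real pattern spaces.

For a regular network with adjacency matrix ``A`` (row = target convention),
the distinct eigenvalues ``mu_1, ..., mu_k`` sorted by ascending real part
index the *pattern spaces* ``P_mu_j`` = real span of the eigenvectors of
``mu_j``.  By Perron-Frobenius, on a strongly connected regular network the
largest eigenvalue ``mu_k`` equals the valence, is simple, and has the
all-ones eigenvector: ``P_mu_k`` is the fully synchronous direction.  The
smallest eigenvalue's space ``P_mu_1`` carries the fine-grained
(lateral-inhibition) patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .network import RegularNetwork, adjacency_matrix


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class SpectralDecomposition:
    """Distinct eigenvalues of an adjacency matrix with real eigenspace bases.

    Attributes
    ----------
    eigenvalues:
        Distinct complex eigenvalues sorted ascending by real part (ties by
        imaginary part).  ``mu_1 = eigenvalues[0]``, ``mu_k = eigenvalues[-1]``.
    alg_mult, geo_mult:
        Algebraic and geometric multiplicities per distinct eigenvalue.
    bases:
        Per distinct eigenvalue, a real ``(dim, n)`` array spanning the real
        form of its (generalized, if defective) eigenspace.  For a complex
        pair the rows are real/imaginary parts of the complex eigenvectors.
    defective:
        Flags eigenvalues whose basis includes generalized eigenvectors.
    """

    eigenvalues: tuple[complex, ...]
    alg_mult: tuple[int, ...]
    geo_mult: tuple[int, ...]
    bases: tuple[np.ndarray, ...]
    defective: tuple[bool, ...]
    valence: int
    all_real: bool
    spectral_radius: float
    n: int

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    @property
    def mu1(self) -> complex:
        return self.eigenvalues[0]

    @property
    def muk(self) -> complex:
        return self.eigenvalues[-1]

    def real_parts(self) -> np.ndarray:
        return np.array([ev.real for ev in self.eigenvalues])


@dataclass(frozen=True)
class PatternSpace:
    """A real subspace of R^n spanned by adjacency eigenvectors."""

    label: str
    basis: np.ndarray  # (dim, n)
    dim: int


def _real_span(vectors: np.ndarray, tol: float) -> np.ndarray:
    """Orthonormal real basis (rows) of the real span of complex columns."""
    stacked = np.hstack([vectors.real, vectors.imag])
    # drop numerically-zero columns, then orthonormalize
    norms = np.linalg.norm(stacked, axis=0)
    stacked = stacked[:, norms > tol]
    q = linalg.orth(stacked, rcond=tol)
    return q.T


def spectral_decomposition(
    A, tol: float = 1e-8
) -> SpectralDecomposition:
    """Distinct-eigenvalue decomposition of a regular adjacency matrix.

    Two computed eigenvalues are the same distinct eigenvalue when their
    difference is within ``tol * max(1, rho(A))``.  Geometric multiplicity is
    the rank deficiency of ``A - mu I`` at the same tolerance.  A symmetric
    matrix is routed to the symmetric solver.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise SpectralError("adjacency matrix must be square")
    n = A.shape[0]
    rowsums = A.sum(axis=1)
    if not np.allclose(rowsums, rowsums[0]):
        raise SpectralError("matrix is not regular (unequal row sums)")
    valence = int(round(rowsums[0]))

    symmetric = np.allclose(A, A.T)
    if symmetric:
        raw = linalg.eigvalsh(A).astype(complex)
    else:
        raw = linalg.eigvals(A)

    rho = float(np.max(np.abs(raw))) if n else 0.0
    group_tol = tol * max(1.0, rho)

    # sort by (real, imag) then cluster
    order = np.lexsort((raw.imag, raw.real))
    raw = raw[order]
    groups: list[list[complex]] = []
    for ev in raw:
        if groups and abs(ev - np.mean(groups[-1])) <= group_tol:
            groups[-1].append(ev)
        else:
            groups.append([ev])

    eigenvalues, alg, geo, bases, defective = [], [], [], [], []
    for grp in groups:
        mu = complex(np.mean(grp))
        if abs(mu.imag) <= group_tol:
            mu = complex(mu.real, 0.0)
        a = len(grp)
        M = A - mu * np.eye(n)
        null = linalg.null_space(M, rcond=tol)
        g = null.shape[1]
        vecs = null.astype(complex)
        is_def = g < a
        if is_def:
            # generalized eigenvectors: null space of (A - mu I)^n
            Mg = np.linalg.matrix_power(M, n)
            vecs = linalg.null_space(Mg, rcond=tol).astype(complex)
        basis = _real_span(vecs, tol)
        eigenvalues.append(mu)
        alg.append(a)
        geo.append(max(g, 1))
        bases.append(basis)
        defective.append(bool(is_def))

    all_real = all(abs(ev.imag) <= group_tol for ev in eigenvalues)
    return SpectralDecomposition(
        eigenvalues=tuple(eigenvalues),
        alg_mult=tuple(alg),
        geo_mult=tuple(geo),
        bases=tuple(bases),
        defective=tuple(defective),
        valence=valence,
        all_real=all_real,
        spectral_radius=rho,
        n=n,
    )


def decompose_network(net: RegularNetwork, tol: float = 1e-8) -> SpectralDecomposition:
    return spectral_decomposition(adjacency_matrix(net), tol=tol)


def pattern_space(dec: SpectralDecomposition, j) -> PatternSpace:
    """The pattern space ``P_mu_j`` (``j`` 1-based) or a symbolic combination.

    ``j`` may be an integer index, or one of the labels ``"P_mu1"``,
    ``"P_muk"``, ``"sum"`` (``P_mu1 (+) P_muk``) and ``"R^n"``.  For ``mu_k``
    the basis is the all-ones direction (Perron eigenvector of a regular
    network).
    """
    if isinstance(j, str):
        label = j
        if label == "P_mu1":
            idx = 1
        elif label == "P_muk":
            idx = dec.k
        elif label == "sum":
            b1 = pattern_space(dec, 1).basis
            bk = pattern_space(dec, dec.k).basis
            basis = np.vstack([b1, bk])
            return PatternSpace("P_mu1 ⊕ P_muk", basis, basis.shape[0])
        elif label == "R^n":
            return PatternSpace("R^n", np.eye(dec.n), dec.n)
        else:
            raise SpectralError(f"unknown pattern-space label {label!r}")
    else:
        idx = int(j)
    if not 1 <= idx <= dec.k:
        raise SpectralError(f"eigenvalue index {idx} out of range 1..{dec.k}")
    if idx == dec.k:
        ones = np.ones((1, dec.n)) / np.sqrt(dec.n)
        return PatternSpace("P_muk", ones, 1)
    label = "P_mu1" if idx == 1 else f"P_mu{idx}"
    basis = dec.bases[idx - 1]
    return PatternSpace(label, basis, basis.shape[0])


def perron_report(dec: SpectralDecomposition, valence: int | None = None) -> dict:
    """Structural sanity checks from Perron-Frobenius theory.

    On a strongly connected, self-arrow-free regular network all five flags
    are true; a false flag signals an upstream construction bug.
    """
    nu = dec.valence if valence is None else valence
    tol = 1e-8 * max(1.0, dec.spectral_radius)
    muk = dec.muk
    ones = np.ones(dec.n) / np.sqrt(dec.n)
    bk = pattern_space(dec, dec.k).basis
    ones_in = project_pattern(ones, PatternSpace("P_muk", bk, bk.shape[0])) > 1 - 1e-8
    trace = sum(ev * a for ev, a in zip(dec.eigenvalues, dec.alg_mult))
    return {
        "largest_is_simple": dec.alg_mult[-1] == 1,
        "largest_equals_valence": abs(muk - nu) <= tol,
        "ones_is_eigenvector": bool(ones_in),
        "exists_negative_real_part": dec.mu1.real < -tol,
        "trace_is_zero": abs(trace) <= 1e-9 * dec.n * max(nu, 1),
    }


def project_pattern(v, space: PatternSpace) -> float:
    """Fraction of ``|v|^2`` captured by the orthogonal projection onto the space."""
    v = np.asarray(v, dtype=float).ravel()
    nv2 = float(v @ v)
    if nv2 == 0.0:
        raise SpectralError("cannot project the zero vector")
    q = linalg.orth(space.basis.T)
    coeffs = q.T @ v
    return float(coeffs @ coeffs) / nv2
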