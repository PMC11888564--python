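"""Randomized constructed bifurcations for validating the classifiers.

Every generator here builds a *bona fide* bifurcation point — numeric
``(Q, R)`` together with an adjacency spectrum such that the synchronous
state is marginally stable with an exactly critical block — so that the sign
classifiers can be checked against direct eigencomputation of every block
``Q + mu_i R`` (the brute-force oracle, which never consults trace/sign
logic).

Construction routes
-------------------
* steady rows (pattern spaces ``P_mu1`` / ``P_muk`` with real criticals):
  rank-1 *trace-free* ``R`` keeps ``tr(Q + mu t R)`` pinned at ``tr Q < 0``
  while ``det(Q + mu t R) = det Q + mu t B`` sweeps linearly; scaling ``t``
  to the first determinant root lands exactly on the ``B > 0`` (critical
  ``mu_1``) or ``B < 0`` (critical ``mu_k``) case.
* Hopf rows: rank-1 ``R`` with ``B = 0`` (one linear condition on the
  right factor) keeps every block determinant at ``det Q > 0`` while the
  trace sweeps; the sign of ``tr R`` selects the ``mu_1`` or ``mu_k`` Hopf.
* ``det R <= 0`` sweeps: arbitrary ``R`` of that class scaled until the
  first stability loss (bisection on the binding margin).
"""

from __future__ import annotations

import numpy as np

from .bifurcation import LocalDynamics, jacobian_full, sync_stability
from .network import RegularNetwork
from .spectral import SpectralDecomposition, decompose_network


def random_regular_network(
    rng: np.random.Generator, n_max: int = 8, n_perms: int = 3, w_max: int = 3
) -> RegularNetwork:
    """Random regular digraph: a weighted sum of derangement permutations.

    Every permutation matrix contributes its weight to each node's input
    count, so the sum is automatically regular; derangements avoid
    self-arrows.
    """
    n = int(rng.integers(3, n_max + 1))
    counts = np.zeros((n, n), dtype=int)
    for _ in range(int(n_perms)):
        while True:
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                break
        w = int(rng.integers(1, w_max + 1))
        counts[perm, np.arange(n)] += w
    return RegularNetwork(counts)


def random_real_spectrum_network(
    rng: np.random.Generator, n_max: int = 8
) -> tuple[RegularNetwork, SpectralDecomposition]:
    """Random regular network with an all-real spectrum (symmetrized arrows)."""
    while True:
        net = random_regular_network(rng, n_max=n_max)
        sym = net.counts + net.counts.T  # symmetric -> real spectrum, still regular
        net = RegularNetwork(sym)
        dec = decompose_network(net)
        if dec.all_real and dec.k >= 2:
            return net, dec


def _random_stable_Q(rng: np.random.Generator) -> np.ndarray:
    """2x2 with negative trace and positive determinant (stable block at R=0)."""
    while True:
        Q = rng.normal(scale=1.0, size=(2, 2))
        Q[0, 0] = -abs(Q[0, 0]) - 0.3
        Q[1, 1] = -abs(Q[1, 1]) - 0.3
        if np.linalg.det(Q) > 0.05:
            return Q


def construct_steady_bifurcation(
    dec: SpectralDecomposition, rng: np.random.Generator, at_mu1: bool
) -> LocalDynamics:
    """Row ``B>0`` (critical ``mu_1``) or ``B<0`` (critical ``mu_k``) point.

    ``R`` is rank-1 and trace-free, so ``det R = 0``, every block trace stays
    at ``tr Q < 0`` (the trace NDG condition holds trivially), and scaling
    ``R`` moves only the block determinants.
    """
    mu1 = dec.mu1.real
    muk = dec.muk.real
    while True:
        Q = _random_stable_Q(rng)
        u = rng.normal(size=2)
        # v orthogonal to u makes R = u v^T trace-free and rank 1
        v = np.array([-u[1], u[0]])
        R1 = np.outer(u, v)
        B1 = float(np.trace(Q) * np.trace(R1) - np.trace(Q @ R1))
        if abs(B1) < 1e-3:
            continue
        if (B1 > 0) != at_mu1:
            R1, B1 = -R1, -B1
        mu_t = mu1 if at_mu1 else muk
        t = np.linalg.det(Q) / (-mu_t * B1)
        if t <= 0:
            continue
        dyn = LocalDynamics(Q, t * R1)
        if sync_stability(dyn, dec)["binding_margin"] > -1e-9:
            return dyn


def construct_hopf_bifurcation(
    dec: SpectralDecomposition, rng: np.random.Generator, at_mu1: bool
) -> LocalDynamics:
    """Hopf-onset point: rank-1 ``R`` with ``B = 0`` and ``tr R`` of chosen sign.

    With ``B = 0`` every block determinant equals ``det Q > 0`` (the
    determinant NDG condition), so the first crossing is a complex pair from
    the block trace; ``tr R < 0`` makes it the ``mu_1`` block, ``tr R > 0``
    the ``mu_k`` block.
    """
    mu1 = dec.mu1.real
    muk = dec.muk.real
    while True:
        Q = _random_stable_Q(rng)
        u = rng.normal(size=2)
        # B(u v^T) = tr(Q)(u.v) - v.(Q u) = v.(tr(Q) u - Q u): pick v in its kernel
        c = np.trace(Q) * u - Q @ u
        if np.linalg.norm(c) < 1e-8:
            continue
        v = np.array([-c[1], c[0]])
        R1 = np.outer(u, v)
        trR1 = float(np.trace(R1))
        if abs(trR1) < 1e-3:
            continue
        want_neg = at_mu1
        if (trR1 < 0) != want_neg:
            R1, trR1 = -R1, -trR1
        mu_t = mu1 if at_mu1 else muk
        t = -np.trace(Q) / (mu_t * trR1)
        if t <= 0:
            continue
        dyn = LocalDynamics(Q, t * R1)
        if sync_stability(dyn, dec)["binding_margin"] > -1e-9:
            return dyn


def construct_detR_nonpositive_bifurcation(
    dec: SpectralDecomposition, rng: np.random.Generator
) -> LocalDynamics | None:
    """First stability loss under scaling of a random ``det R <= 0`` coupling.

    Returns the marginal dynamics, or ``None`` when no crossing occurs within
    the scan range (possible for couplings that only stabilize).
    """
    Q = _random_stable_Q(rng)
    if rng.random() < 0.5:
        while True:  # indefinite R -> det R < 0
            R1 = rng.normal(size=(2, 2))
            if np.linalg.det(R1) < -1e-3:
                break
    else:  # rank-1 -> det R = 0
        R1 = np.outer(rng.normal(size=2), rng.normal(size=2))

    def margin(t):
        return sync_stability(LocalDynamics(Q, t * R1), dec)["binding_margin"]

    t_hi = None
    t = 0.05
    while t <= 50.0:
        if margin(t) <= 0:
            t_hi = t
            break
        t *= 1.6
    if t_hi is None:
        return None
    t_lo = t_hi / 1.6 if t_hi > 0.05 else 0.0
    for _ in range(80):  # bisect to the marginal point
        mid = 0.5 * (t_lo + t_hi)
        if margin(mid) > 0:
            t_lo = mid
        else:
            t_hi = mid
    return LocalDynamics(Q, 0.5 * (t_lo + t_hi) * R1)


def construct_1d_sweep(
    dec: SpectralDecomposition, rng: np.random.Generator, sign: int
) -> LocalDynamics:
    """Scalar-node bifurcation: stable ``Q`` swept up until the first crossing.

    ``sign`` picks the sign of ``R`` (0 allowed).  The marginal point is
    ``Q = -max_i(mu_i R)``, where the maximizing block is the critical one.
    """
    r = 0.0 if sign == 0 else sign * float(rng.uniform(0.2, 2.0))
    mus = dec.real_parts()
    q_crit = -max(mus * r) if r != 0 else 0.0
    return LocalDynamics(np.array([[q_crit]]), np.array([[r]]))


def prop2_trial(
    rng: np.random.Generator, n_max: int = 8
) -> float:
    """One block-decomposition oracle trial; returns the multiset distance."""
    net = random_regular_network(rng, n_max=n_max)
    s = int(rng.integers(1, 3))
    dyn = LocalDynamics(rng.normal(size=(s, s)), rng.normal(size=(s, s)))
    _, rep = jacobian_full(dyn, net.counts)
    return rep["multiset_distance"]
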