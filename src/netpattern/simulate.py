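"""Admissible ODE simulation on regular networks under a quasistatic ramp.

The reference kinetics are Collier-style Delta-Notch lateral inhibition with
node state ``(D, N)``::

    dD/dt = lambda * g(N) - gamma_D * D      g decreasing  (Notch -| Delta)
    dN/dt = F(w_D)       - gamma_N * N       F increasing  (neighbour Delta -> Notch)

where ``w_D`` is the *average* Delta concentration over a cell's input
neighbours and the coupling gain ``lambda`` is the bifurcation parameter
(a morphogen-like signal).  Defaults::

    g(N) = 1 / (1 + (N / K_D)^h_D)          h_D = 2, K_D = 0.1
    F(w) = w^h_N / (K_N + w^h_N)            h_N = 2, K_N = 0.1
    gamma_D = gamma_N = 1

Any smooth kinetics with the same sign structure — internal Jacobian
``((-,-),(0,-))``, coupled Jacobian ``((0,0),(+,0))`` — belong to the same
qualitative class and lead to the same classification.

Because cells average their inputs, the per-input-arrow coupled derivative is
``(1/nu)`` times the derivative with respect to the average; ``linearize``
folds that factor in so that the raw arrow-count adjacency spectrum can be
used unmodified in the block matrices ``Q + mu_j R``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .bifurcation import LocalDynamics
from .network import RegularNetwork, adjacency_matrix
from .spectral import SpectralDecomposition, pattern_space, project_pattern


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CellModel:
    """Identical per-cell kinetics ``rhs(u, w, lam)``.

    ``u`` is the cell's own state and ``w`` the average state of its input
    neighbours; both have shape ``(..., s)`` and ``rhs`` must broadcast over
    leading dimensions.  Identical kinetics for every cell and dependence on
    inputs only through their average make the resulting network ODE
    admissible.
    """

    s: int
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    params: dict = field(default_factory=dict)
    name: str = "custom"


_DELTA_NOTCH_DEFAULTS = dict(
    h_D=2.0, h_N=2.0, K_D=0.1, K_N=0.1, gamma_D=1.0, gamma_N=1.0
)


def make_delta_notch_model(params: dict | None = None) -> CellModel:
    """Collier-style lateral inhibition with state ``(D, N)``."""
    p = dict(_DELTA_NOTCH_DEFAULTS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown Delta-Notch parameters: {sorted(unknown)}")
        p.update(params)
    if p["gamma_D"] <= 0 or p["gamma_N"] <= 0 or p["K_D"] <= 0 or p["K_N"] <= 0:
        raise ValueError("decay rates and thresholds must be positive")
    if p["h_D"] < 1 or p["h_N"] < 1:
        raise ValueError("Hill coefficients must be >= 1")

    hD, hN, KD, KN = p["h_D"], p["h_N"], p["K_D"], p["K_N"]
    gD, gN = p["gamma_D"], p["gamma_N"]

    def rhs(u, w, lam):
        u = np.asarray(u, dtype=float)
        w = np.asarray(w, dtype=float)
        D, N = u[..., 0], u[..., 1]
        wD = w[..., 0]
        g = 1.0 / (1.0 + (N / KD) ** hD)
        F = wD**hN / (KN + wD**hN)
        out = np.empty_like(u)
        out[..., 0] = lam * g - gD * D
        out[..., 1] = F - gN * N
        return out

    return CellModel(s=2, rhs=rhs, params=p, name="delta_notch")


def hill_derivatives(model: CellModel, u: np.ndarray, lam: float) -> dict:
    """Closed-form partials of the Delta-Notch kinetics (test oracle)."""
    if model.name != "delta_notch":
        raise ValueError("analytic derivatives only for the Delta-Notch model")
    p = model.params
    D, N = float(u[0]), float(u[1])
    x = (N / p["K_D"]) ** p["h_D"]
    dg_dN = -p["h_D"] * x / (N * (1.0 + x) ** 2) if N > 0 else 0.0
    wh = D ** p["h_N"]
    dF_dw = (
        p["h_N"] * D ** (p["h_N"] - 1.0) * p["K_N"] / (p["K_N"] + wh) ** 2
    )
    return {"dDdot_dN": lam * dg_dN, "dNdot_dw": dF_dw}


def synchronous_equilibrium(
    model: CellModel,
    lam: float,
    guess: np.ndarray | None = None,
    bounds: tuple[float, float] = (0.0, 1e6),
) -> tuple[np.ndarray, float]:
    """Solve ``rhs(u, u, lam) = 0`` for one cell; returns ``(u*, residual)``.

    All cells identical and averaging inputs means a synchronous equilibrium
    is a fixed point of the single-cell dynamics with ``w = u``.
    """
    def resid(u):
        return model.rhs(np.asarray(u, float), np.asarray(u, float), lam)

    if guess is None:
        guess = np.full(model.s, 0.1)
    sol = root(resid, guess, method="hybr", tol=1e-13)
    u = sol.x
    r = float(np.max(np.abs(resid(u))))
    if r > 1e-10 or np.any(u < bounds[0] - 1e-12) or np.any(u > bounds[1]):
        # retry from a coarse scan of starting points
        for g0 in (1e-3, 0.05, 0.3, 1.0, 3.0):
            sol = root(resid, np.full(model.s, g0), method="hybr", tol=1e-13)
            u = sol.x
            r = float(np.max(np.abs(resid(u))))
            if r <= 1e-10 and np.all(u >= bounds[0] - 1e-12):
                break
        else:
            raise SimulationError(
                f"no synchronous equilibrium found at lambda={lam}: "
                f"residual {r:.3g}, state {u}"
            )
    return np.clip(u, bounds[0], None), r


def delta_notch_equilibrium_bisect(model: CellModel, lam: float) -> np.ndarray:
    """Independent bisection solve of the Delta-Notch synchronous equilibrium."""
    p = model.params

    def f_scalar(D):
        N = (D ** p["h_N"] / (p["K_N"] + D ** p["h_N"])) / p["gamma_N"]
        g = 1.0 / (1.0 + (N / p["K_D"]) ** p["h_D"])
        return lam * g - p["gamma_D"] * D

    if lam <= 0:
        D = 0.0
    else:
        D = brentq(f_scalar, 0.0, max(1.0, 2.0 * lam / p["gamma_D"]), xtol=1e-14)
    N = (D ** p["h_N"] / (p["K_N"] + D ** p["h_N"])) / p["gamma_N"]
    return np.array([D, N])


def linearize(
    model: CellModel, u_star: np.ndarray, lam: float, valence: int
) -> LocalDynamics:
    """Finite-difference ``(Q, R)`` at a synchronous state.

    Central differences with step ``1e-6 * (1 + |u*|)`` per coordinate; the
    per-arrow coupled block is the derivative with respect to the averaged
    input divided by the valence.
    """
    u_star = np.asarray(u_star, dtype=float)
    s = model.s
    res = float(np.max(np.abs(model.rhs(u_star, u_star, lam))))
    meta = {}
    if res > 1e-8 * (1.0 + np.max(np.abs(u_star))):
        meta["warning"] = f"linearizing away from equilibrium (residual {res:.3g})"
    Q = np.empty((s, s))
    Rbar = np.empty((s, s))
    for j in range(s):
        h = 1e-6 * (1.0 + abs(u_star[j]))
        e = np.zeros(s)
        e[j] = h
        Q[:, j] = (model.rhs(u_star + e, u_star, lam)
                   - model.rhs(u_star - e, u_star, lam)) / (2 * h)
        Rbar[:, j] = (model.rhs(u_star, u_star + e, lam)
                      - model.rhs(u_star, u_star - e, lam)) / (2 * h)
    return LocalDynamics(Q, Rbar / valence, meta=meta)


@dataclass(frozen=True)
class Trajectory:
    """Simulated network trajectory on a fixed output grid."""

    times: np.ndarray            # (T,)
    states: np.ndarray           # (T, n, s)
    lambda_path: np.ndarray      # (T,)
    seed: int | None
    valence: int
    events: tuple = ()

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]

    @property
    def s(self) -> int:
        return self.states.shape[2]


def lambda_of_t(schedule) -> Callable[[float], float]:
    """Piecewise-linear interpolation of ``[(t, lambda), ...]`` breakpoints."""
    pts = sorted((float(t), float(l)) for t, l in schedule)
    ts = np.array([t for t, _ in pts])
    ls = np.array([l for _, l in pts])
    return lambda t: float(np.interp(t, ts, ls))


def integrate(
    model: CellModel,
    net: RegularNetwork,
    x0: np.ndarray,
    lam_schedule,
    seed: int | None = None,
    noise_amplitude: float = 0.0,
    n_output: int = 400,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    state_bound: float = 1e6,
) -> Trajectory:
    """Integrate the admissible network ODE under a quasistatic schedule.

    A single seeded uniform perturbation of the given amplitude is applied at
    ``t = 0`` (cells start in a *nearly* identical state, which lets a
    synchrony-breaking instability grow); the integration itself is
    deterministic, so a fixed seed reproduces the trajectory bit for bit.
    """
    A = adjacency_matrix(net).astype(float)
    nu = net.valence
    n, s = net.n_nodes, model.s
    x0 = np.array(x0, dtype=float)
    if x0.shape != (n, s):
        raise SimulationError(f"x0 must have shape {(n, s)}, got {x0.shape}")
    if noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        x0 = x0 + noise_amplitude * rng.uniform(-1.0, 1.0, size=x0.shape)

    lam_fn = lambda_of_t(lam_schedule)
    t0 = min(t for t, _ in lam_schedule)
    t1 = max(t for t, _ in lam_schedule)

    def f(t, y):
        x = y.reshape(n, s)
        w = (A @ x) / nu
        return model.rhs(x, w, lam_fn(t)).ravel()

    t_eval = np.linspace(t0, t1, n_output)
    sol = solve_ivp(
        f, (t0, t1), x0.ravel(), method="RK45", rtol=rtol, atol=atol,
        t_eval=t_eval, dense_output=False,
    )
    states = sol.y.T.reshape(-1, n, s)
    if not sol.success or not np.all(np.isfinite(states)) or np.max(
        np.abs(states)
    ) > state_bound:
        last = states[np.all(np.isfinite(states.reshape(len(states), -1)), axis=1)]
        raise SimulationError(
            "integration failed or state exceeded bound; last valid state: "
            f"{last[-1] if len(last) else None}"
        )
    return Trajectory(
        times=sol.t,
        states=states,
        lambda_path=np.array([lam_fn(t) for t in sol.t]),
        seed=seed,
        valence=nu,
    )


def find_bifurcation_lambda(
    model: CellModel,
    net: RegularNetwork,
    lam_range: tuple[float, float] = (1e-3, 2.0),
    dec: SpectralDecomposition | None = None,
) -> float:
    """Coupling gain at which the synchronous state first loses stability.

    Root of the binding stability margin of the linearized blocks
    ``Q + mu_i R`` along the synchronous equilibrium branch.
    """
    from .bifurcation import sync_stability
    from .spectral import decompose_network

    if dec is None:
        dec = decompose_network(net)
    nu = net.valence

    def margin(lam):
        u, _ = synchronous_equilibrium(model, lam)
        return sync_stability(linearize(model, u, lam, nu), dec)["binding_margin"]

    lo, hi = lam_range
    if margin(lo) <= 0:
        raise SimulationError("synchronous state already unstable at lower bound")
    if margin(hi) >= 0:
        raise SimulationError("no stability loss inside the lambda range")
    return float(brentq(margin, lo, hi, xtol=1e-8))


def quasistatic_pattern_run(
    model: CellModel,
    net: RegularNetwork,
    seed: int | None = 0,
    noise_amplitude: float = 1e-3,
    start_factor: float = 0.9,
    stop_factor: float = 1.3,
    ramp_time: float = 150.0,
    settle_time: float = 550.0,
    dec: SpectralDecomposition | None = None,
    n_output: int = 400,
) -> tuple[Trajectory, dict, float]:
    """Canonical onset experiment: perturb just below threshold, ramp past it.

    Locates the first stability loss ``lambda*``, prepares the tissue at the
    synchronous equilibrium at ``start_factor * lambda*`` with a small seeded
    perturbation, ramps to ``stop_factor * lambda*`` over ``ramp_time`` and
    holds for ``settle_time``.  Stopping modestly above threshold keeps the
    run inside the parameter region where the first bifurcating branch is the
    unique stable pattern; ramping far beyond it would probe secondary
    branches outside the scope of the onset analysis.  Returns
    ``(trajectory, behavior report, lambda*)``.
    """
    from .spectral import decompose_network

    if dec is None:
        dec = decompose_network(net)
    lam_star = find_bifurcation_lambda(model, net, dec=dec)
    lam0, lam1 = start_factor * lam_star, stop_factor * lam_star
    u0, _ = synchronous_equilibrium(model, lam0)
    x0 = np.tile(u0, (net.n_nodes, 1))
    traj = integrate(
        model, net, x0,
        [(0.0, lam0), (ramp_time, lam1), (ramp_time + settle_time, lam1)],
        seed=seed, noise_amplitude=noise_amplitude, n_output=n_output,
    )
    return traj, detect_behavior(traj, dec), lam_star


def detect_behavior(
    traj: Trajectory,
    dec: SpectralDecomposition,
    tol: float = 1e-4,
    sync_tol: float = 1e-3,
) -> dict:
    """Classify the late-time behavior and project the emergent pattern.

    Examined window: the last 20% of the final-``lambda`` plateau.
    Oscillation: peak-to-peak amplitude exceeding ``tol`` relative to the
    state scale.  Synchrony: cross-cell standard deviation below ``sync_tol``
    relative to scale.  For patterned outcomes the time-averaged
    deviation-from-mean profile is projected onto every pattern space
    ``P_mu_j`` (summed over state components).
    """
    lam_final = traj.lambda_path[-1]
    on_plateau = np.isclose(traj.lambda_path, lam_final, rtol=0, atol=1e-12)
    # contiguous tail
    idx = len(on_plateau) - 1
    while idx > 0 and on_plateau[idx - 1]:
        idx -= 1
    plateau = np.arange(idx, len(traj.times))
    if len(plateau) < 3:
        return {"behavior": "undetermined", "reason": "no final plateau sampled"}
    window = plateau[int(np.ceil(0.8 * len(plateau))):]
    if len(window) < 2:
        window = plateau[-2:]
    X = traj.states[window]  # (Tw, n, s)
    scale = max(float(np.mean(np.abs(X))), 1e-12)

    amplitude = float(np.max(X.max(axis=0) - X.min(axis=0)))
    oscillating = amplitude > tol * scale

    mean_state = X.mean(axis=0)  # (n, s)
    cross_std = float(np.max(mean_state.std(axis=0)))
    synchronous = cross_std < sync_tol * scale

    if synchronous:
        behavior = "synchronous_oscillation" if oscillating else "homogeneous_steady"
    else:
        behavior = "patterned_oscillation" if oscillating else "patterned_steady"

    report = {
        "behavior": behavior,
        "amplitude": amplitude,
        "cross_cell_std": cross_std,
        "scale": scale,
        "lambda_final": float(lam_final),
        "projections": {},
    }
    if not synchronous:
        dev = mean_state - mean_state.mean(axis=0, keepdims=True)  # (n, s)
        total = float(np.sum(dev**2))
        if total > 0:
            for j in range(1, dec.k + 1):
                space = pattern_space(dec, j)
                num = sum(
                    project_pattern(dev[:, c], space) * float(dev[:, c] @ dev[:, c])
                    for c in range(dev.shape[1])
                    if float(dev[:, c] @ dev[:, c]) > 0
                )
                report["projections"][space.label if j in (1, dec.k) else f"P_mu{j}"] = (
                    num / total
                )
        report["deviation_pattern"] = dev
    return report
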