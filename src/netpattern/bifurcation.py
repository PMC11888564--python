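"""Classification of the first synchrony-breaking bifurcation.

At a synchronous equilibrium of an admissible ODE on a regular network, the
Jacobian decomposes into the node-space blocks ``Q + mu_j R`` where ``Q`` is
the internal (own-state) linearization, ``R`` the per-input-arrow coupled
linearization, and ``mu_j`` runs over the adjacency eigenvalues.  Which block
first acquires a critical eigenvalue as a bifurcation parameter moves decides
the emergent pattern:

* node dimension 1: the sign of ``R`` alone decides — ``R < 0`` puts the
  critical eigenvalue in the ``mu_1`` block (synchrony-breaking pattern),
  ``R > 0`` in the ``mu_k`` block (synchrony-preserving), ``R = 0`` makes
  every block critical at once;
* node dimension 2 with ``det R = 0``: both ``tr(Q + mu R)`` and
  ``det(Q + mu R)`` are linear in ``mu``, and the signs of ``tr R`` and of
  the invariant ``B = tr(Q) tr(R) - tr(QR)`` select one row of a 15-row
  case table (steady vs oscillatory onset, pattern space ``P_mu1`` vs
  ``P_muk`` vs combinations);
* node dimension 2 with ``det R <= 0``: the critical block can only be the
  extreme one, ``mu_1`` or ``mu_k`` (or all blocks in the fully degenerate
  case) — observing an interior pattern therefore forces ``det R > 0``.

Nondegeneracy (NDG) conditions guaranteeing a unique critical block:
``det(Q) > |nu B|`` rules out steady-state criticality (onset must be a Hopf
pair), and ``tr(Q) < -|nu tr(R)|`` rules out Hopf criticality (onset must be
a real steady-state eigenvalue), where ``nu`` is the network valence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy import linalg
from scipy.optimize import linear_sum_assignment

from .spectral import SpectralDecomposition

SIGNS = ("+", "-", "0", "?")


class DynamicsError(ValueError):
    pass


class WrongClassifierError(DynamicsError):
    """det R is outside the tolerance of the requested classifier."""


class IndeterminateSignsError(DynamicsError):
    """A sign-pattern input does not determine the classification."""


@dataclass(frozen=True)
class LocalDynamics:
    """Linearized node-level dynamics ``(Q, R)`` at a synchronous state.

    ``Q = D_u f`` (internal) and ``R = D_{v_1} f`` (per input arrow).  Entries
    may be numeric, or sign characters ``+ - 0 ?`` when ``sign_only``.
    """

    Q: np.ndarray
    R: np.ndarray
    sign_only: bool = False
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.sign_only:
            Q = np.asarray(self.Q, dtype=object)
            R = np.asarray(self.R, dtype=object)
            for M in (Q, R):
                for entry in M.ravel():
                    if entry not in SIGNS:
                        raise DynamicsError(f"invalid sign entry {entry!r}")
        else:
            Q = np.asarray(self.Q, dtype=float)
            R = np.asarray(self.R, dtype=float)
        if Q.shape != R.shape or Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise DynamicsError("Q and R must be square matrices of equal size")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "R", R)

    @property
    def s(self) -> int:
        return self.Q.shape[0]

    def to_sympy(self) -> tuple[sp.Matrix, sp.Matrix]:
        """Sign entries as sympy symbols carrying positivity assumptions."""
        def conv(M, name):
            rows = []
            for i in range(M.shape[0]):
                row = []
                for j in range(M.shape[1]):
                    e = M[i, j]
                    if self.sign_only:
                        if e == "0":
                            row.append(sp.Integer(0))
                        elif e == "+":
                            row.append(sp.Symbol(f"{name}{i}{j}", positive=True))
                        elif e == "-":
                            row.append(sp.Symbol(f"{name}{i}{j}", negative=True))
                        else:
                            row.append(sp.Symbol(f"{name}{i}{j}", real=True))
                    else:
                        row.append(sp.Float(float(e)))
                rows.append(row)
            return sp.Matrix(rows)

        return conv(self.Q, "q"), conv(self.R, "r")


def sign_of(expr) -> str:
    """Sign character of a sympy expression under its symbols' assumptions."""
    expr = sp.expand(expr)
    if expr.is_zero:
        return "0"
    if expr.is_positive:
        return "+"
    if expr.is_negative:
        return "-"
    return "?"


def _scale(dyn: LocalDynamics) -> float:
    return max(1.0, float(np.max(np.abs(dyn.Q))), float(np.max(np.abs(dyn.R))))


def B_invariant(dyn: LocalDynamics):
    """``B = tr(Q) tr(R) - tr(QR)``; a float, or a sign character for
    sign-pattern input."""
    if dyn.s != 2:
        raise DynamicsError("the B invariant is defined for 2-dimensional nodes")
    if dyn.sign_only:
        Q, R = dyn.to_sympy()
        return sign_of(Q.trace() * R.trace() - (Q * R).trace())
    Q, R = dyn.Q, dyn.R
    return float(np.trace(Q) * np.trace(R) - np.trace(Q @ R))


def sync_stability(dyn: LocalDynamics, dec: SpectralDecomposition) -> dict:
    """Stability of the synchronous equilibrium via the blocks ``Q + mu_i R``.

    Node dimension 1: stable iff ``Q + Re(mu_i) R < 0`` for every distinct
    eigenvalue.  Node dimension 2 (real spectrum required): stable iff
    ``tr(Q + mu_i R) < 0`` and ``det(Q + mu_i R) > 0`` for every ``mu_i``.
    Reports the per-eigenvalue margins and the binding (critical-closest) one.
    """
    if dyn.sign_only:
        raise DynamicsError(
            "sync_stability needs numeric dynamics; use the sign-inference path"
        )
    margins = []
    if dyn.s == 1:
        q = float(dyn.Q[0, 0])
        r = float(dyn.R[0, 0])
        for mu in dec.eigenvalues:
            margins.append(-(q + mu.real * r))
        necessary = {"Q<0": q < 0}
    elif dyn.s == 2:
        if not dec.all_real:
            raise DynamicsError(
                "2-dimensional stability determinant checks need a real spectrum"
            )
        for mu in dec.eigenvalues:
            M = dyn.Q + mu.real * dyn.R
            margins.append(min(-np.trace(M), np.linalg.det(M)))
        necessary = {"tr Q<0": float(np.trace(dyn.Q)) < 0}
    else:
        raise DynamicsError("node dimensions above 2 are not supported here")
    margins = [float(m) for m in margins]
    binding = int(np.argmin(margins))
    return {
        "stable": all(m > 0 for m in margins),
        "margins": margins,
        "binding_mu_index": binding + 1,
        "binding_margin": margins[binding],
        "necessary_conditions": necessary,
    }


@dataclass(frozen=True)
class BifurcationClassification:
    """Outcome of a first-bifurcation classification.

    ``rule`` is ``"1d"`` (three-case rule for scalar nodes) or ``"table"``
    (15-row table for planar nodes with ``det R = 0``).  ``case_id`` indexes
    the case/row; counts are reported both symbolically (in terms of the
    multiplicities ``alpha_j``/``beta_j``) and numerically when a spectral
    decomposition is available.
    """

    rule: str
    case_id: int | None
    pattern_space_label: str
    eig_type: str | None
    n_critical: str
    n_critical_value: int | None
    eigenspace_dim: str
    eigenspace_dim_value: int | None
    synchrony_breaking: bool | None
    conditions_used: tuple = ()
    degenerate: bool = False
    warnings: tuple = ()


def classify_1d(R_value) -> BifurcationClassification:
    """Three-case rule for scalar node dynamics at a bifurcation point.

    ``R < 0``: critical block is ``mu_1`` — synchrony-breaking pattern.
    ``R > 0``: critical block is ``mu_k`` — synchrony-preserving.
    ``R = 0``: every block critical; the critical pattern space is ``R^n``.
    """
    if isinstance(R_value, str):
        if R_value not in SIGNS:
            raise DynamicsError(f"invalid sign {R_value!r}")
        if R_value == "?":
            raise IndeterminateSignsError("sign of R is unknown")
        sgn = R_value
    else:
        r = float(R_value)
        sgn = "0" if r == 0 else ("+" if r > 0 else "-")
    if sgn == "0":
        return BifurcationClassification(
            rule="1d", case_id=1, pattern_space_label="R^n", eig_type="real",
            n_critical="n", n_critical_value=None, eigenspace_dim="n",
            eigenspace_dim_value=None, synchrony_breaking=True,
            conditions_used=(("R", "=0"),),
        )
    if sgn == "-":
        return BifurcationClassification(
            rule="1d", case_id=2, pattern_space_label="P_mu1", eig_type="real",
            n_critical="alpha1", n_critical_value=None, eigenspace_dim="beta1",
            eigenspace_dim_value=None, synchrony_breaking=True,
            conditions_used=(("R", "<0"),),
        )
    return BifurcationClassification(
        rule="1d", case_id=3, pattern_space_label="P_muk", eig_type="real",
        n_critical="1", n_critical_value=1, eigenspace_dim="1",
        eigenspace_dim_value=1, synchrony_breaking=False,
        conditions_used=(("R", ">0"),),
    )


# Table rows for planar nodes with det R = 0.  Each entry:
# (pattern label, eigenvalue type, symbolic count, symbolic eigenspace dim,
#  (B sign, trR sign) or NDG markers)
_TABLE = {
    1: ("P_mu1", "real", "alpha1", "beta1", ("B>0", "NDG_tr")),
    2: ("P_mu1", "imaginary", "2*alpha1", "beta1", ("NDG_det", "trR<0")),
    3: ("P_muk", "real", "1", "1", ("B<0", "NDG_tr")),
    4: ("P_muk", "imaginary", "2", "1", ("NDG_det", "trR>0")),
    5: ("P_mu1", "real", "2*alpha1", "2*beta1", ("B>0", "trR<0")),
    6: ("P_muk", "real", "2", "2", ("B<0", "trR>0")),
    7: ("P_mu1 ⊕ P_muk", "mixed", "alpha1 real + 2 imag", "beta1+1",
        ("B>0", "trR>0")),
    8: ("P_mu1 ⊕ P_muk", "mixed", "2*alpha1 imag + 1 real", "beta1+1",
        ("B<0", "trR<0")),
    9: ("R^n", "mixed", "2*alpha1 real + sum_{j!=1} 2*alpha_j imag",
        "n+beta1", ("B>0", "trR=0")),
    10: ("R^n", "mixed", "2 real + sum_{j!=k} 2*alpha_j imag", "n+1",
         ("B<0", "trR=0")),
    11: ("R^n", "real", "2*alpha1 real + sum_{j!=1} alpha_j real", "n+beta1",
         ("B=0", "trR<0")),
    12: ("R^n", "real", "2 real + sum_{j!=k} alpha_j real", "n+1",
         ("B=0", "trR>0")),
    13: ("R^n", "imaginary", "sum_j 2*alpha_j", "n", ("NDG_det", "trR=0")),
    14: ("R^n", "real", "sum_j alpha_j", "n", ("B=0", "NDG_tr")),
    15: ("R^n", "real", "sum_j 2*alpha_j", "2n", ("B=0", "trR=0")),
}


def _table_counts(row: int, dec: SpectralDecomposition) -> tuple[int, int]:
    a1, b1 = dec.alg_mult[0], dec.geo_mult[0]
    n = dec.n
    counts = {
        1: (a1, b1), 2: (2 * a1, b1), 3: (1, 1), 4: (2, 1),
        5: (2 * a1, 2 * b1), 6: (2, 2), 7: (a1 + 2, b1 + 1),
        8: (2 * a1 + 1, b1 + 1), 9: (2 * n, n + b1), 10: (2 * n, n + 1),
        11: (n + a1, n + b1), 12: (n + 1, n + 1), 13: (2 * n, n),
        14: (n, n), 15: (2 * n, 2 * n),
    }
    return counts[row]


def _make_table_classification(
    row: int | None, dec: SpectralDecomposition, conds, degenerate, warnings
) -> BifurcationClassification:
    if row is None:
        return BifurcationClassification(
            rule="table", case_id=None, pattern_space_label="none",
            eig_type=None, n_critical="0", n_critical_value=0,
            eigenspace_dim="0", eigenspace_dim_value=0,
            synchrony_breaking=None, conditions_used=tuple(conds),
            degenerate=True, warnings=tuple(warnings),
        )
    pat, etype, ncrit, edim, _ = _TABLE[row]
    nval, dval = _table_counts(row, dec)
    return BifurcationClassification(
        rule="table", case_id=row, pattern_space_label=pat, eig_type=etype,
        n_critical=ncrit, n_critical_value=nval, eigenspace_dim=edim,
        eigenspace_dim_value=dval, synchrony_breaking=pat != "P_muk",
        conditions_used=tuple(conds), degenerate=degenerate,
        warnings=tuple(warnings),
    )


def classify_2d_detR_zero(
    dyn: LocalDynamics, dec: SpectralDecomposition, tol: float = 1e-9
) -> BifurcationClassification:
    """Select the table row for planar nodes with ``det R = 0``.

    Branches on the signs of ``B`` and ``tr R`` (zero within tolerance) and
    on the two NDG inequalities.  Rows beyond 4 require a coincidence of
    critical roots and are returned with ``degenerate=True``; when both NDG
    inequalities hold no block can be critical and no row is selected.
    """
    if dyn.s != 2:
        raise DynamicsError("this classifier needs 2-dimensional node dynamics")
    if not dec.all_real:
        raise DynamicsError(
            "classification requires a real adjacency spectrum"
        )
    nu = dec.valence
    warnings: list[str] = []
    conds: list[tuple[str, str]] = []

    if dyn.sign_only:
        return _classify_signs(dyn, dec, conds, warnings)

    scale = _scale(dyn)
    ztol = tol * scale
    ztol2 = tol * scale * scale
    Q, R = dyn.Q, dyn.R
    detR = float(np.linalg.det(R))
    if abs(detR) > ztol2:
        raise WrongClassifierError(
            f"det R = {detR:.3g} is not zero at tolerance; use "
            "classify_2d_detR_nonpositive (det R < 0) or the brute-force "
            "block eigenvalues (det R > 0)"
        )
    trR = float(np.trace(R))
    trQ = float(np.trace(Q))
    detQ = float(np.linalg.det(Q))
    B = B_invariant(dyn)

    def signed(x, tol_):
        if abs(x) <= tol_:
            return "0"
        if abs(x) <= 10 * tol_:
            warnings.append(f"quantity {x:.3g} within 10x of the zero tolerance")
        return "+" if x > 0 else "-"

    sB = signed(B, ztol2)
    strR = signed(trR, ztol)
    ndg_tr = trQ + nu * abs(trR) < -ztol
    ndg_det = detQ - nu * abs(B) > ztol2
    conds.append(("B", sB))
    conds.append(("tr R", strR))
    conds.append(("tr Q < -|nu tr R| (NDG)", str(ndg_tr)))
    conds.append(("det Q > |nu B| (NDG)", str(ndg_det)))

    if ndg_tr and ndg_det:
        warnings.append(
            "both NDG inequalities hold: no block can carry a critical "
            "eigenvalue, so no bifurcation occurs at this point"
        )
        return _make_table_classification(None, dec, conds, True, warnings)
    if ndg_tr:
        row = {"+": 1, "-": 3, "0": 14}[sB]
        return _make_table_classification(row, dec, conds, row == 14, warnings)
    if ndg_det:
        row = {"-": 2, "+": 4, "0": 13}[strR]
        return _make_table_classification(row, dec, conds, row == 13, warnings)
    row = {
        ("+", "-"): 5, ("-", "+"): 6, ("+", "+"): 7, ("-", "-"): 8,
        ("+", "0"): 9, ("-", "0"): 10, ("0", "-"): 11, ("0", "+"): 12,
        ("0", "0"): 15,
    }[(sB, strR)]
    warnings.append(
        "neither NDG inequality holds: the selected row assumes a "
        "degenerate coincidence of critical roots"
    )
    return _make_table_classification(row, dec, conds, True, warnings)


def _classify_signs(dyn, dec, conds, warnings) -> BifurcationClassification:
    Q, R = dyn.to_sympy()
    s_detR = sign_of(R.det())
    if s_detR != "0":
        raise WrongClassifierError(
            f"sign pattern does not force det R = 0 (sign {s_detR!r})"
        )
    s_trR = sign_of(R.trace())
    s_trQ = sign_of(Q.trace())
    s_B = sign_of(Q.trace() * R.trace() - (Q * R).trace())
    conds.append(("B", s_B))
    conds.append(("tr R", s_trR))
    # NDG from signs alone: tr R = 0 structurally and tr Q < 0 gives
    # tr Q < -|nu tr R| = 0; det Q > |nu B| is provable only when B = 0
    # structurally and det Q > 0.
    ndg_tr = s_trR == "0" and s_trQ == "-"
    ndg_det = s_B == "0" and sign_of(Q.det()) == "+"
    conds.append(("tr Q < -|nu tr R| (NDG)", str(ndg_tr)))
    conds.append(("det Q > |nu B| (NDG)", str(ndg_det)))
    if ndg_tr:
        if s_B == "?":
            raise IndeterminateSignsError("sign of B is not determined")
        row = {"+": 1, "-": 3, "0": 14}[s_B]
        return _make_table_classification(row, dec, conds, row == 14, warnings)
    if ndg_det:
        if s_trR == "?":
            raise IndeterminateSignsError("sign of tr R is not determined")
        row = {"-": 2, "+": 4, "0": 13}[s_trR]
        return _make_table_classification(row, dec, conds, row == 13, warnings)
    if "?" in (s_B, s_trR):
        raise IndeterminateSignsError(
            "sign pattern does not determine B and tr R"
        )
    row = {
        ("+", "-"): 5, ("-", "+"): 6, ("+", "+"): 7, ("-", "-"): 8,
        ("+", "0"): 9, ("-", "0"): 10, ("0", "-"): 11, ("0", "+"): 12,
        ("0", "0"): 15,
    }[(s_B, s_trR)]
    warnings.append("degenerate row selected from signs without NDG support")
    return _make_table_classification(row, dec, conds, True, warnings)


def classify_2d_detR_nonpositive(
    dyn: LocalDynamics, dec: SpectralDecomposition
) -> dict:
    """Admissible pattern spaces when ``det R <= 0``: only the extremes.

    Returns the admissible label set; the contrapositive — a pattern outside
    these spaces forces ``det R > 0`` — is what the inference module uses.
    """
    if dyn.s != 2:
        raise DynamicsError("this classifier needs 2-dimensional node dynamics")
    if not dec.all_real:
        raise DynamicsError("classification requires a real adjacency spectrum")
    if dyn.sign_only:
        s = sign_of(dyn.to_sympy()[1].det())
        if s == "+":
            raise DynamicsError("det R > 0: the extreme-block restriction does not apply")
        if s == "?":
            raise IndeterminateSignsError("sign of det R is not determined")
    else:
        detR = float(np.linalg.det(dyn.R))
        if detR > 1e-9 * _scale(dyn) ** 2:
            raise DynamicsError(
                f"det R = {detR:.3g} > 0: the extreme-block restriction does not apply"
            )
    return {
        "admissible": {"P_mu1", "P_muk", "P_mu1 ⊕ P_muk", "R^n"},
        "contrapositive": "a critical pattern space outside the admissible "
        "set implies det R > 0",
    }


def jacobian_full(dyn: LocalDynamics, A) -> tuple[np.ndarray, dict]:
    """Full Jacobian ``I (x) Q + A (x) R`` and its block-eigenvalue check.

    The eigenvalues of the full Jacobian are the union over adjacency
    eigenvalues ``mu_j`` (with algebraic multiplicity) of the eigenvalues of
    ``Q + mu_j R``; the report measures the multiset distance between the two
    computations (optimal matching).
    """
    if dyn.sign_only:
        raise DynamicsError("jacobian_full needs numeric dynamics")
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    J = np.kron(np.eye(n), dyn.Q) + np.kron(A, dyn.R)
    eig_full = linalg.eigvals(J)
    mus = linalg.eigvals(A)  # with multiplicity
    eig_blocks = np.concatenate(
        [linalg.eigvals(dyn.Q + mu * dyn.R) for mu in mus]
    )
    cost = np.abs(eig_full[:, None] - eig_blocks[None, :])
    ri, ci = linear_sum_assignment(cost)
    dist = float(cost[ri, ci].max())
    return J, {
        "multiset_distance": dist,
        "eig_full": eig_full,
        "eig_blocks": eig_blocks,
    }


def brute_force_critical(
    dyn: LocalDynamics, dec: SpectralDecomposition, tol: float = 1e-7
) -> dict:
    """Direct eigencomputation of every block ``Q + mu_i R``.

    Independent of the sign-based classifiers: reports, per distinct
    adjacency eigenvalue, the block eigenvalues, which blocks carry a
    critical (zero-real-part) eigenvalue, and whether those criticals are
    real or imaginary pairs.
    """
    if dyn.sign_only:
        raise DynamicsError("brute force needs numeric dynamics")
    scale = _scale(dyn) * max(1.0, dec.spectral_radius)
    atol = tol * scale
    report = {"blocks": [], "critical_indices": [], "critical_types": {}}
    for i, mu in enumerate(dec.eigenvalues, start=1):
        M = dyn.Q + mu.real * dyn.R if dec.all_real else dyn.Q + mu * dyn.R
        evs = np.atleast_1d(linalg.eigvals(np.asarray(M, dtype=complex)))
        crit = [ev for ev in evs if abs(ev.real) <= atol]
        report["blocks"].append({"mu": mu, "eigenvalues": evs})
        if crit:
            report["critical_indices"].append(i)
            kind = "imaginary" if any(abs(ev.imag) > atol for ev in crit) else "real"
            report["critical_types"][i] = kind
    return report


def design_local_dynamics(
    dec: SpectralDecomposition, target_j: int
) -> LocalDynamics:
    """Construct planar dynamics whose unique critical block is ``mu_target``.

    With ``m`` the target eigenvalue, take::

        Q = [[-t, u], [v, -t]],   R = [[0, 1], [-1, 0]]

    with ``u = 1 + 2|m|``, ``v = u + 2m`` and ``t = sqrt(m^2 + u v)``.  Then
    ``det(Q + mu R) = (mu - m)^2`` (zero exactly at the target, positive
    elsewhere) and ``tr(Q + mu R) = -2t < 0`` for every ``mu``, so the single
    critical eigenvalue of the full Jacobian comes from the target block.
    ``det R = 1 > 0``, as interior targets require.
    """
    if not dec.all_real:
        raise DynamicsError("designer requires a real adjacency spectrum")
    if dec.k < 2:
        raise DynamicsError("need at least two distinct eigenvalues")
    if not 1 <= target_j <= dec.k:
        raise DynamicsError(f"target index {target_j} out of range 1..{dec.k}")
    m = float(dec.eigenvalues[target_j - 1].real)
    u = 1.0 + 2.0 * abs(m)
    v = u + 2.0 * m
    t = float(np.sqrt(m * m + u * v))
    assert t > 0 and v > 0
    Q = np.array([[-t, u], [v, -t]])
    R = np.array([[0.0, 1.0], [-1.0, 0.0]])
    return LocalDynamics(Q, R, meta={"target_j": target_j, "target_mu": m})
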