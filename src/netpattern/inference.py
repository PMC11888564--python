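"""Inferring signaling-network signs from observed tissue behavior.

This inverts the forward pipeline: given partial knowledge of the signaling
diagram (entries of the internal dynamics ``Q`` and coupled dynamics ``R``
as named variables or fixed signs) and the observed tissue behavior —
homogeneous steady state, patterned steady state, synchronous oscillation,
or oscillating pattern — derive sign constraints on the unknown entries.
The derivation chains:

1. stability of the initially uniform tissue (``Q < 0`` for one chemical,
   ``tr Q < 0`` for two);
2. the case table of the first bifurcation (selected by ``tr R`` and the
   invariant ``B = tr(Q) tr(R) - tr(QR)`` when ``det R = 0``);
3. the determinant constraint: a steady pattern outside ``P_mu1``, ``P_muk``
   or their sum forces ``det R > 0``.

A sign on an entry of ``R`` is an intercell statement (activation/inhibition
of a neighbour's chemical); a sign on an off-diagonal of ``Q`` is an
intracell statement; a negative diagonal of ``Q`` is decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .bifurcation import sign_of
from .network import RegularNetwork
from .spectral import (
    PatternSpace,
    decompose_network,
    pattern_space,
    project_pattern,
)


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """A partially-known signaling architecture.

    Templates are matrices of strings: a named variable (unknown sign), a
    sign character ``+ - 0``, or a numeric literal.  Built-in ids:

    ``single_chemical_self_coupling``
        one chemical ``u``; ``Q = [[q]]``, ``R = [[r]]``.
    ``two_chemical_uu_coupling``
        chemicals ``(u, v)`` interacting within the cell; neighbour ``u``
        influences own ``u``: ``R = [[kappa, 0], [0, 0]]``.
    ``two_chemical_uv_coupling``
        neighbour ``u`` influences own ``v``: ``R = [[0, 0], [kappa, 0]]``.
    """

    id: str
    s: int
    Q_template: tuple
    R_template: tuple
    entry_meanings: dict = field(default_factory=dict)


def builtin_scenario(scenario_id: str) -> Scenario:
    if scenario_id == "single_chemical_self_coupling":
        return Scenario(
            id=scenario_id, s=1, Q_template=(("q",),), R_template=(("r",),),
            entry_meanings={
                "q": "self-regulation of u within a cell",
                "r": "influence of u in a neighbouring cell on u",
            },
        )
    if scenario_id == "two_chemical_uu_coupling":
        return Scenario(
            id=scenario_id, s=2,
            Q_template=(("a", "b"), ("c", "d")),
            R_template=(("kappa", "0"), ("0", "0")),
            entry_meanings={
                "a": "self-regulation of u", "d": "self-regulation of v",
                "b": "influence of v on u within the cell",
                "c": "influence of u on v within the cell",
                "kappa": "influence of u in a neighbouring cell on u",
            },
        )
    if scenario_id == "two_chemical_uv_coupling":
        return Scenario(
            id=scenario_id, s=2,
            Q_template=(("a", "b"), ("c", "d")),
            R_template=(("0", "0"), ("kappa", "0")),
            entry_meanings={
                "a": "self-regulation of u", "d": "self-regulation of v",
                "b": "influence of v on u within the cell",
                "c": "influence of u on v within the cell",
                "kappa": "influence of u in a neighbouring cell on v",
            },
        )
    raise InferenceError(f"unknown scenario id {scenario_id!r}")


@dataclass
class SignConstraints:
    """Per-entry sign conclusions plus symbolic relations and readings."""

    entries: dict            # variable name -> '+', '-', '0', 'nonzero', 'unconstrained'
    relations: list          # (expression string, relation string)
    narrative: list          # human-readable statements
    possible: bool = True    # False when the behavior is impossible

    def merge_entry(self, name: str, sign: str):
        old = self.entries.get(name, "unconstrained")
        if old in ("unconstrained", None):
            self.entries[name] = sign
        elif old != sign and "unconstrained" not in (old, sign):
            if {old, sign} == {"nonzero", "+"}:
                self.entries[name] = "+"
            elif {old, sign} == {"nonzero", "-"}:
                self.entries[name] = "-"
            else:
                raise InferenceError(
                    f"contradictory constraints on {name}: {old} vs {sign}"
                )


def _template_to_sympy(template, signs: dict[str, str]):
    """Template matrix -> sympy matrix; `signs` may pre-assign variable signs."""
    rows = []
    symbols = {}
    for row in template:
        out = []
        for e in row:
            e = str(e)
            if e in ("0",):
                out.append(sp.Integer(0))
            elif e == "+":
                out.append(sp.Symbol(f"_p{len(symbols)}", positive=True))
            elif e == "-":
                out.append(sp.Symbol(f"_n{len(symbols)}", negative=True))
            else:
                try:
                    out.append(sp.Float(float(e)))
                    continue
                except ValueError:
                    pass
                sgn = signs.get(e)
                if e not in symbols:
                    if sgn == "+":
                        symbols[e] = sp.Symbol(e, positive=True)
                    elif sgn == "-":
                        symbols[e] = sp.Symbol(e, negative=True)
                    else:
                        symbols[e] = sp.Symbol(e, real=True)
                out.append(symbols[e])
        rows.append(out)
    return sp.Matrix(rows), symbols


def _monomial_sign_conclusions(expr, required: str, constraints: SignConstraints,
                               meanings: dict):
    """Solve ``sign(expr) = required`` when expr is a single monomial.

    With one unknown factor, its sign is pinned; with two, their sign
    relation (equal/opposite) is recorded.
    """
    expr = sp.expand(expr)
    terms = expr.as_ordered_terms()
    if len(terms) != 1:
        constraints.relations.append((str(expr), f"{required} (not reducible)"))
        return
    coeff, factors = terms[0].as_coeff_mul()
    unknowns = [f for f in factors if f.is_Symbol and f.is_positive is None
                and f.is_negative is None]
    knowns = [f for f in factors if f not in unknowns]
    sgn = 1 if coeff > 0 else -1
    for f in knowns:
        if f.is_negative:
            sgn = -sgn
    want = 1 if required == ">0" else -1
    if len(unknowns) == 1:
        u = unknowns[0]
        s = "+" if sgn * want > 0 else "-"
        constraints.merge_entry(str(u), s)
        reading = meanings.get(str(u), str(u))
        verb = "activates (positive)" if s == "+" else "inhibits (negative)"
        constraints.narrative.append(f"{reading}: {verb}")
    elif len(unknowns) == 2:
        u1, u2 = unknowns
        same = sgn * want > 0
        rel = "same sign" if same else "opposite signs"
        constraints.relations.append((f"{u1}*{u2}", f"{'>' if same else '<'}0"))
        constraints.narrative.append(
            f"sgn({u1}) {'=' if same else '!='} sgn({u2}): "
            f"{meanings.get(str(u1), u1)} and {meanings.get(str(u2), u2)} "
            f"have {rel}"
        )
        for u in (u1, u2):
            constraints.merge_entry(str(u), "nonzero")
    else:
        constraints.relations.append((str(expr), required))


def infer_from_behavior(
    scenario: Scenario, behavior: str, assume_decay: bool = False
) -> SignConstraints:
    """Derive sign constraints on a scenario's unknowns from tissue behavior.

    ``behavior`` is one of ``homogeneous_steady``, ``patterned_steady``,
    ``synchronous_oscillation``, ``patterned_oscillation``.  With
    ``assume_decay`` every chemical's self-term (diagonal of ``Q``) is taken
    negative before the bifurcation logic runs.
    """
    valid = {
        "homogeneous_steady", "patterned_steady",
        "synchronous_oscillation", "patterned_oscillation",
    }
    if behavior not in valid:
        raise InferenceError(f"unknown behavior {behavior!r}")

    cons = SignConstraints(entries={}, relations=[], narrative=[])
    presigns: dict[str, str] = {}

    # step 1-2: stability of the initially uniform tissue
    if scenario.s == 1:
        qname = str(scenario.Q_template[0][0])
        cons.merge_entry(qname, "-")
        presigns[qname] = "-"
        cons.narrative.append(
            f"uniform state initially stable: {scenario.entry_meanings.get(qname, qname)}"
            " is negative (u decays)"
        )
    else:
        diag = [str(scenario.Q_template[i][i]) for i in range(scenario.s)]
        cons.relations.append(("+".join(diag), "<0"))
        cons.narrative.append(
            "uniform state initially stable: tr(Q) = "
            + "+".join(diag) + " < 0 (net decay)"
        )
        if assume_decay:
            for name in diag:
                cons.merge_entry(name, "-")
                presigns[name] = "-"
            cons.narrative.append("assuming each chemical decays: "
                                  + ", ".join(f"{d}<0" for d in diag))

    Q, _ = _template_to_sympy(scenario.Q_template, presigns)
    R, _ = _template_to_sympy(scenario.R_template, presigns)

    if scenario.s == 1:
        r = R[0, 0]
        if behavior == "patterned_steady":
            _monomial_sign_conclusions(r, "<0", cons, scenario.entry_meanings)
            cons.narrative.append(
                "a steady pattern needs a synchrony-breaking bifurcation, "
                "which for one chemical occurs iff R < 0: u in one cell "
                "inhibits u in its neighbours"
            )
        elif behavior in ("synchronous_oscillation", "patterned_oscillation"):
            cons.possible = False
            cons.narrative.append(
                "impossible under this architecture: with a 1-dimensional "
                "node space every block eigenvalue Q + mu_i R is real, so "
                "no oscillation can onset"
            )
        return cons

    # two-chemical scenarios: the table logic needs det R = 0 structurally
    if sign_of(R.det()) != "0":
        raise InferenceError(
            "two-chemical inference requires det R = 0 structurally"
        )
    trR = sp.expand(R.trace())
    B = sp.expand(Q.trace() * R.trace() - (Q * R).trace())
    trR_zero = trR.is_zero

    if behavior == "synchronous_oscillation":
        if trR_zero:
            cons.possible = False
            cons.narrative.append(
                "impossible: tr(R) = 0 structurally, so tr(Q) < -|nu tr R| "
                "holds whenever the uniform state was stable and the onset "
                "can only be a steady-state bifurcation (no oscillations)"
            )
            return cons
        _monomial_sign_conclusions(trR, ">0", cons, scenario.entry_meanings)
        cons.narrative.append(
            "synchronous oscillations arise from a synchrony-preserving "
            "Hopf onset, which requires tr(R) > 0"
        )
    elif behavior == "patterned_oscillation":
        if trR_zero:
            cons.possible = False
            cons.narrative.append(
                "impossible: tr(R) = 0 structurally excludes Hopf onset "
                "under this architecture"
            )
            return cons
        _monomial_sign_conclusions(trR, "<0", cons, scenario.entry_meanings)
        cons.narrative.append(
            "an oscillating pattern arises from a synchrony-breaking Hopf "
            "onset, which requires tr(R) < 0"
        )
    elif behavior == "patterned_steady":
        cons.relations.append((str(B), ">0"))
        _monomial_sign_conclusions(B, ">0", cons, scenario.entry_meanings)
        cons.narrative.append(
            "a steady pattern arises from a synchrony-breaking steady-state "
            f"onset, which requires B = {B} > 0"
        )
    else:  # homogeneous_steady: no bifurcation to condition on
        cons.narrative.append(
            "no pattern observed: only the stability preconditions constrain "
            "the signs"
        )
    return cons


def classify_observed_pattern(
    net: RegularNetwork,
    pattern: np.ndarray,
    tol: float = 0.05,
    spectral_tol: float = 1e-8,
) -> dict:
    """Locate an observed per-cell pattern among the pattern spaces.

    The pattern's synchronous (cross-cell mean) component is removed first;
    membership is the fraction of the deviation variance captured by each
    ``P_mu_j`` (and by ``P_mu1 (+) P_muk``).  A dominant interior membership
    (``>= 1 - tol``) generically forces ``det R > 0``; membership in the
    extreme spaces is consistent with ``det R <= 0``.
    """
    dec = decompose_network(net, tol=spectral_tol)
    if not dec.all_real:
        raise InferenceError("pattern classification needs a real spectrum")
    v = np.asarray(pattern, dtype=float).ravel()
    if v.size != net.n_nodes:
        raise InferenceError("pattern length does not match network size")
    dev = v - v.mean()
    sync_fraction = 1.0 - (float(dev @ dev) / float(v @ v) if v @ v > 0 else 0.0)
    if float(dev @ dev) <= 1e-24 * max(1.0, float(v @ v)):
        return {
            "memberships": {}, "in_mu1": False, "in_muk": True,
            "in_sum": True, "sync_fraction": sync_fraction,
            "detR_inference": "pattern is synchronous (all cells equal): "
            "synchrony-preserving, no determinant inference",
        }

    memberships = {}
    for j in range(1, dec.k + 1):
        space = pattern_space(dec, j)
        key = "P_mu1" if j == 1 else ("P_muk" if j == dec.k else f"P_mu{j}")
        memberships[key] = project_pattern(dev, space)
    sum_basis = np.vstack(
        [pattern_space(dec, 1).basis, pattern_space(dec, dec.k).basis]
    )
    in_sum_frac = project_pattern(
        dev, PatternSpace("P_mu1 ⊕ P_muk", sum_basis, sum_basis.shape[0])
    )

    thresh = 1.0 - tol
    in_mu1 = memberships["P_mu1"] >= thresh
    in_muk = memberships["P_muk"] >= thresh
    in_sum = in_sum_frac >= thresh
    dominant_interior = None
    for key, frac in memberships.items():
        if key not in ("P_mu1", "P_muk") and frac >= thresh:
            dominant_interior = key

    weak = ""
    best = max(max(memberships.values()), in_sum_frac)
    if thresh <= best < 0.99:
        weak = " (weak: membership between 0.95 and 0.99)"

    if in_mu1 or in_muk or in_sum:
        inference = (
            "consistent with det R <= 0 (pattern lies in the extreme "
            "pattern spaces)" + weak
        )
    elif dominant_interior:
        inference = (
            f"det R > 0 (generically): pattern lies in the interior space "
            f"{dominant_interior}, which cannot be critical when det R <= 0 "
            "(barring the extremely degenerate all-blocks-critical case)"
            + weak
        )
    else:
        inference = "inconclusive: no pattern space dominates the deviation"
    return {
        "memberships": memberships,
        "in_mu1": bool(in_mu1),
        "in_muk": bool(in_muk),
        "in_sum": bool(in_sum),
        "sum_fraction": in_sum_frac,
        "sync_fraction": sync_fraction,
        "dominant_interior": dominant_interior,
        "detR_inference": inference,
    }
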