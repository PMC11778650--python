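"""Flux balance analysis and its linear-programming dual.

The primal problem is

    maximize   Z = v_objective
    subject to S · v = 0
               lb_i <= v_i <= ub_i   (i = 1 .. n)

solved with HiGHS through :func:`scipy.optimize.linprog`.  Dual values are
reported with a fixed orientation:

* shadow price of metabolite i: dZ*/db_i where the mass-balance row is
  relaxed to S_i·v = b_i and b_i > 0 forces net production (a drain) of i.
  A metabolite that is costly to produce therefore has a NEGATIVE price.
* reduced cost of reaction j: dZ*/d(active bound value); zero for reactions
  strictly inside their bounds.

Because dual sign conventions differ across LP backends, every solve can
re-check the orientation with a single finite-difference probe against one
metabolite with a nonzero price (``check_orientation``).  LP dual values are
not unique at degenerate optima; :func:`price_subgradient_interval` reports
the one-sided finite-difference interval for such metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .core import MetabolicModel

__all__ = [
    "FBAResult",
    "FBAError",
    "solve_fba",
    "shadow_prices",
    "reduced_costs",
    "finite_difference_price",
    "price_subgradient_interval",
]

#: primal/dual feasibility tolerance passed to HiGHS
SOLVER_TOL = 1e-9


class FBAError(RuntimeError):
    """Raised when the LP cannot be solved or the solution is unusable."""


@dataclass
class FBAResult:
    """Primal and dual solution of one FBA solve."""

    status: str                      # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)
    shadow_prices: Dict[str, float] = field(default_factory=dict)
    reduced_costs: Dict[str, float] = field(default_factory=dict)
    objective_id: Optional[str] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def shadow_price(self, met_id: str) -> float:
        return self.shadow_prices[met_id]


def _solve_raw(model: MetabolicModel, objective: str, sense: str,
               b_eq: Optional[np.ndarray] = None,
               bounds_override: Optional[Dict[str, Tuple[float, float]]] = None):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if bounds_override:
        for rid, (lo, hi) in bounds_override.items():
            j = model._rxn_index[rid]
            lb[j], ub[j] = lo, hi
    n = len(model.reactions)
    c = np.zeros(n)
    j_obj = model._rxn_index[objective]
    c[j_obj] = -1.0 if sense == "max" else 1.0
    if b_eq is None:
        b_eq = np.zeros(S.shape[0])
    res = linprog(
        c, A_eq=S, b_eq=b_eq, bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    return res, j_obj


def solve_fba(model: MetabolicModel, objective: Optional[str] = None,
              sense: str = "max", check_orientation: bool = True) -> FBAResult:
    """Solve the FBA linear program and extract primal and dual solutions.

    Parameters
    ----------
    model:
        Validated metabolic model.
    objective:
        Reaction id to optimize; defaults to ``model.objective``.
    sense:
        ``"max"`` (default) or ``"min"``.
    check_orientation:
        Re-verify the dual sign convention once per solve with a
        finite-difference probe on the metabolite with the largest |price|.

    Infeasible or unbounded problems are reported through
    ``FBAResult.status``, never silently as zeros.
    """
    objective = objective if objective is not None else model.objective
    if objective is None:
        raise FBAError("no objective reaction given and model declares none")
    if not model.has_reaction(objective):
        raise FBAError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise FBAError(f"sense must be 'max' or 'min', got {sense!r}")

    res, j_obj = _solve_raw(model, objective, sense)
    if res.status == 2:
        return FBAResult(status="infeasible", objective_value=None,
                         objective_id=objective)
    if res.status == 3:
        return FBAResult(status="unbounded", objective_value=None,
                         objective_id=objective)
    if res.status != 0:
        raise FBAError(f"LP solver failure: {res.message}")

    sign = -1.0 if sense == "max" else 1.0
    z = sign * res.fun
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    # duals of a minimized problem measure d(min)/d(rhs); convert to dZ*/d(rhs)
    prices = {
        m.id: float(sign * y)
        for m, y in zip(model.metabolites, res.eqlin.marginals)
    }
    rcosts = {
        r.id: float(sign * (lo + hi))
        for r, lo, hi in zip(model.reactions, res.lower.marginals,
                             res.upper.marginals)
    }
    result = FBAResult(status="optimal", objective_value=float(z),
                       fluxes=fluxes, shadow_prices=prices,
                       reduced_costs=rcosts, objective_id=objective)

    if check_orientation:
        _verify_orientation(model, objective, sense, result)
    return result


def _verify_orientation(model: MetabolicModel, objective: str, sense: str,
                        result: FBAResult, eps: float = 1e-5,
                        rtol: float = 1e-3) -> None:
    """One finite-difference probe pinning the dual sign convention.

    Probes the metabolite with the largest |shadow price| (skipped when all
    prices vanish).  A mismatch in sign raises: it would mean the backend's
    dual convention changed under us.
    """
    if not result.shadow_prices:
        return
    met_id, price = max(result.shadow_prices.items(), key=lambda kv: abs(kv[1]))
    if abs(price) < 1e-9:
        return
    fd = finite_difference_price(model, met_id, objective=objective,
                                 sense=sense, eps=eps,
                                 base_objective=result.objective_value)
    if fd is None:
        return  # probe infeasible: degenerate edge, interval machinery applies
    if abs(fd - price) > rtol * max(1.0, abs(price)) and np.sign(fd) != np.sign(price):
        raise FBAError(
            f"dual orientation check failed for {met_id}: reported price "
            f"{price:.6g}, finite difference {fd:.6g}"
        )


def finite_difference_price(model: MetabolicModel, met_id: str,
                            objective: Optional[str] = None,
                            sense: str = "max", eps: float = 1e-6,
                            base_objective: Optional[float] = None
                            ) -> Optional[float]:
    """One-sided finite-difference estimate of dZ*/db for metabolite ``met_id``
    (b > 0 forces net production).  Returns None if the probe is infeasible.
    """
    objective = objective if objective is not None else model.objective
    if base_objective is None:
        base = solve_fba(model, objective, sense, check_orientation=False)
        if not base.optimal:
            raise FBAError("base problem not optimal; cannot probe")
        base_objective = base.objective_value
    i = model._met_index[met_id]
    b = np.zeros(len(model.metabolites))
    b[i] = eps
    res, _ = _solve_raw(model, objective, sense, b_eq=b)
    if res.status != 0:
        return None
    sign = -1.0 if sense == "max" else 1.0
    return (sign * res.fun - base_objective) / eps


def price_subgradient_interval(model: MetabolicModel, met_id: str,
                               objective: Optional[str] = None,
                               sense: str = "max", eps: float = 1e-6
                               ) -> Tuple[Optional[float], Optional[float]]:
    """Two one-sided finite differences bracketing the shadow price.

    At a non-degenerate optimum both sides agree with the LP dual; at a
    degenerate optimum any value inside the interval is a valid subgradient
    and alternate optimal bases can report different prices.  Either side is
    None if the corresponding perturbation is infeasible.
    """
    right = finite_difference_price(model, met_id, objective, sense, eps=eps)
    left = finite_difference_price(model, met_id, objective, sense, eps=-eps)
    return left, right


def duality_gap(model: MetabolicModel, objective: Optional[str] = None,
                sense: str = "max") -> float:
    """|primal Z* - dual objective| for one solve.

    With homogeneous mass-balance right-hand side the dual objective reduces
    to the bound terms  sum_j (lambda_j^- lb_j + lambda_j^+ ub_j); strong
    duality holds at any optimum, so this gap is solver noise.
    """
    objective = objective if objective is not None else model.objective
    res, _ = _solve_raw(model, objective, sense)
    if res.status != 0:
        raise FBAError(f"LP not optimal (status {res.status}); no duality gap")
    lb, ub = model.bounds_arrays()
    lo = np.where(res.lower.marginals != 0, lb, 0.0)   # 0 * inf guard
    hi = np.where(res.upper.marginals != 0, ub, 0.0)
    dual_obj = float(res.lower.marginals @ lo + res.upper.marginals @ hi)
    return abs(res.fun - dual_obj)


def shadow_prices(model: MetabolicModel, objective: Optional[str] = None,
                  flag_degenerate: bool = False, degeneracy_tol: float = 1e-4
                  ) -> Dict[str, float]:
    """Per-metabolite shadow prices at the FBA optimum.

    With ``flag_degenerate`` the return value maps metabolite ids to
    ``(price, is_degenerate)`` where degeneracy means the two one-sided
    finite differences disagree by more than ``degeneracy_tol``.
    """
    result = solve_fba(model, objective)
    if not result.optimal:
        raise FBAError(f"FBA not optimal (status {result.status}); no duals")
    if not flag_degenerate:
        return result.shadow_prices
    out = {}
    for met_id, price in result.shadow_prices.items():
        left, right = price_subgradient_interval(model, met_id, objective)
        degenerate = (
            left is None or right is None or abs(left - right) > degeneracy_tol
        )
        out[met_id] = (price, degenerate)
    return out


def reduced_costs(model: MetabolicModel, objective: Optional[str] = None
                  ) -> Dict[str, float]:
    """Per-reaction reduced costs (dZ*/d active bound) at the FBA optimum."""
    result = solve_fba(model, objective)
    if not result.optimal:
        raise FBAError(f"FBA not optimal (status {result.status}); no duals")
    return result.reduced_costs
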