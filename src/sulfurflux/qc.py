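"""Model quality control.

Elemental/charge balance per reaction, metabolite connectivity statistics,
dead-end detection and parsimonious (minimum-cardinality) gap filling.

Exchange and biomass reactions are exempt from balance checking: both are
inherently unbalanced boundary/drain pseudo-reactions, and a reconstruction's
mass/charge-balance claim concerns its chemical reactions.  Reactions with a
participant lacking formula or charge are reported as *unverifiable*, never
silently treated as balanced.  Proton and water imbalances are reported like
any other element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import (
    FormulaError,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_formula,
)
from .fba import solve_fba

__all__ = [
    "BalanceReport",
    "ConnectivityProfile",
    "GapFillError",
    "check_balance",
    "balance_model",
    "connectivity_profile",
    "find_dead_ends",
    "gap_fill",
]

BALANCE_TOL = 1e-9


@dataclass
class BalanceReport:
    """Outcome of one reaction's elemental/charge bookkeeping.

    ``element_delta`` holds signed products-minus-substrates excess per
    element; ``verdict`` is balanced / imbalanced / unverifiable (the latter
    with a reason naming the offending participants).
    """

    reaction_id: str
    verdict: str
    element_delta: Dict[str, float] = field(default_factory=dict)
    charge_delta: Optional[float] = None
    reason: str = ""

    @property
    def balanced(self) -> bool:
        return self.verdict == "balanced"


def check_balance(reaction: Reaction,
                  metabolites: Dict[str, Metabolite]) -> BalanceReport:
    """Elemental and charge bookkeeping for one reaction.

    The per-element delta is the coefficient-weighted sum of parsed
    formulas; balanced means every element delta and the charge delta are
    zero.  Exchange/biomass reactions are exempt by contract and raise
    ``ValueError`` if passed.
    """
    if reaction.kind in ("exchange", "biomass"):
        raise ValueError(
            f"reaction {reaction.id!r} is of exempt kind {reaction.kind!r}"
        )
    missing = []
    delta: Dict[str, float] = {}
    charge = 0.0
    charge_known = True
    for met_id, coef in reaction.stoichiometry.items():
        met = metabolites[met_id]
        if met.formula is None:
            missing.append(met_id)
            continue
        try:
            counts = parse_formula(met.formula)
        except FormulaError as exc:
            return BalanceReport(reaction.id, "unverifiable",
                                 reason=f"malformed formula for {met_id}: {exc}")
        for el, n in counts.items():
            delta[el] = delta.get(el, 0.0) + coef * n
        if met.charge is None:
            charge_known = False
        else:
            charge += coef * met.charge
    if missing:
        return BalanceReport(
            reaction.id, "unverifiable",
            reason=f"missing formula for {', '.join(sorted(missing))}",
        )
    delta = {el: d for el, d in delta.items() if abs(d) > BALANCE_TOL}
    charge_delta = charge if charge_known else None
    if not delta and (charge_delta is None or abs(charge_delta) <= BALANCE_TOL):
        if charge_delta is None:
            return BalanceReport(reaction.id, "unverifiable",
                                 reason="charge unknown for some participants",
                                 element_delta={})
        return BalanceReport(reaction.id, "balanced", {}, charge_delta)
    return BalanceReport(reaction.id, "imbalanced", delta, charge_delta)


def balance_model(model: MetabolicModel) -> List[BalanceReport]:
    """Balance reports for every non-exempt reaction of the model."""
    lookup = {m.id: m for m in model.metabolites}
    return [
        check_balance(r, lookup)
        for r in model.reactions
        if r.kind not in ("exchange", "biomass")
    ]


@dataclass
class ConnectivityProfile:
    """Metabolite connectivity histogram.

    ``degree_counts[k]`` is the number of metabolites participating in
    exactly k qualifying reactions (k >= 1); ``more_than`` aggregates
    degrees above the reporting cutoff.
    """

    degree_counts: Dict[int, int]
    scope: Tuple[str, ...]
    cutoff: int = 3

    def count(self, degree: int) -> int:
        return self.degree_counts.get(degree, 0)

    @property
    def more_than_cutoff(self) -> int:
        return sum(n for k, n in self.degree_counts.items() if k > self.cutoff)

    @property
    def total_connected(self) -> int:
        return sum(self.degree_counts.values())


def connectivity_profile(model: MetabolicModel,
                         scope: Sequence[str] = ("metabolic",),
                         cutoff: int = 3) -> ConnectivityProfile:
    """Connectivity taken as the number of qualifying reactions in which a
    metabolite participates; default scope counts metabolic reactions only."""
    scope = tuple(scope)
    degree: Dict[str, int] = {}
    for r in model.reactions:
        if r.kind not in scope:
            continue
        for met_id in r.stoichiometry:
            degree[met_id] = degree.get(met_id, 0) + 1
    counts: Dict[int, int] = {}
    for d in degree.values():
        counts[d] = counts.get(d, 0) + 1
    return ConnectivityProfile(degree_counts=counts, scope=scope, cutoff=cutoff)


def find_dead_ends(model: MetabolicModel) -> List[str]:
    """Metabolites that can only be produced or only consumed.

    Bounds-aware: a reversible reaction (lb < 0 < ub) counts as both a
    producer and a consumer of everything it touches; a reaction fixed to
    zero flux counts as neither.
    """
    producible: Set[str] = set()
    consumable: Set[str] = set()
    touched: Set[str] = set()
    for r in model.reactions:
        fwd = r.upper_bound > 0
        rev = r.lower_bound < 0
        for met_id, coef in r.stoichiometry.items():
            touched.add(met_id)
            if coef > 0:
                if fwd:
                    producible.add(met_id)
                if rev:
                    consumable.add(met_id)
            elif coef < 0:
                if fwd:
                    consumable.add(met_id)
                if rev:
                    producible.add(met_id)
    return sorted(
        m for m in touched
        if (m in producible) != (m in consumable)
    )


class GapFillError(RuntimeError):
    """Raised when no subset of the universal pool can restore growth."""


def gap_fill(model: MetabolicModel, universal: Iterable[Reaction],
             min_growth: float = 0.05,
             objective: Optional[str] = None) -> List[str]:
    """Minimum-cardinality set of pool reactions restoring growth.

    Solves a MILP with one binary indicator per pool reaction gating its
    flux bounds, a growth constraint ``v_obj >= min_growth``, and the
    indicator sum as objective.  Returns the selected pool reaction ids
    (empty when the model already meets ``min_growth``); raises
    :class:`GapFillError` when even the full pool cannot.

    ``model`` and the pool must share a metabolite namespace; pool reactions
    may introduce new metabolites.
    """
    if min_growth <= 0:
        raise ValueError("min_growth must be positive")
    objective = objective if objective is not None else model.objective
    base = solve_fba(model, objective, check_orientation=False)
    if base.optimal and base.objective_value >= min_growth - 1e-9:
        return []

    universal = [r for r in universal if not model.has_reaction(r.id)]
    if not universal:
        raise GapFillError("empty universal pool and model below min_growth")

    met_ids = [m.id for m in model.metabolites]
    met_index = {m: i for i, m in enumerate(met_ids)}
    for r in universal:
        for met_id in r.stoichiometry:
            if met_id not in met_index:
                met_index[met_id] = len(met_index)
    n_met = len(met_index)
    n_model = len(model.reactions)
    n_pool = len(universal)
    n = n_model + n_pool          # flux variables
    # columns: [model fluxes | pool fluxes | pool indicators]
    rows, cols, data = [], [], []
    for j, r in enumerate(list(model.reactions) + universal):
        for met_id, coef in r.stoichiometry.items():
            rows.append(met_index[met_id]); cols.append(j); data.append(coef)
    S = sparse.csr_matrix((data, (rows, cols)), shape=(n_met, n + n_pool))

    lb, ub = model.bounds_arrays()
    lb = np.concatenate([lb, [r.lower_bound for r in universal], np.zeros(n_pool)])
    ub = np.concatenate([ub, [r.upper_bound for r in universal], np.ones(n_pool)])

    constraints = [LinearConstraint(S, np.zeros(n_met), np.zeros(n_met))]
    # v_j <= ub_j * y_j  and  v_j >= lb_j * y_j for pool reactions
    for k, r in enumerate(universal):
        row = sparse.csr_matrix(
            ([1.0, -r.upper_bound], ([0, 0], [n_model + k, n + k])),
            shape=(1, n + n_pool))
        constraints.append(LinearConstraint(row, -np.inf, 0.0))
        row = sparse.csr_matrix(
            ([1.0, -r.lower_bound], ([0, 0], [n_model + k, n + k])),
            shape=(1, n + n_pool))
        constraints.append(LinearConstraint(row, 0.0, np.inf))
    # growth requirement
    j_obj = model._rxn_index[objective]
    row = sparse.csr_matrix(([1.0], ([0], [j_obj])), shape=(1, n + n_pool))
    constraints.append(LinearConstraint(row, min_growth, np.inf))

    c = np.concatenate([np.zeros(n), np.ones(n_pool)])
    integrality = np.concatenate([np.zeros(n), np.ones(n_pool)])
    res = milp(c=c, constraints=constraints, integrality=integrality,
               bounds=Bounds(lb, ub))
    if res.status != 0 or res.x is None:
        raise GapFillError(
            f"gap filling infeasible even with the full pool "
            f"(solver status: {res.message})"
        )
    chosen = [universal[k].id for k in range(n_pool) if res.x[n + k] > 0.5]
    return chosen
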