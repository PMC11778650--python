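"""The study's simulation experiments as reusable procedures.

* carbon-source growth scans at constant total carbon uptake,
* DBT titration with the desulfurization end product (2-HBP) as readout,
* shadow-cost ranking of sulfur-containing metabolites (absolute and
  per sulfur atom),
* the PAP-bypass strain design: knock out the sulfate-activation enzymes
  (ATP sulfurylase, EC 2.7.7.4 / APS kinase, EC 2.7.1.25) and feed
  adenosine 3',5'-bisphosphate through its transporter instead.

All procedures condition a copy of the model and run FBA; the input model
is never mutated.  Where a tracked flux is not unique at the growth
optimum, a lexicographic second stage re-optimizes that flux at fixed
optimal growth so the reported number is well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import MetabolicModel, ModelValidationError, parse_formula
from .fba import FBAError, FBAResult, solve_fba

__all__ = [
    "ScenarioResult",
    "carbon_source_scan",
    "dbt_titration",
    "sulfur_shadow_costs",
    "pap_bypass_scenario",
    "lexicographic_flux",
]


@dataclass
class ScenarioResult:
    """One simulated condition: growth plus tracked fluxes and prices."""

    label: str
    status: str
    growth: float
    tracked_fluxes: Dict[str, float] = field(default_factory=dict)
    shadow_prices: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _require_exchange(model: MetabolicModel, rxn_id: str) -> None:
    if not model.has_reaction(rxn_id):
        raise ModelValidationError(f"unknown exchange reaction {rxn_id!r}")
    if model.reaction(rxn_id).kind != "exchange":
        raise ModelValidationError(f"{rxn_id!r} is not an exchange reaction")


def lexicographic_flux(model: MetabolicModel, track: str,
                       objective: Optional[str] = None,
                       sense: str = "max") -> Tuple[FBAResult, FBAResult]:
    """Growth-first, tracked-flux-second lexicographic optimization.

    Solves FBA, pins the objective flux at its optimum (within solver
    tolerance) and re-optimizes the tracked reaction's flux.  Returns the
    first-stage result and the full second-stage result; tracked fluxes
    should be read from the second stage so they belong to one consistent
    flux distribution.
    """
    objective = objective if objective is not None else model.objective
    first = solve_fba(model, objective, check_orientation=False)
    if not first.optimal:
        return first, first
    pinned = model.copy()
    z = first.objective_value
    pinned.set_bounds(objective, z - 1e-8 * max(1.0, abs(z)), 1000.0)
    second = solve_fba(pinned, track, sense=sense, check_orientation=False)
    if not second.optimal:
        raise FBAError(
            f"lexicographic stage for {track!r} unexpectedly {second.status}"
        )
    return first, second


def carbon_source_scan(model: MetabolicModel,
                       sources: Sequence[Tuple[str, int]],
                       total_carbon: float = 6.0,
                       sulfur_source: str = "EX_so4",
                       sulfur_bounds: Tuple[float, float] = (-1.0, 1000.0),
                       ) -> List[ScenarioResult]:
    """Growth on each carbon source at constant total carbon uptake.

    For a source with k carbons per molecule the uptake lower bound is
    ``-total_carbon / k`` mmol·gDW⁻¹·h⁻¹, all other listed carbon exchanges
    are closed to uptake, and the chosen sulfur source is opened.  The
    carbon-normalized bounds make yields comparable across substrates of
    different reduction states.
    """
    for ex, k in sources:
        _require_exchange(model, ex)
        if k <= 0:
            raise ModelValidationError(f"carbon count for {ex!r} must be > 0")
    _require_exchange(model, sulfur_source)

    results = []
    for ex, k in sources:
        conditioned = model.copy()
        for other, _ in sources:
            conditioned.set_bounds(other, 0.0,
                                   conditioned.reaction(other).upper_bound)
        uptake = total_carbon / k
        conditioned.set_bounds(ex, -uptake,
                               conditioned.reaction(ex).upper_bound)
        conditioned.set_bounds(sulfur_source, *sulfur_bounds)
        res = solve_fba(conditioned, check_orientation=False)
        results.append(ScenarioResult(
            label=ex,
            status=res.status,
            growth=res.objective_value or 0.0,
            tracked_fluxes={ex: res.fluxes.get(ex, 0.0)} if res.optimal else {},
            shadow_prices=res.shadow_prices if res.optimal else {},
        ))
    return results


def dbt_titration(model: MetabolicModel,
                  levels: Iterable[float],
                  dbt_exchange: str = "EX_dbt",
                  hbp_exchange: str = "EX_hbp",
                  carbon_fixed: Tuple[str, float] = ("EX_glc", -1.0),
                  sulfur_exchanges: Sequence[str] = ("EX_so4", "EX_h2s"),
                  block_product_oxidation: bool = True,
                  product_oxidation_id: str = "HBPMO",
                  hbp_transport_id: str = "t_hbp",
                  ) -> List[ScenarioResult]:
    """2-HBP production as a function of the DBT uptake bound.

    DBT is made the sole sulfur source (all exchanges in
    ``sulfur_exchanges`` closed to uptake), the carbon source is fixed, and
    for each level d the DBT exchange gets bounds (-d, 0).  Secreted 2-HBP
    is read with a lexicographic secondary maximization at fixed optimal
    growth, so the reported flux is well-defined among alternate optima.

    ``block_product_oxidation`` disables the downstream aromatic oxidation
    of 2-HBP and opens its secretion route, mirroring the experimental
    readout in which 2-HBP accumulates in the medium; with the oxidation
    active the end product would be catabolized instead of exported.
    Infeasible levels are recorded as zero-growth scenarios.
    """
    _require_exchange(model, dbt_exchange)
    _require_exchange(model, hbp_exchange)
    base = model.copy()
    carbon_ex, carbon_lb = carbon_fixed
    base.set_bounds(carbon_ex, carbon_lb, base.reaction(carbon_ex).upper_bound)
    for ex in sulfur_exchanges:
        if base.has_reaction(ex):
            base.set_bounds(ex, 0.0, base.reaction(ex).upper_bound)
    if block_product_oxidation:
        if base.has_reaction(product_oxidation_id):
            base.set_bounds(product_oxidation_id, 0.0, 0.0)
        if base.has_reaction(hbp_transport_id):
            base.set_bounds(hbp_transport_id, 0.0, 1000.0)
        base.set_bounds(hbp_exchange, 0.0, 1000.0)

    results = []
    for d in levels:
        if d < 0:
            raise ModelValidationError("titration levels are uptake magnitudes (>= 0)")
        conditioned = base.copy()
        conditioned.set_bounds(dbt_exchange, -d, 0.0)
        res, second = lexicographic_flux(conditioned, hbp_exchange)
        if not res.optimal:
            results.append(ScenarioResult(
                label=f"dbt={d:g}", status=res.status, growth=0.0))
            continue
        results.append(ScenarioResult(
            label=f"dbt={d:g}",
            status="optimal",
            growth=res.objective_value,
            tracked_fluxes={
                hbp_exchange: second.fluxes[hbp_exchange],
                dbt_exchange: second.fluxes[dbt_exchange],
            },
        ))
    return results


def sulfur_shadow_costs(model: MetabolicModel,
                        objective: Optional[str] = None,
                        ) -> Tuple[List[Dict[str, float]], List[str]]:
    """Shadow-cost ranking of sulfur-containing metabolites.

    Runs FBA on the model as conditioned by the caller (e.g. glucose as
    carbon source, DBT as sole sulfur source), filters metabolites with at
    least one sulfur atom, and reports price and price per sulfur atom,
    most negative first.  Returns (table, skipped) where ``skipped`` lists
    sulfur-unverifiable metabolites (no formula).
    """
    result = solve_fba(model, objective)
    if not result.optimal:
        raise FBAError(f"FBA not optimal (status {result.status})")
    table: List[Dict[str, float]] = []
    skipped: List[str] = []
    for met in model.metabolites:
        if met.formula is None:
            skipped.append(met.id)
            continue
        n_s = parse_formula(met.formula).get("S", 0.0)
        if n_s < 1:
            continue
        price = result.shadow_prices[met.id]
        table.append({
            "metabolite": met.id,
            "name": met.name,
            "sulfur_atoms": n_s,
            "shadow_price": price,
            "price_per_sulfur": price / n_s,
        })
    table.sort(key=lambda row: row["shadow_price"])
    return table, skipped


def pap_bypass_scenario(model: MetabolicModel,
                        atp_sulfurylase_rxns: Sequence[str],
                        aps_kinase_rxns: Sequence[str],
                        pap_exchange: str = "EX_pap",
                        pap_uptake: float = -1.0,
                        dbt_exchange: Optional[str] = "EX_dbt",
                        dbt_uptake: float = -10.0,
                        closed_sulfur: Sequence[str] = ("EX_so4", "EX_h2s"),
                        ) -> Dict[str, ScenarioResult]:
    """The strain-design hypothesis: sulfate-activation knockout with and
    without adenosine 3',5'-bisphosphate (PAP) supplementation.

    All three runs are conditioned on the desulfurizing medium the design
    targets: DBT open as the sole sulfur source (``closed_sulfur``
    exchanges shut).  Scenario A closes the named ATP-sulfurylase and
    APS-kinase reactions and keeps the PAP exchange closed to uptake;
    scenario B additionally opens PAP uptake.  Growth and the 2-HBP-pathway
    flux (via the last 4S step when present) are reported for both,
    alongside the wild type.
    """
    for rid in list(atp_sulfurylase_rxns) + list(aps_kinase_rxns):
        if not model.has_reaction(rid):
            raise ModelValidationError(f"knockout target {rid!r} not in model")
    _require_exchange(model, pap_exchange)
    base = model.copy()
    if dbt_exchange is not None and base.has_reaction(dbt_exchange):
        base.set_bounds(dbt_exchange, dbt_uptake, 0.0)
    for ex in closed_sulfur:
        if base.has_reaction(ex):
            base.set_bounds(ex, 0.0, base.reaction(ex).upper_bound)

    def run(label: str, knock: bool, pap_open: bool) -> ScenarioResult:
        conditioned = base.copy()
        if knock:
            for rid in list(atp_sulfurylase_rxns) + list(aps_kinase_rxns):
                conditioned.set_bounds(rid, 0.0, 0.0)
        ub = conditioned.reaction(pap_exchange).upper_bound
        if pap_open:
            conditioned.set_bounds(pap_exchange, pap_uptake, ub)
        else:
            conditioned.set_bounds(pap_exchange, 0.0, ub)
        res = solve_fba(conditioned, check_orientation=False)
        growth = res.objective_value if res.optimal else 0.0
        tracked = {}
        if res.optimal and conditioned.has_reaction("DSZB"):
            tracked["DSZB"] = res.fluxes["DSZB"]
        return ScenarioResult(label=label, status=res.status,
                              growth=growth or 0.0, tracked_fluxes=tracked)

    return {
        "wild_type": run("wild type", knock=False, pap_open=False),
        "knockout": run("knockout, no PAP", knock=True, pap_open=False),
        "knockout_plus_pap": run("knockout + PAP feed", knock=True,
                                 pap_open=True),
    }
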