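"""Biomass pseudo-reaction assembly from macromolecular composition.

The biomass reaction drains precursor metabolites in growth proportions; by
convention its stoichiometry is normalized so that one flux unit consumes
1 g of precursors per gDW, i.e. the biomass "molecular weight" is
1,000 g/mol.  Given class mass fractions (protein, carbohydrate, lipid, ...)
and per-class precursor tables, coefficients follow in closed form:

    coefficient_p  =  target_mw/1000 · m_p / M_p      [mmol · gDW⁻¹]

where m_p is the precursor's mass share (g/g) and M_p its molar mass
(g/mmol).  This deterministic proportional rescaling replaces the
spreadsheet-solver step sometimes used for the same normalization and is
exactly equivalent for this linear objective.

Energy-maintenance turnover (growth-associated ATP hydrolysis) is part of
the reaction but excluded from the molecular-weight sum: it is turnover,
not mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

from .core import Metabolite, Reaction, parse_formula

__all__ = [
    "BiomassComposition",
    "BiomassError",
    "assemble_biomass",
    "biomass_molecular_weight",
    "DEFAULT_ENERGY_SPECIES",
]

#: energy-cycle species excluded from the biomass molecular weight;
#: ATP/H2O consumption and ADP/Pi release are maintenance turnover
DEFAULT_ENERGY_SPECIES = frozenset(
    {"atp[c]", "adp[c]", "pi[c]", "h2o[c]", "h[c]", "ppi[c]"}
)


class BiomassError(ValueError):
    """Raised for invalid biomass compositions."""


@dataclass
class BiomassComposition:
    """Macromolecular composition of one gram of dry biomass.

    ``class_fractions`` maps macromolecule classes to mass fractions (g/g);
    they are normalized to sum to 1.  ``precursors`` maps each class to a
    table ``{metabolite id: (molar mass g/mmol, relative molar abundance)}``.
    ``sulfur_enrichment`` multiplies the relative abundance of every
    precursor whose formula contains sulfur (factor > 1 models the elevated
    S-amino-acid/cofactor content of desulfurizing organisms); the
    composition is re-normalized afterwards, so enrichment shifts mass
    toward sulfur species.  ``maintenance_atp`` is growth-associated ATP
    hydrolysis in mmol per gDW.
    """

    class_fractions: Dict[str, float]
    precursors: Dict[str, Dict[str, Tuple[float, float]]]
    sulfur_enrichment: float = 1.0
    maintenance_atp: float = 30.0
    formulas: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.sulfur_enrichment <= 0:
            raise BiomassError("sulfur enrichment factor must be positive")
        for k, f in self.class_fractions.items():
            if f < 0:
                raise BiomassError(f"class fraction for {k!r} is negative")
        total = sum(self.class_fractions.values())
        if total <= 0:
            raise BiomassError("class fractions sum to zero")
        missing = set(self.class_fractions) - set(self.precursors)
        if missing:
            raise BiomassError(f"no precursor table for classes {sorted(missing)}")

    def _is_sulfurous(self, met_id: str) -> bool:
        formula = self.formulas.get(met_id)
        if formula is None:
            return False
        return parse_formula(formula).get("S", 0) > 0

    def mass_shares(self) -> Dict[str, float]:
        """Per-precursor mass shares (g per g biomass), after sulfur
        enrichment and normalization to unit total mass."""
        raw: Dict[str, float] = {}
        total_fraction = sum(self.class_fractions.values())
        for cls, fraction in self.class_fractions.items():
            fraction = fraction / total_fraction
            table = self.precursors[cls]
            if not table:
                raise BiomassError(f"empty precursor table for class {cls!r}")
            weights = {}
            for met_id, (molar_mass, abundance) in table.items():
                if molar_mass <= 0:
                    raise BiomassError(
                        f"precursor {met_id!r} has non-positive molar mass"
                    )
                if abundance < 0:
                    raise BiomassError(
                        f"precursor {met_id!r} has negative abundance"
                    )
                factor = (self.sulfur_enrichment
                          if self._is_sulfurous(met_id) else 1.0)
                weights[met_id] = abundance * factor * molar_mass
            denom = sum(weights.values())
            if denom <= 0:
                raise BiomassError(f"class {cls!r} has zero total mass")
            for met_id, w in weights.items():
                raw[met_id] = raw.get(met_id, 0.0) + fraction * w / denom
        total = sum(raw.values())
        return {m: v / total for m, v in raw.items()}

    def molar_masses(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for table in self.precursors.values():
            for met_id, (molar_mass, _) in table.items():
                out[met_id] = molar_mass
        return out

    def sulfur_per_gram(self) -> float:
        """mmol sulfur atoms per gram of biomass, from precursor formulas."""
        shares = self.mass_shares()
        masses = self.molar_masses()
        total = 0.0
        for met_id, share in shares.items():
            formula = self.formulas.get(met_id)
            if formula is None:
                continue
            n_s = parse_formula(formula).get("S", 0.0)
            total += n_s * share / masses[met_id]
        return total


def assemble_biomass(composition: BiomassComposition,
                     target_mw: float = 1000.0,
                     model_metabolites: Optional[Iterable[str]] = None,
                     reaction_id: str = "BIOMASS",
                     energy_species: Mapping[str, float] = None,
                     ) -> Reaction:
    """Build the biomass pseudo-reaction from a macromolecular composition.

    Substrate coefficients (mmol/gDW) are scaled so that the mass-weighted
    coefficient sum equals ``target_mw``/1000 g per gDW, i.e. the biomass
    molecular weight is exactly ``target_mw`` g/mol.  ATP maintenance is
    appended as ATP + H2O -> ADP + Pi turnover (``energy_species`` may remap
    the four species ids; pass an empty mapping to omit maintenance).
    """
    if target_mw <= 0:
        raise BiomassError("target molecular weight must be positive")
    shares = composition.mass_shares()
    masses = composition.molar_masses()
    if model_metabolites is not None:
        known = set(model_metabolites)
        missing = sorted(set(shares) - known)
        if missing:
            raise BiomassError(
                f"biomass precursors absent from the model: {missing}"
            )
    scale = target_mw / 1000.0
    stoich = {met_id: -scale * share / masses[met_id]
              for met_id, share in shares.items()}

    if energy_species is None:
        energy_species = {"atp": "atp[c]", "h2o": "h2o[c]",
                          "adp": "adp[c]", "pi": "pi[c]"}
    gam = composition.maintenance_atp
    if gam > 0 and energy_species:
        stoich[energy_species["atp"]] = stoich.get(energy_species["atp"], 0.0) - gam
        stoich[energy_species["h2o"]] = stoich.get(energy_species["h2o"], 0.0) - gam
        stoich[energy_species["adp"]] = stoich.get(energy_species["adp"], 0.0) + gam
        stoich[energy_species["pi"]] = stoich.get(energy_species["pi"], 0.0) + gam

    return Reaction(
        id=reaction_id,
        name="biomass pseudo-reaction",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        kind="biomass",
        subsystem="biomass",
    )


def biomass_molecular_weight(reaction: Reaction,
                             masses: Mapping[str, float],
                             energy_species: Iterable[str] = DEFAULT_ENERGY_SPECIES,
                             ) -> float:
    """Molecular weight (g/mol) implied by a biomass reaction.

    Sums |coefficient| x molar mass over consumed precursors minus produced
    byproducts, x1000; energy-cycle species are excluded.  Raises
    :class:`BiomassError` when a participating species has no molar mass.
    """
    skip = set(energy_species)
    total = 0.0
    for met_id, coef in reaction.stoichiometry.items():
        if met_id in skip:
            continue
        if met_id not in masses:
            raise BiomassError(f"no molar mass for biomass participant {met_id!r}")
        total += -coef * masses[met_id]   # consumed (negative) adds mass
    return 1000.0 * total
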