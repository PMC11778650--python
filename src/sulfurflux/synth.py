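"""Synthetic desulfurization model and reference-data generators.

:func:`build_desulfurization_toy` emits a compact (~60 reaction) fungal-style
metabolic network with the structure the analyses in this package assume:

* four carbon sources (glucose, ethanol, glycerol, succinate; 6/2/3/4
  carbons) feeding a lumped central metabolism (pyruvate, NAD(P)H, ATP);
* the assimilatory sulfate branch sulfate -> APS -> PAPS -> sulfite ->
  sulfide -> cysteine -> methionine/glutathione, with choline sulfate made
  from PAPS and PAP released as the activation byproduct;
* the 4S dibenzothiophene branch DBT -> DBTO -> DBTO2 -> HBPS ->
  2-HBP + sulfite, each oxidation consuming one FMNH2 regenerated from NADH
  by a flavin reductase;
* a downstream aromatic oxidation shunt for 2-HBP (the organism this toy
  emulates degrades aromatic compounds), which is what gives the pathway
  end product its positive shadow price at the optimum;
* a biomass reaction assembled from a bundled synthetic macromolecular
  composition, normalized to a molecular weight of 1,000 g/mol.

All toy formulas are simplified but self-consistent (DBT is C12H8S and each
4S oxidation adds one O), every non-exchange reaction is elementally
balanced by construction (asserted at build time), and generation is a pure
function of the config, seed included.

The bundled composition is illustrative, not a measured composition of any
real organism; the manifest of modelling assumptions lives in
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .biomass import BiomassComposition, assemble_biomass
from .core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    formula_weight,
    parse_formula,
)
from .essentiality import (
    ConfusionMatrix,
    EssentialityCall,
    OrthologMap,
    single_gene_deletion,
)

__all__ = [
    "ToyModelConfig",
    "ReferenceConfig",
    "ToyConfigError",
    "build_desulfurization_toy",
    "default_composition",
    "generate_reference",
    "generate_reference_table",
    "CARBON_SOURCES",
    "FOUR_S_REACTIONS",
]

BIG = 1000.0

#: carbon source exchange ids with carbons per molecule
CARBON_SOURCES: Dict[str, int] = {
    "EX_glc": 6, "EX_etoh": 2, "EX_glyc": 3, "EX_succ": 4,
}

#: the 4S chain reaction ids in pathway order
FOUR_S_REACTIONS = ("DSZC1", "DSZC2", "DSZA", "DSZB")

_FORMULAS: Dict[str, str] = {
    "glc": "C6H12O6", "etoh": "C2H6O", "glyc": "C3H8O3", "succ": "C4H6O4",
    "pyr": "C3H4O3", "o2": "O2", "co2": "CO2", "nh3": "H3N", "h2o": "H2O",
    "pi": "H3O4P", "ppi": "H4O7P2",
    "atp": "C10H16N5O13P3", "adp": "C10H15N5O10P2", "amp": "C10H14N5O7P",
    "nad": "C21H27N7O14P2", "nadh": "C21H29N7O14P2",
    "nadp": "C21H28N7O17P3", "nadph": "C21H30N7O17P3",
    "fmn": "C17H21N4O9P", "fmnh2": "C17H23N4O9P",
    "so4": "H2O4S", "slf": "H2O3S", "h2s": "H2S",
    "aps": "C10H14N5O10PS", "paps": "C10H15N5O13P2S", "pap": "C10H15N5O10P2",
    "cho": "C5H13NO", "chos": "C5H13NO4S",
    "dbt": "C12H8S", "dbto": "C12H8OS", "dbto2": "C12H8O2S",
    "hbps": "C12H10O3S", "hbp": "C12H10O", "hbpd": "C12H10O2",
    "ala": "C3H7NO2", "cys": "C3H7NO2S", "met": "C5H11NO2S",
    "gsh": "C10H17N3O6S", "carb": "C6H10O5", "lipid": "C16H32O2",
    "pig": "C9H10O4",
}

_NAMES: Dict[str, str] = {
    "glc": "D-glucose", "etoh": "ethanol", "glyc": "glycerol",
    "succ": "succinate", "pyr": "pyruvate", "o2": "oxygen",
    "co2": "carbon dioxide", "nh3": "ammonia", "h2o": "water",
    "pi": "phosphate", "ppi": "diphosphate", "atp": "ATP", "adp": "ADP",
    "amp": "AMP", "nad": "NAD+", "nadh": "NADH", "nadp": "NADP+",
    "nadph": "NADPH", "fmn": "FMN", "fmnh2": "FMNH2",
    "so4": "sulfate", "slf": "sulfite", "h2s": "hydrogen sulfide",
    "aps": "5'-adenylyl sulfate (APS)",
    "paps": "3'-phospho-5'-adenylyl sulfate (PAPS)",
    "pap": "adenosine 3',5'-bisphosphate (PAP)",
    "cho": "choline", "chos": "choline sulfate",
    "dbt": "dibenzothiophene (DBT)",
    "dbto": "dibenzothiophene 5-sulfoxide (DBTO)",
    "dbto2": "dibenzothiophene 5-sulfone (DBTO2)",
    "hbps": "2-(2'-hydroxyphenyl)benzenesulfinate (HBPS)",
    "hbp": "2-hydroxybiphenyl (2-HBP)",
    "hbpd": "2,3-dihydroxybiphenyl (2-HBP oxidation product)",
    "ala": "L-alanine (bulk amino acid pool)", "cys": "L-cysteine",
    "met": "L-methionine", "gsh": "glutathione",
    "carb": "carbohydrate unit (glucan)", "lipid": "lipid (palmitate)",
    "pig": "pigment precursor (melanin-like)",
}

#: metabolites that exist extracellularly (have transport + exchange)
_EXTRACELLULAR = [
    "glc", "etoh", "glyc", "succ", "o2", "co2", "nh3", "pi", "h2o",
    "so4", "dbt", "h2s", "slf", "hbp", "hbpd", "pap",
]

#: export-only transports (everything else is reversible passive transport)
_EXPORT_ONLY = {"slf", "hbp", "hbpd"}


class ToyConfigError(ValueError):
    """Raised for internally inconsistent toy configurations."""


@dataclass(frozen=True)
class ToyModelConfig:
    """Configuration of the synthetic desulfurization model.

    ``fmnh2_per_step`` is the flavin cost of each 4S oxidation (the uniform
    per-step cost is what produces the 1:2:3 shadow-price progression along
    the chain).  ``po_ratio`` is the ATP yield per NADH respired.
    ``pap_in_biomass`` gates the sulfate-activation-pathway demand in
    biomass (PAP and choline sulfate stand or fall together).  ``n_decoys``
    seeded isozyme-duplicate reactions give the essentiality scan nontrivial
    non-essential genes.
    """

    carbon_sources: Tuple[str, ...] = ("glc", "etoh", "glyc", "succ")
    po_ratio: float = 2.0
    four_s: bool = True
    fmnh2_per_step: float = 1.0
    hbp_oxidation: bool = True
    sulfate_assimilation: bool = True
    pap_in_biomass: bool = True
    sulfur_enrichment: float = 1.2
    maintenance_atp: float = 30.0
    ngam_atp: float = 1.0
    target_biomass_mw: float = 1000.0
    n_decoys: int = 3
    seed: int = 42

    def validate(self) -> "ToyModelConfig":
        if not self.carbon_sources:
            raise ToyConfigError("at least one carbon source is required")
        unknown = [c for c in self.carbon_sources
                   if f"EX_{c}" not in CARBON_SOURCES]
        if unknown:
            raise ToyConfigError(f"unknown carbon sources {unknown}")
        if not (self.four_s or self.sulfate_assimilation):
            raise ToyConfigError(
                "growth is expected but no sulfur route is enabled "
                "(need the 4S chain and/or sulfate assimilation)"
            )
        if self.fmnh2_per_step <= 0 or self.po_ratio <= 0:
            raise ToyConfigError("fmnh2_per_step and po_ratio must be positive")
        return self


def _c(met: str) -> str:
    return f"{met}[c]"


def _e(met: str) -> str:
    return f"{met}[e]"


def _assert_balanced(rxn_id: str, stoich: Dict[str, float]) -> None:
    """Elemental bookkeeping: every generated non-exchange reaction must
    conserve every element (generator contract)."""
    delta: Dict[str, float] = {}
    for met_id, coef in stoich.items():
        base = met_id.rsplit("[", 1)[0]
        for el, n in parse_formula(_FORMULAS[base]).items():
            delta[el] = delta.get(el, 0.0) + coef * n
    bad = {el: d for el, d in delta.items() if abs(d) > 1e-9}
    if bad:
        raise AssertionError(f"generated reaction {rxn_id} is unbalanced: {bad}")


def default_composition(pap_in_biomass: bool = True,
                        sulfur_enrichment: float = 1.2,
                        maintenance_atp: float = 30.0) -> BiomassComposition:
    """The bundled synthetic macromolecular composition (illustrative, not a
    measured composition).  Molar masses derive from the toy formulas."""
    def mm(met: str) -> float:
        return formula_weight(_FORMULAS[met]) / 1000.0   # g/mmol

    cofactors: Dict[str, Tuple[float, float]] = {_c("gsh"): (mm("gsh"), 0.5)}
    if pap_in_biomass:
        cofactors[_c("pap")] = (mm("pap"), 0.3)
        cofactors[_c("chos")] = (mm("chos"), 0.2)

    return BiomassComposition(
        class_fractions={
            "protein": 0.45, "carbohydrate": 0.25, "lipid": 0.12,
            "nucleic_acid": 0.10, "cofactor": 0.05, "pigment": 0.03,
        },
        precursors={
            "protein": {
                _c("ala"): (mm("ala"), 0.75),
                _c("cys"): (mm("cys"), 0.12),
                _c("met"): (mm("met"), 0.13),
            },
            "carbohydrate": {_c("carb"): (mm("carb"), 1.0)},
            "lipid": {_c("lipid"): (mm("lipid"), 1.0)},
            "nucleic_acid": {_c("amp"): (mm("amp"), 1.0)},
            "cofactor": cofactors,
            "pigment": {_c("pig"): (mm("pig"), 1.0)},
        },
        sulfur_enrichment=sulfur_enrichment,
        maintenance_atp=maintenance_atp,
        formulas={_c(m): f for m, f in _FORMULAS.items()},
    )


def _core_reactions(cfg: ToyModelConfig) -> List[Reaction]:
    p = cfg.po_ratio
    f = cfg.fmnh2_per_step
    R: List[Tuple[str, str, Dict[str, float], float, float, str, str]] = []

    def add(rid, name, stoich, gpr="", lb=0.0, ub=BIG, subsystem="central"):
        R.append((rid, name, stoich, lb, ub, gpr, subsystem))

    # -- carbon assimilation to pyruvate (lumped) -------------------------
    if "glc" in cfg.carbon_sources:
        add("GLK", "glycolysis (lumped)",
            {_c("glc"): -1, _c("nad"): -2, _c("adp"): -2, _c("pi"): -2,
             _c("pyr"): 2, _c("nadh"): 2, _c("atp"): 2, _c("h2o"): 2},
            gpr="g_glk1 or g_glk2")
    if "etoh" in cfg.carbon_sources:
        add("ETA", "ethanol assimilation (lumped carboxylation)",
            {_c("etoh"): -1, _c("co2"): -1, _c("nad"): -1, _c("atp"): -1,
             _c("h2o"): -1, _c("pyr"): 1, _c("nadh"): 1, _c("adp"): 1,
             _c("pi"): 1},
            gpr="g_adh")
    if "glyc" in cfg.carbon_sources:
        add("GLY", "glycerol assimilation (lumped)",
            {_c("glyc"): -1, _c("nad"): -2, _c("adp"): -1, _c("pi"): -1,
             _c("pyr"): 1, _c("nadh"): 2, _c("atp"): 1, _c("h2o"): 1},
            gpr="g_glpk")
    if "succ" in cfg.carbon_sources:
        add("SCA", "succinate assimilation (lumped)",
            {_c("succ"): -1, _c("h2o"): -1, _c("nad"): -2,
             _c("pyr"): 1, _c("co2"): 1, _c("nadh"): 2},
            gpr="g_sdh")

    # -- energy metabolism ------------------------------------------------
    add("PDH", "pyruvate oxidation (lumped TCA)",
        {_c("pyr"): -1, _c("h2o"): -3, _c("nad"): -5,
         _c("co2"): 3, _c("nadh"): 5},
        gpr="g_pdh1 and g_pdh2")
    add("RESP", "respiration (NADH -> ATP)",
        {_c("nadh"): -1, _c("o2"): -0.5, _c("adp"): -p, _c("pi"): -p,
         _c("nad"): 1, _c("h2o"): 1 + p, _c("atp"): p},
        gpr="g_cox1 and g_cox2")
    add("THD", "transhydrogenase",
        {_c("nadh"): -1, _c("nadp"): -1, _c("nad"): 1, _c("nadph"): 1},
        gpr="g_thd")
    # non-growth-associated maintenance doubles as the ATP dissipation
    # valve; without it the energy stoichiometry is rigid
    add("ATPM", "non-growth-associated maintenance",
        {_c("atp"): -1, _c("h2o"): -1, _c("adp"): 1, _c("pi"): 1},
        lb=cfg.ngam_atp)
    # links de-novo AMP (and the AMP moiety drained as APS/PAPS/PAP) back
    # into the adenylate pool
    add("ADK", "adenylate kinase",
        {_c("amp"): -1, _c("atp"): -1, _c("adp"): 2},
        gpr="g_adk", lb=-BIG)
    add("FRD", "FMN reductase (DszD)",
        {_c("fmn"): -1, _c("nadh"): -1, _c("fmnh2"): 1, _c("nad"): 1},
        gpr="g_dszD", subsystem="4S pathway")

    # -- precursor biosynthesis (lumped, balanced) ------------------------
    add("ALA_S", "bulk amino-acid synthesis",
        {_c("pyr"): -1, _c("nh3"): -1, _c("nadh"): -1, _c("atp"): -1,
         _c("ala"): 1, _c("nad"): 1, _c("adp"): 1, _c("pi"): 1},
        gpr="g_alaT", subsystem="biosynthesis")
    add("CYS_S", "cysteine synthesis",
        {_c("pyr"): -1, _c("nh3"): -1, _c("h2s"): -1,
         _c("cys"): 1, _c("h2o"): 1},
        gpr="g_cysK1 or g_cysK2", subsystem="sulfur assimilation")
    add("MET_S", "methionine synthesis",
        {_c("cys"): -1, _c("pyr"): -1, _c("nadh"): -1,
         _c("met"): 1, _c("co2"): 1, _c("h2o"): 1, _c("nad"): 1},
        gpr="g_metE", subsystem="sulfur assimilation")
    add("GSH_S", "glutathione synthesis",
        {_c("cys"): -1, _c("pyr"): -3, _c("nh3"): -2, _c("nad"): -3,
         _c("atp"): -2, _c("h2o"): -1,
         _c("gsh"): 1, _c("co2"): 2, _c("nadh"): 3, _c("adp"): 2,
         _c("pi"): 2},
        gpr="g_gsh1 and g_gsh2", subsystem="sulfur assimilation")
    add("CHO_S", "choline synthesis",
        {_c("pyr"): -2, _c("nh3"): -1, _c("nadh"): -4, _c("atp"): -1,
         _c("cho"): 1, _c("co2"): 1, _c("h2o"): 2, _c("nad"): 4,
         _c("adp"): 1, _c("pi"): 1},
        gpr="g_cho", subsystem="biosynthesis")
    add("CRB_S", "storage carbohydrate synthesis (gluconeogenic)",
        {_c("pyr"): -2, _c("nadh"): -2, _c("atp"): -4, _c("h2o"): -3,
         _c("carb"): 1, _c("nad"): 2, _c("adp"): 4, _c("pi"): 4},
        gpr="g_pck", subsystem="biosynthesis")
    add("LIP_S", "lipid synthesis",
        {_c("pyr"): -8, _c("nadh"): -6, _c("atp"): -7, _c("h2o"): -1,
         _c("lipid"): 1, _c("co2"): 8, _c("nad"): 6, _c("adp"): 7,
         _c("pi"): 7},
        gpr="g_fas", subsystem="biosynthesis")
    add("NUC_S", "nucleotide synthesis",
        {_c("pyr"): -4, _c("nh3"): -5, _c("nad"): -5, _c("atp"): -4,
         _c("amp"): 1, _c("co2"): 2, _c("h2o"): 1, _c("nadh"): 5,
         _c("adp"): 4, _c("pi"): 3},
        gpr="g_ade", subsystem="biosynthesis")
    add("PIG_S", "pigment precursor synthesis",
        {_c("pyr"): -3, _c("nadh"): -4,
         _c("pig"): 1, _c("h2o"): 5, _c("nad"): 4},
        gpr="g_pks and g_lac", subsystem="pigment")

    # -- sulfate assimilation ---------------------------------------------
    if cfg.sulfate_assimilation:
        add("SULY", "ATP sulfurylase (EC 2.7.7.4)",
            {_c("so4"): -1, _c("atp"): -1, _c("aps"): 1, _c("ppi"): 1},
            gpr="g_met3", subsystem="sulfur assimilation")
        add("PPA", "inorganic pyrophosphatase",
            {_c("ppi"): -1, _c("h2o"): -1, _c("pi"): 2},
            gpr="g_ppa")
        add("APSK", "APS kinase (EC 2.7.1.25)",
            {_c("aps"): -1, _c("atp"): -1, _c("paps"): 1, _c("adp"): 1},
            gpr="g_met14", subsystem="sulfur assimilation")
        add("PAPSR", "PAPS reductase",
            {_c("paps"): -1, _c("nadph"): -1,
             _c("slf"): 1, _c("pap"): 1, _c("nadp"): 1},
            gpr="g_met16", lb=-BIG, subsystem="sulfur assimilation")
        add("SOTR", "choline sulfotransferase",
            {_c("paps"): -1, _c("cho"): -1, _c("chos"): 1, _c("pap"): 1},
            gpr="g_sot", subsystem="sulfur assimilation")
        # PAP recycling back to the adenylate pool; without it every pass
        # through the activation branch exports an adenylate moiety
        add("PAPN", "PAP 3'-nucleotidase",
            {_c("pap"): -1, _c("h2o"): -1, _c("amp"): 1, _c("pi"): 1},
            gpr="g_met22", subsystem="sulfur assimilation")
    add("SLFR", "sulfite reductase",
        {_c("slf"): -1, _c("nadph"): -3,
         _c("h2s"): 1, _c("h2o"): 3, _c("nadp"): 3},
        gpr="g_met5 and g_met10", subsystem="sulfur assimilation")
    add("SOX", "sulfite oxidase",
        {_c("slf"): -1, _c("o2"): -0.5, _c("so4"): 1},
        gpr="g_sox", subsystem="sulfur assimilation")

    # -- the 4S desulfurization chain -------------------------------------
    if cfg.four_s:
        # oxygen/water coefficients keep the steps balanced for any flavin
        # cost f: surplus FMNH2 hydrogens leave as water
        add("DSZC1", "DBT monooxygenase step 1 (DszC)",
            {_c("dbt"): -1, _c("fmnh2"): -f, _c("o2"): -(f + 1) / 2,
             _c("dbto"): 1, _c("fmn"): f, _c("h2o"): f},
            gpr="g_dszC", subsystem="4S pathway")
        add("DSZC2", "DBT monooxygenase step 2 (DszC)",
            {_c("dbto"): -1, _c("fmnh2"): -f, _c("o2"): -(f + 1) / 2,
             _c("dbto2"): 1, _c("fmn"): f, _c("h2o"): f},
            gpr="g_dszC", subsystem="4S pathway")
        dsza = {_c("dbto2"): -1, _c("fmnh2"): -f, _c("o2"): -f / 2,
                _c("hbps"): 1, _c("fmn"): f}
        if f != 1:
            dsza[_c("h2o")] = f - 1
        add("DSZA", "DBT sulfone monooxygenase (DszA)", dsza,
            gpr="g_dszA", subsystem="4S pathway")
        add("DSZB", "HBPS desulfinase (DszB)",
            {_c("hbps"): -1, _c("h2o"): -1, _c("hbp"): 1, _c("slf"): 1},
            gpr="g_dszB", subsystem="4S pathway")
        if cfg.hbp_oxidation:
            # first step of downstream aromatic degradation: an
            # NADH-dependent ring monooxygenase; making 2-HBP's only
            # disposal route reductant-consuming is what gives the pathway
            # end product its positive shadow price
            add("HBPMO", "2-HBP ring monooxygenase (downstream degradation)",
                {_c("hbp"): -1, _c("nadh"): -1, _c("o2"): -1,
                 _c("hbpd"): 1, _c("nad"): 1, _c("h2o"): 1},
                gpr="g_hox", subsystem="aromatic degradation")

    out = []
    for rid, name, stoich, lb, ub, gpr, subsystem in R:
        _assert_balanced(rid, stoich)
        out.append(Reaction(id=rid, name=name, stoichiometry=stoich,
                            lower_bound=lb, upper_bound=ub, gpr=gpr,
                            kind="metabolic", subsystem=subsystem))
    return out


def _boundary_reactions(cfg: ToyModelConfig) -> List[Reaction]:
    out: List[Reaction] = []
    skip = set()
    if not cfg.four_s:
        skip.update({"dbt", "hbp", "hbpd"})
    elif not cfg.hbp_oxidation:
        skip.add("hbpd")
    for met in _EXTRACELLULAR:
        if met in skip:
            continue
        # transport
        if met in _EXPORT_ONLY:
            lb, ub = 0.0, BIG
        else:
            lb, ub = -BIG, BIG
        if met == "hbp" and cfg.hbp_oxidation:
            lb, ub = 0.0, 0.0   # opened by the titration procedure
        gpr = {"dbt": "g_dbtT", "pap": "g_papT"}.get(met, "")
        stoich = {_e(met): -1.0, _c(met): 1.0}
        if met in _EXPORT_ONLY:
            stoich = {_c(met): -1.0, _e(met): 1.0}
        _assert_balanced(f"t_{met}", stoich)
        out.append(Reaction(id=f"t_{met}", name=f"{_NAMES[met]} transport",
                            stoichiometry=stoich, lower_bound=lb,
                            upper_bound=ub, gpr=gpr, kind="transport",
                            subsystem="transport"))
        # exchange: default reference condition is a minimal glucose/sulfate
        # medium; scenario code reconfigures bounds through MediumSpec
        elb, eub = 0.0, BIG
        if met in ("glc", "so4"):
            elb = -1.0
        elif met in ("o2", "co2", "nh3", "pi", "h2o"):
            elb = -BIG
        elif met == "hbp" and cfg.hbp_oxidation:
            # with the downstream aromatic oxidation active, 2-HBP does not
            # accumulate extracellularly; the titration procedure opens this
            # exchange (and blocks the oxidation) to read the product yield
            eub = 0.0
        out.append(Reaction(id=f"EX_{met}", name=f"{_NAMES[met]} exchange",
                            stoichiometry={_e(met): -1.0}, lower_bound=elb,
                            upper_bound=eub, kind="exchange",
                            subsystem="exchange"))
    return out


def _decoy_reactions(cfg: ToyModelConfig, pool: List[Reaction]
                     ) -> List[Reaction]:
    """Seeded isozyme duplicates of central/biosynthetic reactions, each
    under its own decoy gene; they make the scan's NonEssential class
    nontrivial without touching the sulfur subsystems."""
    rng = np.random.default_rng(cfg.seed)
    eligible = [r for r in pool
                if r.kind == "metabolic"
                and r.subsystem in ("central", "biosynthesis")]
    eligible.sort(key=lambda r: r.id)
    n = min(cfg.n_decoys, len(eligible))
    idx = rng.choice(len(eligible), size=n, replace=False)
    out = []
    for k, i in enumerate(sorted(int(j) for j in idx)):
        src = eligible[i]
        out.append(Reaction(
            id=f"{src.id}_iso{k + 1}",
            name=f"{src.name} (decoy isozyme)",
            stoichiometry=dict(src.stoichiometry),
            lower_bound=src.lower_bound, upper_bound=src.upper_bound,
            gpr=f"g_dec{k + 1}", kind="metabolic",
            subsystem=src.subsystem,
        ))
    return out


def build_desulfurization_toy(config: Optional[ToyModelConfig] = None
                              ) -> MetabolicModel:
    """Generate the synthetic desulfurization model.

    Generation is deterministic in the config (seed included).  The returned
    model is validated, every non-exchange reaction is elementally balanced,
    and the default medium is minimal glucose + sulfate.
    """
    cfg = (config or ToyModelConfig()).validate()

    reactions = _core_reactions(cfg)
    reactions.extend(_boundary_reactions(cfg))
    reactions.extend(_decoy_reactions(cfg, reactions))

    composition = default_composition(
        pap_in_biomass=cfg.pap_in_biomass and cfg.sulfate_assimilation,
        sulfur_enrichment=cfg.sulfur_enrichment,
        maintenance_atp=cfg.maintenance_atp,
    )
    biomass_rxn = assemble_biomass(composition,
                                   target_mw=cfg.target_biomass_mw)
    reactions.append(biomass_rxn)

    met_ids = sorted({m for r in reactions for m in r.stoichiometry})
    metabolites = []
    for met_id in met_ids:
        base = met_id.rsplit("[", 1)[0]
        metabolites.append(Metabolite(
            id=met_id, name=_NAMES.get(base, base),
            formula=_FORMULAS[base], charge=0,
        ))
    genes = sorted({g for r in reactions for g in r.gpr.genes})

    model = MetabolicModel(
        metabolites=metabolites, reactions=reactions, genes=genes,
        objective=biomass_rxn.id,
        compartments={"c": "cytosol", "e": "extracellular"},
        name=f"toy desulfurization model (seed {cfg.seed})",
    )
    return model.validate()


# ---------------------------------------------------------------------------
# Synthetic essentiality references
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceConfig:
    """Controls the synthetic ortholog/essentiality reference.

    ``agreement`` is the per-gene probability that the reference class
    matches the in-silico truth; ``essential_fraction`` is only used by the
    model-free table generator.
    """

    n_genes: Optional[int] = None
    essential_fraction: float = 0.10
    agreement: float = 1.0
    evalue_threshold: float = 1e-6
    seed: int = 0

    def validate(self) -> "ReferenceConfig":
        if not (0.0 <= self.agreement <= 1.0):
            raise ToyConfigError("agreement rate must be in [0, 1]")
        if not (0.0 <= self.essential_fraction <= 1.0):
            raise ToyConfigError("essential fraction must be in [0, 1]")
        return self


def _flip(call: str) -> str:
    return "NE" if call == "E" else "E"


def _build_reference(true_calls: Dict[str, str], cfg: ReferenceConfig
                     ) -> Tuple[OrthologMap, Dict[str, str], ConfusionMatrix]:
    rng = np.random.default_rng(cfg.seed)
    genes = list(true_calls)
    rows: List[Tuple[str, str, float]] = []
    reference: Dict[str, str] = {}
    planted = ConfusionMatrix()
    for gene in genes:
        ref_gene = f"Y{gene.upper()}"
        evalue = 10.0 ** (-rng.uniform(10, 50))
        rows.append((gene, ref_gene, evalue))
        truth = true_calls[gene]
        agrees = rng.random() < cfg.agreement
        ref_class = truth if agrees else _flip(truth)
        reference[ref_gene] = ref_class
        planted.n_shared += 1
        key = {"EE": "ee", "EN": "en", "NE": "ne", "NN": "nn"}[
            ("E" if ref_class == "E" else "N") + ("E" if truth == "E" else "N")
        ]
        setattr(planted, key, getattr(planted, key) + 1)
    # a few above-threshold rows exercise the E-value filter without
    # affecting the comparison
    for k in range(3):
        rows.append((genes[k % len(genes)], f"YDECOY{k}", 1e-3))
    return OrthologMap(rows=rows, evalue_threshold=cfg.evalue_threshold), \
        reference, planted


def generate_reference(model: MetabolicModel,
                       config: Optional[ReferenceConfig] = None,
                       calls: Optional[List[EssentialityCall]] = None,
                       ) -> Tuple[OrthologMap, Dict[str, str], ConfusionMatrix]:
    """Synthetic ortholog map + reference call table for ``model``.

    The reference agrees with the model's true single-gene-deletion scan at
    the configured rate in expectation; the returned planted confusion
    matrix is the exact bookkeeping of the flips, so the validator's output
    must reproduce it when run on the same scan.
    """
    cfg = (config or ReferenceConfig()).validate()
    if calls is None:
        calls = single_gene_deletion(model)
    true_calls = {c.gene: c.call for c in calls}
    if cfg.n_genes is not None:
        if cfg.n_genes > len(true_calls):
            raise ToyConfigError(
                f"n_genes={cfg.n_genes} exceeds the model's {len(true_calls)} genes"
            )
        rng = np.random.default_rng(cfg.seed)
        keep = rng.choice(sorted(true_calls), size=cfg.n_genes, replace=False)
        true_calls = {g: true_calls[g] for g in keep}
    return _build_reference(true_calls, cfg)


def generate_reference_table(config: ReferenceConfig
                             ) -> Tuple[OrthologMap, Dict[str, str],
                                        Dict[str, str], ConfusionMatrix]:
    """Model-free variant: synthesizes ``n_genes`` in-silico truth calls at
    ``essential_fraction`` and a reference at the configured agreement.
    Returns (ortholog map, reference table, true calls, planted counts)."""
    cfg = config.validate()
    if cfg.n_genes is None:
        raise ToyConfigError("n_genes is required for the model-free generator")
    if cfg.n_genes < 1:
        raise ToyConfigError("n_genes must be at least 1")
    rng = np.random.default_rng(cfg.seed + 1)
    true_calls = {
        f"g{i:05d}": ("E" if rng.random() < cfg.essential_fraction else "NE")
        for i in range(cfg.n_genes)
    }
    omap, reference, planted = _build_reference(true_calls, cfg)
    return omap, reference, true_calls, planted
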