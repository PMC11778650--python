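"""Model and medium I/O.

The primary on-disk format is a tabular workbook (XLSX) with Reactions,
Metabolites and Genes sheets, mirroring the supplementary-file dialect in
which curated genome-scale reconstructions are commonly distributed.
Column headers are matched case-insensitively through an alias table (the
resolved mapping is logged), reaction equations use the
``2 A[c] + B[c] -> C[p]`` / ``<=>`` syntax, and unparseable rows are
collected into a structured issue report rather than silently dropped —
except for errors that make the model unusable (missing sheets, duplicate
ids, unknown metabolites), which are fatal with the row named.

Media are read/written as 3-column TSV (exchange_id, lower, upper; the word
``present`` in the bounds columns selects the standard (-1, 1) window) or
as YAML.  SBML Level 3 + FBC import/export is available when python-libsbml
is importable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import openpyxl

from .core import (
    GeneProductRule,
    MediumSpec,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_gpr,
)

__all__ = [
    "WorkbookError",
    "IssueReport",
    "parse_model_workbook",
    "write_model_workbook",
    "read_medium",
    "write_medium",
    "read_sbml",
    "write_sbml",
    "read_reference_table",
    "read_ortholog_map",
]

logger = logging.getLogger(__name__)


class WorkbookError(ModelValidationError):
    """Fatal workbook problem (missing sheet, duplicate id, unknown
    metabolite); carries the offending row when applicable."""


@dataclass
class IssueReport:
    """Non-fatal parse issues: (sheet, row number, message) triples."""

    issues: List[Tuple[str, int, str]] = field(default_factory=list)

    def add(self, sheet: str, row: int, message: str):
        self.issues.append((sheet, row, message))

    def __len__(self):
        return len(self.issues)


#: canonical column name -> accepted aliases (case-insensitive)
COLUMN_ALIASES: Dict[str, Tuple[str, ...]] = {
    "id": ("id", "rxn id", "reaction id", "abbreviation", "met id",
           "metabolite id", "gene id", "gene"),
    "name": ("name", "description", "reaction name", "metabolite name"),
    "equation": ("equation", "reaction", "formula (equation)", "rxn formula"),
    "lower_bound": ("lower_bound", "lb", "lower bound", "min flux"),
    "upper_bound": ("upper_bound", "ub", "upper bound", "max flux"),
    "gpr": ("gpr", "gene association", "gene-reaction rule", "grrule",
            "gene_reaction_rule"),
    "kind": ("kind", "type", "reaction type"),
    "subsystem": ("subsystem", "pathway"),
    "formula": ("formula", "chemical formula", "elemental formula"),
    "charge": ("charge",),
    "compartment": ("compartment", "comp"),
}

_EQ_ARROWS = ("<=>", "<->", "->", "=>")
_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S.*?)\s*$")


def _resolve_columns(header: List[Optional[str]], wanted: List[str],
                     sheet: str) -> Dict[str, int]:
    lookup = {}
    for idx, cell in enumerate(header):
        if cell is None:
            continue
        lookup[str(cell).strip().lower()] = idx
    resolved = {}
    for name in wanted:
        for alias in COLUMN_ALIASES[name]:
            if alias in lookup:
                resolved[name] = lookup[alias]
                break
    logger.info("workbook sheet %r: resolved columns %s", sheet,
                {k: header[v] for k, v in resolved.items()})
    return resolved


def parse_equation(text: str, row: int = -1, sheet: str = "Reactions"
                   ) -> Tuple[Dict[str, float], bool]:
    """Parse ``"2 A[c] + B[c] -> C[p]"`` into (stoichiometry, reversible)."""
    arrow = None
    for a in _EQ_ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise WorkbookError(
            f"{sheet} row {row}: equation {text!r} has no arrow")
    left, right = text.split(arrow, 1)
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            m = _TERM_RE.match(term)
            if not m or not m.group(2):
                raise WorkbookError(
                    f"{sheet} row {row}: cannot parse term {term!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2).strip()
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    return stoich, arrow in ("<=>", "<->")


def _sheet(workbook, names: Tuple[str, ...], path) -> Optional[object]:
    for name in workbook.sheetnames:
        if name.strip().lower() in names:
            return workbook[name]
    return None


def parse_model_workbook(path, objective: Optional[str] = None,
                         validate: bool = True,
                         ) -> Tuple[MetabolicModel, IssueReport]:
    """Read a model workbook; returns (model, issue report).

    Requires Reactions and Metabolites sheets (a Genes sheet is optional —
    genes are otherwise collected from the GPRs).  The objective defaults
    to the unique reaction of kind biomass, or a reaction whose id/name
    contains "biomass".
    """
    path = Path(path)
    if not path.exists():
        raise WorkbookError(f"workbook {path} does not exist")
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    issues = IssueReport()

    met_sheet = _sheet(wb, ("metabolites", "mets"), path)
    rxn_sheet = _sheet(wb, ("reactions", "rxns"), path)
    if met_sheet is None or rxn_sheet is None:
        raise WorkbookError(
            f"workbook {path} lacks a required sheet "
            f"(need Reactions and Metabolites; found {wb.sheetnames})"
        )

    # -- metabolites ------------------------------------------------------
    rows = met_sheet.iter_rows(values_only=True)
    header = list(next(rows))
    cols = _resolve_columns(header, ["id", "name", "formula", "charge"],
                            "Metabolites")
    if "id" not in cols:
        raise WorkbookError("Metabolites sheet has no recognizable id column")
    metabolites: List[Metabolite] = []
    seen = set()
    for i, row in enumerate(rows, start=2):
        raw_id = row[cols["id"]] if cols["id"] < len(row) else None
        if raw_id is None or str(raw_id).strip() == "":
            continue
        met_id = str(raw_id).strip()
        if met_id in seen:
            raise WorkbookError(f"Metabolites row {i}: duplicate id {met_id!r}")
        seen.add(met_id)

        def get(col):
            j = cols.get(col)
            return row[j] if j is not None and j < len(row) else None

        charge = get("charge")
        formula = get("formula")
        try:
            metabolites.append(Metabolite(
                id=met_id,
                name=str(get("name") or ""),
                formula=str(formula).strip() if formula not in (None, "") else None,
                charge=int(charge) if charge not in (None, "") else None,
            ))
        except (ModelValidationError, ValueError) as exc:
            issues.add("Metabolites", i, str(exc))

    # -- reactions --------------------------------------------------------
    rows = rxn_sheet.iter_rows(values_only=True)
    header = list(next(rows))
    cols = _resolve_columns(
        header,
        ["id", "name", "equation", "lower_bound", "upper_bound", "gpr",
         "kind", "subsystem"],
        "Reactions")
    for required in ("id", "equation"):
        if required not in cols:
            raise WorkbookError(
                f"Reactions sheet has no recognizable {required!r} column")
    met_ids = {m.id for m in metabolites}
    reactions: List[Reaction] = []
    seen = set()
    for i, row in enumerate(rows, start=2):
        def get(col):
            j = cols.get(col)
            return row[j] if j is not None and j < len(row) else None

        raw_id = get("id")
        if raw_id is None or str(raw_id).strip() == "":
            continue
        rxn_id = str(raw_id).strip()
        if rxn_id in seen:
            raise WorkbookError(f"Reactions row {i}: duplicate id {rxn_id!r}")
        seen.add(rxn_id)
        equation = str(get("equation") or "")
        stoich, reversible = parse_equation(equation, row=i)
        unknown = sorted(set(stoich) - met_ids)
        if unknown:
            raise WorkbookError(
                f"Reactions row {i}: equation references unknown "
                f"metabolite(s) {unknown}")
        lb = get("lower_bound")
        ub = get("upper_bound")
        lb = float(lb) if lb not in (None, "") else (-1000.0 if reversible else 0.0)
        ub = float(ub) if ub not in (None, "") else 1000.0
        kind = str(get("kind") or "").strip().lower()
        if not kind:
            kind = "exchange" if len(stoich) == 1 else "metabolic"
        try:
            reactions.append(Reaction(
                id=rxn_id, name=str(get("name") or ""),
                stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                gpr=parse_gpr(str(get("gpr") or "")),
                kind=kind, subsystem=str(get("subsystem") or ""),
            ))
        except (ModelValidationError, ValueError) as exc:
            issues.add("Reactions", i, str(exc))

    # -- genes ------------------------------------------------------------
    genes: List[str] = []
    gene_sheet = _sheet(wb, ("genes",), path)
    if gene_sheet is not None:
        rows = gene_sheet.iter_rows(values_only=True)
        header = list(next(rows))
        cols = _resolve_columns(header, ["id"], "Genes")
        if "id" in cols:
            for row in rows:
                val = row[cols["id"]] if cols["id"] < len(row) else None
                if val not in (None, ""):
                    genes.append(str(val).strip())
    gpr_genes = sorted({g for r in reactions for g in r.gpr.genes})
    genes = sorted(set(genes) | set(gpr_genes))

    compartments = sorted({m.compartment for m in metabolites})
    if objective is None:
        biomass = [r.id for r in reactions if r.kind == "biomass"]
        if not biomass:
            biomass = [r.id for r in reactions
                       if "biomass" in r.id.lower()
                       or "biomass" in r.name.lower()]
            for r in reactions:
                if r.id in biomass:
                    r.kind = "biomass"
        objective = biomass[0] if len(biomass) >= 1 else None

    model = MetabolicModel(
        metabolites=metabolites, reactions=reactions, genes=genes,
        objective=objective,
        compartments={c: c for c in compartments},
        name=path.stem,
    )
    if validate:
        model.validate()
    return model, issues


def write_model_workbook(model: MetabolicModel, path) -> Path:
    """Write a model to the workbook dialect; inverse of
    :func:`parse_model_workbook` (round-trip identity up to float
    formatting)."""
    path = Path(path)
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "Reactions"
    ws.append(["id", "name", "equation", "lower_bound", "upper_bound",
               "gpr", "kind", "subsystem"])
    for r in model.reactions:
        ws.append([r.id, r.name, r.equation(), r.lower_bound, r.upper_bound,
                   r.gpr.to_string(), r.kind, r.subsystem])
    ws = wb.create_sheet("Metabolites")
    ws.append(["id", "name", "formula", "charge"])
    for m in model.metabolites:
        ws.append([m.id, m.name, m.formula, m.charge])
    ws = wb.create_sheet("Genes")
    ws.append(["id"])
    for g in model.genes:
        ws.append([g])
    wb.save(path)
    return path


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def read_medium(path) -> MediumSpec:
    """Read a medium from 3-column TSV or from YAML (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(path.read_text())
        entries = {}
        for key, bounds in (data.get("exchanges") or {}).items():
            if bounds == "present":
                entries[key] = ("present", "present")
            else:
                entries[key] = (float(bounds[0]), float(bounds[1]))
        return MediumSpec(entries=entries,
                          default_ub=float(data.get("default_ub", 1000.0)),
                          name=str(data.get("name", path.stem)))
    entries = {}
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in ("exchange_id", "id"):
            continue
        if len(parts) < 3:
            raise ModelValidationError(
                f"{path} line {line_no}: need exchange_id, lb, ub")
        if parts[1] == "present" or parts[2] == "present":
            entries[parts[0]] = ("present", "present")
        else:
            entries[parts[0]] = (float(parts[1]), float(parts[2]))
    return MediumSpec(entries=entries, name=path.stem)


def write_medium(medium: MediumSpec, path) -> Path:
    path = Path(path)
    lines = ["exchange_id\tlb\tub"]
    for key, (lb, ub) in sorted(medium.entries.items()):
        lines.append(f"{key}\t{lb}\t{ub}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Reference tables (essentiality validation inputs)
# ---------------------------------------------------------------------------

def read_reference_table(path) -> Dict[str, str]:
    """TSV of (gene, class) with class in {E, NE}."""
    out: Dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or parts[1] not in ("E", "NE"):
            raise ModelValidationError(
                f"{path} line {line_no}: expected 'gene<TAB>E|NE'")
        out[parts[0]] = parts[1]
    return out


def read_ortholog_map(path, evalue_threshold: float = 1e-6):
    """TSV of (model gene, reference gene, E-value)."""
    from .essentiality import OrthologMap

    rows = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("model_gene"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ModelValidationError(
                f"{path} line {line_no}: expected 'model_gene<TAB>ref_gene<TAB>evalue'")
        rows.append((parts[0], parts[1], float(parts[2])))
    return OrthologMap(rows=rows, evalue_threshold=evalue_threshold)


# ---------------------------------------------------------------------------
# Optional SBML Level 3 + FBC
# ---------------------------------------------------------------------------

def _require_libsbml():
    try:
        import libsbml  # type: ignore
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "SBML support requires python-libsbml, which is not installed; "
            "use the workbook format instead"
        ) from exc
    return libsbml


def write_sbml(model: MetabolicModel, path) -> Path:
    """Export as SBML Level 3 Version 1 with the FBC v2 package."""
    libsbml = _require_libsbml()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(re.sub(r"\W", "_", model.name or "model"))
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(True)

    for code, cname in (model.compartments or
                        {c: c for c in sorted({m.compartment for m in model.metabolites})}).items():
        comp = sm.createCompartment()
        comp.setId(code)
        comp.setName(cname)
        comp.setConstant(True)

    def sid(met_id: str) -> str:
        return "M_" + re.sub(r"\W", "_", met_id)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(sid(m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if m.formula is not None:
            splug.setChemicalFormula(m.formula)
        if m.charge is not None:
            splug.setCharge(int(m.charge))

    for g in model.genes:
        gp = fbc.createGeneProduct()
        gp.setId("G_" + re.sub(r"\W", "_", g))
        gp.setLabel(g)

    # bounds as shared parameters
    bound_params = {}

    def bound_param(value: float) -> str:
        key = f"{value:.10g}"
        if key not in bound_params:
            pid = "fb_%d" % len(bound_params)
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    def gpr_to_association(node, parent):
        if isinstance(node, str):
            ref = parent.createGeneProductRef()
            ref.setGeneProduct("G_" + re.sub(r"\W", "_", node))
        elif node[0] == "and":
            sub = parent.createAnd()
            for child in node[1]:
                gpr_to_association(child, sub)
        else:
            sub = parent.createOr()
            for child in node[1]:
                gpr_to_association(child, sub)

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId("R_" + re.sub(r"\W", "_", r.id))
        rx.setName(r.name or r.id)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for met_id, coef in r.stoichiometry.items():
            if coef < 0:
                ref = rx.createReactant()
            else:
                ref = rx.createProduct()
            ref.setSpecies(sid(met_id))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            gpr_to_association(r.gpr.expression, assoc)

    if model.objective is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + re.sub(r"\W", "_", model.objective))
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))
    return Path(path)


def read_sbml(path, objective: Optional[str] = None) -> MetabolicModel:
    """Import an SBML L3/FBC model.

    Reaction kinds are inferred: single-species boundary conversions become
    exchanges, multi-compartment reactions transports, the objective
    biomass, everything else metabolic.  Identifier prefixes (``M_``,
    ``R_``, ``G_``) are stripped.
    """
    libsbml = _require_libsbml()
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            f"SBML parse errors in {path}: "
            f"{doc.getErrorLog().toString()}"
        )
    sm = doc.getModel()

    def unprefix(s: str, prefix: str) -> str:
        return s[len(prefix):] if s.startswith(prefix) else s

    label_by_gp = {}
    fbc = sm.getPlugin("fbc")
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label_by_gp[gp.getId()] = gp.getLabel() or unprefix(gp.getId(), "G_")

    met_compartment = {}
    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        raw = unprefix(sp.getId(), "M_")
        comp = sp.getCompartment()
        met_id = raw if raw.endswith(f"[{comp}]") else f"{raw}[{comp}]" \
            if not re.search(r"\[[a-zA-Z]\]$", raw) else raw
        met_compartment[sp.getId()] = met_id
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(Metabolite(id=met_id, name=sp.getName() or raw,
                                      formula=formula, charge=charge))

    def association_to_tree(assoc):
        if assoc.isGeneProductRef():
            return label_by_gp.get(assoc.getGeneProduct(),
                                   unprefix(assoc.getGeneProduct(), "G_"))
        children = tuple(association_to_tree(assoc.getAssociation(i))
                         for i in range(assoc.getNumAssociations()))
        return ("and" if assoc.isFbcAnd() else "or", children)

    objective_id = objective
    if objective_id is None and fbc is not None:
        active = fbc.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = unprefix(
                active.getFluxObjective(0).getReaction(), "R_")

    params = {sm.getParameter(i).getId(): sm.getParameter(i).getValue()
              for i in range(sm.getNumParameters())}
    reactions = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        rid = unprefix(rx.getId(), "R_")
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = met_compartment[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = met_compartment[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb = params.get(rplug.getLowerFluxBound(), -1000.0) \
            if rplug is not None else -1000.0
        ub = params.get(rplug.getUpperFluxBound(), 1000.0) \
            if rplug is not None else 1000.0
        gpr = GeneProductRule(None)
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = GeneProductRule(association_to_tree(
                rplug.getGeneProductAssociation().getAssociation()))
        comps = {re.search(r"\[([a-zA-Z])\]$", m).group(1) for m in stoich}
        if rid == objective_id:
            kind = "biomass"
        elif len(stoich) == 1:
            kind = "exchange"
        elif len(comps) > 1:
            kind = "transport"
        else:
            kind = "metabolic"
        reactions.append(Reaction(id=rid, name=rx.getName() or rid,
                                  stoichiometry=stoich, lower_bound=lb,
                                  upper_bound=ub, gpr=gpr, kind=kind))

    genes = sorted({g for r in reactions for g in r.gpr.genes})
    compartments = {sm.getCompartment(i).getId():
                    sm.getCompartment(i).getName() or sm.getCompartment(i).getId()
                    for i in range(sm.getNumCompartments())}
    return MetabolicModel(metabolites=metabolites, reactions=reactions,
                          genes=genes, objective=objective_id,
                          compartments=compartments,
                          name=sm.getId() or Path(path).stem).validate()
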