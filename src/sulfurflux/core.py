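"""Domain types for compartmented genome-scale metabolic models.

A model is a triple of metabolites, reactions and genes together with a
declared biomass objective.  Metabolite identifiers carry a bracketed
one-letter compartment suffix (``glc[c]``, ``so4[e]``) following the common
workbook dialect for fungal genome-scale reconstructions.  The stoichiometric
matrix S (metabolites x reactions) is derived, never stored.

Flux units are mmol·gDW⁻¹·h⁻¹ throughout; the biomass reaction flux is the
specific growth rate in h⁻¹.  Exchange reactions follow the COBRA sign
convention: negative flux is uptake from the medium, positive is secretion.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "GeneProductRule",
    "ModelValidationError",
    "GPRParseError",
    "FormulaError",
    "parse_formula",
    "formula_weight",
    "parse_gpr",
    "build_stoichiometric_matrix",
    "apply_medium",
    "rich_medium",
    "minimal_medium",
    "split_compartment",
    "REACTION_KINDS",
]

REACTION_KINDS = ("metabolic", "transport", "exchange", "biomass")

#: monoisotopic-free average atomic masses (g/mol), sufficient for the
#: elements that occur in metabolic reconstructions
ATOMIC_MASS: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Cu": 63.546, "Mn": 54.938, "Cl": 35.45,
    "Se": 78.971, "Co": 58.933, "Mo": 95.95, "I": 126.904, "R": 0.0,
}

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[a-zA-Z])\]$")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class FormulaError(ValueError):
    """Raised for elemental formula strings that cannot be parsed."""


def split_compartment(met_id: str) -> Tuple[str, str]:
    """Split ``"glc[c]"`` into ``("glc", "c")``.

    Raises :class:`ModelValidationError` if the id has no bracketed
    single-letter compartment suffix.
    """
    m = _COMPARTMENT_RE.match(met_id)
    if m is None:
        raise ModelValidationError(
            f"metabolite id {met_id!r} lacks a bracketed compartment suffix"
        )
    return m.group("base"), m.group("comp")


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse a Hill-style elemental formula into an element -> count map.

    Counts may be fractional (biomass pseudo-species).  Parentheses are not
    part of the dialect.  Raises :class:`FormulaError` on anything that does
    not tokenize completely into element symbols with optional counts.
    """
    if formula is None or formula == "":
        raise FormulaError("empty formula")
    pos = 0
    counts: Dict[str, float] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at offset {pos}")
        element, num = m.group(1), m.group(2)
        if element not in ATOMIC_MASS:
            raise FormulaError(f"unknown element {element!r} in formula {formula!r}")
        n = float(num) if num else 1.0
        if n < 0:
            raise FormulaError(f"negative count in formula {formula!r}")
        counts[element] = counts.get(element, 0.0) + n
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at offset {pos}")
    return counts


def formula_weight(formula: str) -> float:
    """Molecular weight (g/mol) of an elemental formula string."""
    return sum(ATOMIC_MASS[el] * n for el, n in parse_formula(formula).items())


# ---------------------------------------------------------------------------
# Gene-product rules
# ---------------------------------------------------------------------------

class GPRParseError(ValueError):
    """Raised for malformed gene-product rule strings; carries a position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GeneProductRule:
    """Boolean AND/OR tree over gene ids governing reaction availability.

    ``expression`` is either ``None`` (no gene association: the reaction is
    always available), a gene id string (leaf), or a tuple
    ``("and"|"or", (child, child, ...))``.  AND encodes complex subunits —
    losing any gene disables the reaction; OR encodes isozymes — the reaction
    is kept active in the absence of any one of the associated genes.
    """

    expression: object = None

    @property
    def is_empty(self) -> bool:
        return self.expression is None

    @property
    def genes(self) -> frozenset:
        """All gene ids appearing as leaves."""
        out = set()

        def walk(node):
            if node is None:
                return
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        walk(self.expression)
        return frozenset(out)

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        """Is the reaction available when ``deleted`` genes are absent?

        Deleted genes evaluate False, all others True; the empty rule is
        always active.
        """
        deleted = set(deleted)

        def ev(node) -> bool:
            if isinstance(node, str):
                return node not in deleted
            op, children = node
            if op == "and":
                return all(ev(c) for c in children)
            return any(ev(c) for c in children)

        if self.expression is None:
            return True
        return ev(self.expression)

    def to_string(self) -> str:
        def render(node, parent_op=None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            inner = f" {op} ".join(render(c, op) for c in children)
            # parenthesize whenever nested under a different operator
            if parent_op is not None and parent_op != op:
                return f"({inner})"
            return inner

        if self.expression is None:
            return ""
        return render(self.expression)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _tokenize_gpr(text: str):
    tokens = []  # (kind, value, position)
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            tokens.append(("lpar", ch, i)); i += 1
        elif ch == ")":
            tokens.append(("rpar", ch, i)); i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            word = text[i:j]
            low = word.lower()
            if low in ("and", "or"):
                tokens.append((low, word, i))
            else:
                tokens.append(("gene", word, i))
            i = j
    return tokens


def parse_gpr(text: Optional[str]) -> GeneProductRule:
    """Parse a boolean gene-association string into a :class:`GeneProductRule`.

    Grammar: gene ids combined with case-insensitive ``and`` / ``or`` and
    parentheses; ``or`` binds weaker than ``and``.  Blank or ``None`` input
    yields the empty rule.  Malformed input raises :class:`GPRParseError`
    with the offending position.
    """
    if text is None or not text.strip():
        return GeneProductRule(None)
    tokens = _tokenize_gpr(text)
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else ("eof", "", len(text))

    def take():
        tok = peek()
        pos[0] += 1
        return tok

    def parse_atom():
        kind, value, at = peek()
        if kind == "gene":
            take()
            return value
        if kind == "lpar":
            take()
            node = parse_or()
            kind2, _, at2 = take()
            if kind2 != "rpar":
                raise GPRParseError("unbalanced parentheses", at2)
            return node
        raise GPRParseError(f"expected gene or '(' but found {value!r}", at)

    def parse_and():
        children = [parse_atom()]
        while peek()[0] == "and":
            take()
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return ("and", tuple(children))

    def parse_or():
        children = [parse_and()]
        while peek()[0] == "or":
            take()
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return ("or", tuple(children))

    node = parse_or()
    kind, value, at = peek()
    if kind != "eof":
        raise GPRParseError(f"unexpected trailing token {value!r}", at)
    return GeneProductRule(node)


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    """A chemical species in a specific compartment.

    ``formula`` (Hill-style) and ``charge`` may be absent; balance checks
    treat reactions with such participants as unverifiable rather than
    balanced.
    """

    id: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self):
        split_compartment(self.id)  # validates the suffix
        if self.formula is not None:
            parse_formula(self.formula)

    @property
    def compartment(self) -> str:
        return split_compartment(self.id)[1]

    @property
    def elements(self) -> Optional[Dict[str, float]]:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a gene rule.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed).  ``kind`` is one of metabolic, transport, exchange, biomass.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: GeneProductRule = field(default_factory=GeneProductRule)
    kind: str = "metabolic"
    subsystem: str = ""

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if not (self.lower_bound <= self.upper_bound):
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def compartments(self) -> frozenset:
        return frozenset(split_compartment(m)[1] for m in self.stoichiometry)

    def equation(self) -> str:
        """Human/workbook-readable equation string."""
        def side(items):
            parts = []
            for met, coef in items:
                coef = abs(coef)
                if coef == 1:
                    parts.append(met)
                else:
                    # shortest representation that round-trips the float
                    text = f"{coef:g}"
                    if float(text) != coef:
                        text = repr(coef)
                    parts.append(f"{text} {met}")
            return " + ".join(parts)

        subs = sorted((m, c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)
        arrow = "<=>" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}"


# ---------------------------------------------------------------------------
# The model container
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """A validated compartmented metabolic network with a biomass objective."""

    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    objective: Optional[str] = None
    compartments: Dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        self._met_index: Dict[str, int] = {}
        self._rxn_index: Dict[str, int] = {}
        self._reindex()

    def _reindex(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def reactions_of(self, met_id: str, kinds: Optional[Iterable[str]] = None
                     ) -> List[Reaction]:
        kinds = set(kinds) if kinds is not None else None
        return [
            r for r in self.reactions
            if met_id in r.stoichiometry and (kinds is None or r.kind in kinds)
        ]

    # -- mutation helpers (return new objects; models are cheap to copy) --
    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def add_reaction(self, reaction: Reaction):
        if reaction.id in self._rxn_index:
            raise ModelValidationError(f"duplicate reaction id {reaction.id!r}")
        self.reactions.append(reaction)
        self._rxn_index[reaction.id] = len(self.reactions) - 1

    def set_bounds(self, rxn_id: str, lower: float, upper: float):
        r = self.reaction(rxn_id)
        if lower > upper:
            raise ModelValidationError(
                f"bounds for {rxn_id!r} out of order: {lower} > {upper}"
            )
        r.lower_bound, r.upper_bound = lower, upper

    # -- validation -------------------------------------------------------
    def validate(self) -> "MetabolicModel":
        """Check all structural invariants; returns self for chaining."""
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
            _, comp = split_compartment(m.id)
            if self.compartments and comp not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {m.id!r} uses unregistered compartment {comp!r}"
                )
        seen = set()
        gene_set = set(self.genes)
        for r in self.reactions:
            if r.id in seen:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
            missing = r.gpr.genes - gene_set
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR references unknown genes {sorted(missing)}"
                )
            if r.kind == "exchange" and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {r.id!r} must touch exactly one metabolite"
                )
            if r.kind == "transport" and len(r.compartments) < 2:
                raise ModelValidationError(
                    f"transport reaction {r.id!r} must span >= 2 compartments"
                )
        if self.objective is not None:
            if self.objective not in self._rxn_index:
                raise ModelValidationError(
                    f"objective reaction {self.objective!r} not in model"
                )
            if self.reaction(self.objective).kind != "biomass":
                raise ModelValidationError(
                    f"objective reaction {self.objective!r} is not of kind 'biomass'"
                )
        return self

    # -- derived matrix ---------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        return build_stoichiometric_matrix(self)

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def summary(self) -> Dict[str, int]:
        """Headline counts in the style of a reconstruction summary table."""
        kinds = {k: 0 for k in REACTION_KINDS}
        for r in self.reactions:
            kinds[r.kind] += 1
        gene_rxn_counts: Dict[str, int] = {g: 0 for g in self.genes}
        for r in self.reactions:
            for g in r.gpr.genes:
                gene_rxn_counts[g] += 1
        mono = sum(1 for g, n in gene_rxn_counts.items() if n == 1)
        multi = sum(1 for g, n in gene_rxn_counts.items() if n > 1)
        return {
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "genes": len(self.genes),
            "metabolic_reactions": kinds["metabolic"],
            "transport_reactions": kinds["transport"],
            "exchange_reactions": kinds["exchange"],
            "biomass_reactions": kinds["biomass"],
            "compartments": len({m.compartment for m in self.metabolites}),
            "monofunctional_genes": mono,
            "multifunctional_genes": multi,
        }


def build_stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """The S matrix: entry (i, j) is the signed coefficient of metabolite i
    in reaction j; row order follows ``model.metabolites``, column order
    follows ``model.reactions``."""
    rows, cols, data = [], [], []
    for j, r in enumerate(model.reactions):
        for met_id, coef in r.stoichiometry.items():
            rows.append(model._met_index[met_id])
            cols.append(j)
            data.append(float(coef))
    return sparse.csr_matrix(
        (data, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

#: sentinel bound pair meaning "metabolite present, use the standard
#: (-1, 1) mmol·gDW⁻¹·h⁻¹ window"
PRESENT = ("present", "present")


@dataclass
class MediumSpec:
    """Exchange-reaction bound overrides defining a growth condition.

    ``entries`` maps exchange reaction ids to ``(lower, upper)`` bound pairs;
    the :data:`PRESENT` sentinel (or the string ``"present"``) stands for the
    standard (-1, 1) window used for metabolites declared present in the
    medium.  Exchanges not listed become secretion-only ``(0, default_ub)``
    when the medium is applied.
    """

    entries: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    default_ub: float = 1000.0
    name: str = ""

    def resolved_bounds(self, rxn_id: str) -> Tuple[float, float]:
        lb, ub = self.entries[rxn_id]
        if lb == "present" or ub == "present":
            return (-1.0, 1.0)
        lb, ub = float(lb), float(ub)
        if lb > ub:
            raise ModelValidationError(
                f"medium bounds for {rxn_id!r} out of order: {lb} > {ub}"
            )
        return lb, ub


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set by ``medium``.

    Listed exchanges get the medium's bounds; every unlisted exchange becomes
    secretion-only ``(0, medium.default_ub)``.  The input model is not
    mutated, and re-application of the same medium is idempotent.
    """
    exchange_ids = {r.id for r in model.exchanges}
    for key in medium.entries:
        if key not in exchange_ids:
            raise ModelValidationError(
                f"medium entry {key!r} is not an exchange reaction of the model"
            )
    out = model.copy()
    for r in out.reactions:
        if r.kind != "exchange":
            continue
        if r.id in medium.entries:
            r.lower_bound, r.upper_bound = medium.resolved_bounds(r.id)
        else:
            r.lower_bound, r.upper_bound = 0.0, medium.default_ub
    return out


def rich_medium(model: MetabolicModel, default_ub: float = 1000.0) -> MediumSpec:
    """Every exchange opened to (-default_ub, +default_ub): the in-silico
    rich-media condition used for essentiality screening."""
    return MediumSpec(
        entries={r.id: (-default_ub, default_ub) for r in model.exchanges},
        default_ub=default_ub,
        name="rich",
    )


def minimal_medium(present: Iterable[str],
                   fixed: Optional[Mapping[str, Tuple[float, float]]] = None,
                   default_ub: float = 1000.0,
                   name: str = "minimal") -> MediumSpec:
    """Minimal medium: ``present`` exchanges opened to the (-1, 1) window,
    ``fixed`` exchanges pinned to explicit bounds, everything else closed to
    uptake when applied."""
    entries: Dict[str, Tuple[float, float]] = {r: (-1.0, 1.0) for r in present}
    if fixed:
        entries.update({k: (float(a), float(b)) for k, (a, b) in fixed.items()})
    return MediumSpec(entries=entries, default_ub=default_ub, name=name)
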