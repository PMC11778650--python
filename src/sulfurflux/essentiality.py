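"""Single-gene-deletion essentiality screening and reference validation.

A gene deletion removes every reaction whose gene-product rule evaluates
inactive without that gene (isozyme-covered reactions are kept active), the
FBA problem is re-solved, and the gene is called Essential when the
knockout/wild-type growth ratio falls below a threshold.  The screen is
conventionally run in in-silico rich media: every exchange reaction opened
in both directions, mimicking knockout experiments done in broth.

Validation compares the in-silico calls with a reference call table (e.g.
experimental essentiality from a model organism) joined through an ortholog
map, yielding a confusion matrix and an accuracy over the shared genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from .core import GeneProductRule, MetabolicModel, MediumSpec, apply_medium, rich_medium
from .fba import FBAError, solve_fba

__all__ = [
    "EssentialityCall",
    "ConfusionMatrix",
    "OrthologMap",
    "evaluate_gpr",
    "knockout_reactions",
    "single_gene_deletion",
    "validate_against_reference",
]

ESSENTIAL, NON_ESSENTIAL = "E", "NE"


def evaluate_gpr(rule: GeneProductRule, deleted: Iterable[str] = ()) -> bool:
    """Availability of a reaction under a set of deleted genes.

    Deleted genes evaluate False, all others True; AND nodes are complexes
    (any missing subunit inactivates), OR nodes are isozymes (the reaction
    is kept active in the absence of any one associated gene); the empty
    rule is always active.
    """
    return rule.evaluate(deleted)


@dataclass
class EssentialityCall:
    """Outcome of one in-silico gene deletion."""

    gene: str
    wild_type_growth: float
    knockout_growth: float
    essential: bool

    @property
    def growth_ratio(self) -> float:
        if self.wild_type_growth == 0:
            return 0.0
        return self.knockout_growth / self.wild_type_growth

    @property
    def call(self) -> str:
        return ESSENTIAL if self.essential else NON_ESSENTIAL


@dataclass
class ConfusionMatrix:
    """Counts of (reference class, predicted class) pairs.

    Cells are keyed by reference first: ``ee`` is reference-Essential &
    predicted-Essential, ``en`` reference-Essential & predicted-NonEssential,
    etc.  ``n_shared`` is the number of genes compared (which may exceed the
    four-cell sum when some shared genes could not be resolved to a single
    reference class); accuracy is agreements over ``n_shared``, in percent.
    """

    ee: int = 0
    en: int = 0
    ne: int = 0
    nn: int = 0
    n_shared: int = 0
    unmatched: List[str] = field(default_factory=list)

    @property
    def agreements(self) -> int:
        return self.ee + self.nn

    @property
    def accuracy(self) -> float:
        if self.n_shared == 0:
            raise ValueError("empty comparison: no shared genes")
        return 100.0 * self.agreements / self.n_shared

    def as_dict(self) -> Dict[str, object]:
        return {
            "reference_E_predicted_E": self.ee,
            "reference_E_predicted_NE": self.en,
            "reference_NE_predicted_E": self.ne,
            "reference_NE_predicted_NE": self.nn,
            "n_shared": self.n_shared,
            "n_unmatched": len(self.unmatched),
            "accuracy_percent": self.accuracy,
        }


@dataclass
class OrthologMap:
    """Model-gene -> reference-gene pairs with BLAST-style E-values.

    Rows above ``evalue_threshold`` are dropped by :meth:`filtered`.  A model
    gene may map to several reference genes (many-to-many resolution is the
    validator's job).
    """

    rows: List[Tuple[str, str, float]]
    evalue_threshold: float = 1e-6

    def filtered(self) -> List[Tuple[str, str, float]]:
        return [r for r in self.rows if r[2] <= self.evalue_threshold]

    def mapping(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for model_gene, ref_gene, _ in self.filtered():
            out.setdefault(model_gene, []).append(ref_gene)
        return out


def knockout_reactions(model: MetabolicModel, deleted: Iterable[str]
                       ) -> List[str]:
    """Reaction ids whose GPR evaluates inactive under ``deleted`` genes."""
    deleted = set(deleted)
    return [
        r.id for r in model.reactions
        if not r.gpr.is_empty and not r.gpr.evaluate(deleted)
    ]


def single_gene_deletion(model: MetabolicModel,
                         medium: Optional[MediumSpec] = None,
                         threshold: float = 1e-3,
                         genes: Optional[Iterable[str]] = None,
                         ) -> List[EssentialityCall]:
    """Delete every gene individually and classify it by growth impact.

    ``medium`` defaults to the rich preset (all exchanges opened both ways).
    A gene is Essential when knockout/wild-type growth ratio < ``threshold``
    (numerical LP solutions return ~1e-12 noise rather than exact zeros, so
    "growth rate of zero" is implemented as a small relative threshold).

    Raises :class:`FBAError` if the wild type itself cannot grow.
    """
    medium = medium if medium is not None else rich_medium(model)
    conditioned = apply_medium(model, medium)
    wt = solve_fba(conditioned, check_orientation=False)
    if not wt.optimal or wt.objective_value is None or wt.objective_value <= 0:
        raise FBAError(
            "wild-type FBA is not optimal with positive growth; "
            f"status={wt.status}, growth={wt.objective_value}"
        )
    wt_growth = wt.objective_value

    gene_list = list(genes) if genes is not None else list(conditioned.genes)
    calls: List[EssentialityCall] = []
    for gene in gene_list:
        disabled = knockout_reactions(conditioned, {gene})
        if not disabled:
            calls.append(EssentialityCall(gene, wt_growth, wt_growth, False))
            continue
        override = {rid: (0.0, 0.0) for rid in disabled}
        ko = _solve_with_overrides(conditioned, override)
        growth = ko if ko is not None else 0.0
        growth = max(growth, 0.0)
        calls.append(EssentialityCall(
            gene, wt_growth, growth, growth / wt_growth < threshold
        ))
    return calls


def _solve_with_overrides(model: MetabolicModel,
                          override: Mapping[str, Tuple[float, float]]
                          ) -> Optional[float]:
    from .fba import _solve_raw  # shared LP path, bounds overridden in place

    res, _ = _solve_raw(model, model.objective, "max",
                        bounds_override=dict(override))
    if res.status == 0:
        return -res.fun
    if res.status in (2, 3):
        return None
    raise FBAError(f"LP solver failure during knockout scan: {res.message}")


def validate_against_reference(calls: Iterable[EssentialityCall],
                               ortholog_map: OrthologMap,
                               reference: Mapping[str, str],
                               ) -> ConfusionMatrix:
    """Confusion matrix of in-silico calls against a reference call table.

    Model genes are joined to the reference through the E-value-filtered
    ortholog map.  A model gene with several reference orthologs takes the
    reference class Essential if ANY ortholog is essential (conservative
    many-to-many resolution).  Shared genes whose orthologs all lack a
    reference class are counted in ``n_shared`` but reported as unmatched.
    """
    call_by_gene = {c.gene: c.call for c in calls}
    mapping = ortholog_map.mapping()
    shared = [g for g in call_by_gene if g in mapping]
    if not shared:
        raise ValueError("no overlap between in-silico calls and ortholog map")

    cm = ConfusionMatrix()
    for gene in shared:
        ref_classes = {reference[r] for r in mapping[gene] if r in reference}
        cm.n_shared += 1
        if not ref_classes:
            cm.unmatched.append(gene)
            continue
        ref = ESSENTIAL if ESSENTIAL in ref_classes else NON_ESSENTIAL
        pred = call_by_gene[gene]
        if ref == ESSENTIAL:
            if pred == ESSENTIAL:
                cm.ee += 1
            else:
                cm.en += 1
        else:
            if pred == ESSENTIAL:
                cm.ne += 1
            else:
                cm.nn += 1
    return cm
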