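"""End-to-end orchestration: model -> QC -> scenarios -> essentiality -> report.

:func:`run_pipeline` chains the package's stages over a model that is either
generated synthetically or parsed from a workbook, writing per-stage TSV/JSON
outputs plus a single markdown report whose every number traces to a stage
output file.  A serialized copy of the configuration is written into the
output directory for provenance, and outputs are deterministic for a given
configuration (seed included).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .core import MetabolicModel
from .qc import balance_model, connectivity_profile, find_dead_ends
from .scenarios import (
    carbon_source_scan,
    dbt_titration,
    pap_bypass_scenario,
    sulfur_shadow_costs,
)
from .essentiality import single_gene_deletion, validate_against_reference
from .synth import (
    CARBON_SOURCES,
    ReferenceConfig,
    ToyModelConfig,
    build_desulfurization_toy,
    generate_reference,
)
from .io import parse_model_workbook, write_model_workbook

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Pipeline configuration.

    ``model_workbook`` (path) takes precedence over the synthetic config.
    The scenario list selects which analyses run; ``seed`` feeds both the
    synthetic model and the reference generator.
    """

    model_workbook: Optional[str] = None
    seed: int = 42
    scenarios: Tuple[str, ...] = (
        "summary", "qc", "carbon_scan", "dbt_titration", "sulfur_costs",
        "pap_bypass", "essentiality",
    )
    total_carbon: float = 6.0
    dbt_levels: Tuple[float, ...] = (0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 1.0)
    reference_agreement: float = 0.781
    essentiality_threshold: float = 1e-3
    output_dir: str = "sulfurflux_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "scenarios" in data:
            data["scenarios"] = tuple(data["scenarios"])
        if "dbt_levels" in data:
            data["dbt_levels"] = tuple(float(x) for x in data["dbt_levels"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["scenarios"] = list(self.scenarios)
        data["dbt_levels"] = list(self.dbt_levels)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _write_tsv(path: Path, header: Sequence[str],
               rows: Sequence[Sequence[object]]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(
            f"{v:.10g}" if isinstance(v, float) else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Run all configured stages; returns {artifact name: path}.

    Raises :class:`PipelineError` naming the failing stage; outputs of
    completed stages are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    config.to_yaml(out / "run_config.yaml")
    artifacts["config"] = out / "run_config.yaml"
    report: List[str] = ["# sulfurflux pipeline report", ""]

    def stage(name: str):
        def wrap(fn):
            if name not in config.scenarios:
                return
            logger.info("pipeline stage: %s", name)
            try:
                fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # -- model ------------------------------------------------------------
    synthetic = config.model_workbook is None
    try:
        if synthetic:
            model = build_desulfurization_toy(ToyModelConfig(seed=config.seed))
            write_model_workbook(model, out / "model.xlsx")
            artifacts["model"] = out / "model.xlsx"
        else:
            model, issues = parse_model_workbook(config.model_workbook)
            if len(issues):
                _write_tsv(out / "parse_issues.tsv",
                           ["sheet", "row", "message"], issues.issues)
                artifacts["parse_issues"] = out / "parse_issues.tsv"
    except Exception as exc:
        raise PipelineError(f"stage 'model' failed: {exc}") from exc
    origin = "synthetic model" if synthetic else f"workbook {config.model_workbook}"
    report += [f"Model source: **{origin}** "
               f"(results below describe this model, not any organism's "
               f"published reconstruction unless the workbook is one)", ""]

    @stage("summary")
    def _summary():
        summary = model.summary()
        _write_tsv(out / "model_summary.tsv", ["feature", "value"],
                   sorted(summary.items()))
        artifacts["model_summary"] = out / "model_summary.tsv"
        report.append("## Model summary (model_summary.tsv)")
        for k, v in sorted(summary.items()):
            report.append(f"- {k}: {v}")
        report.append("")

    @stage("qc")
    def _qc():
        reports = balance_model(model)
        rows = [(r.reaction_id, r.verdict,
                 ";".join(f"{e}:{d:g}" for e, d in sorted(r.element_delta.items())),
                 "" if r.charge_delta is None else f"{r.charge_delta:g}",
                 r.reason) for r in reports]
        _write_tsv(out / "qc_balance.tsv",
                   ["reaction", "verdict", "element_delta", "charge_delta",
                    "reason"], rows)
        artifacts["qc_balance"] = out / "qc_balance.tsv"
        prof = connectivity_profile(model)
        _write_tsv(out / "qc_connectivity.tsv", ["degree", "metabolites"],
                   sorted(prof.degree_counts.items()))
        artifacts["qc_connectivity"] = out / "qc_connectivity.tsv"
        dead = find_dead_ends(model)
        (out / "qc_dead_ends.tsv").write_text(
            "metabolite\n" + "".join(f"{m}\n" for m in dead))
        artifacts["qc_dead_ends"] = out / "qc_dead_ends.tsv"
        n_bal = sum(1 for r in reports if r.verdict == "balanced")
        report.extend([
            "## QC (qc_balance.tsv, qc_connectivity.tsv, qc_dead_ends.tsv)",
            f"- balanced reactions: {n_bal}/{len(reports)} "
            f"(exchange/biomass exempt)",
            f"- imbalanced: {sum(1 for r in reports if r.verdict == 'imbalanced')}, "
            f"unverifiable: {sum(1 for r in reports if r.verdict == 'unverifiable')}",
            f"- degree-2 metabolites: {prof.count(2)}, degree-3: {prof.count(3)}, "
            f">3: {prof.more_than_cutoff}",
            f"- dead ends: {len(dead)}", "",
        ])

    @stage("carbon_scan")
    def _carbon():
        sources = [(ex, k) for ex, k in CARBON_SOURCES.items()
                   if model.has_reaction(ex)]
        results = carbon_source_scan(model, sources,
                                     total_carbon=config.total_carbon)
        _write_tsv(out / "carbon_scan.tsv",
                   ["carbon_source", "status", "growth_per_h", "uptake_bound"],
                   [(r.label, r.status, r.growth,
                     -config.total_carbon / dict(sources)[r.label])
                    for r in results])
        artifacts["carbon_scan"] = out / "carbon_scan.tsv"
        report.append("## Carbon-source scan (carbon_scan.tsv)")
        for r in results:
            report.append(f"- {r.label}: growth {r.growth:.6g} /h")
        report.append("")

    @stage("dbt_titration")
    def _titration():
        results = dbt_titration(model, config.dbt_levels)
        _write_tsv(out / "dbt_titration.tsv",
                   ["dbt_uptake_bound", "status", "growth_per_h",
                    "hbp_secretion", "dbt_uptake"],
                   [(lvl, r.status, r.growth,
                     r.tracked_fluxes.get("EX_hbp", 0.0),
                     r.tracked_fluxes.get("EX_dbt", 0.0))
                    for lvl, r in zip(config.dbt_levels, results)])
        artifacts["dbt_titration"] = out / "dbt_titration.tsv"
        report.extend([
            "## DBT titration (dbt_titration.tsv)",
            f"- levels: {list(config.dbt_levels)}",
            f"- max 2-HBP secretion: "
            f"{max(r.tracked_fluxes.get('EX_hbp', 0.0) for r in results):.6g}",
            ""])

    @stage("sulfur_costs")
    def _sulfur():
        conditioned = model.copy()
        for ex in ("EX_so4", "EX_h2s"):
            if conditioned.has_reaction(ex):
                conditioned.set_bounds(
                    ex, 0.0, conditioned.reaction(ex).upper_bound)
        if conditioned.has_reaction("EX_dbt"):
            conditioned.set_bounds("EX_dbt", -10.0, 0.0)
        table, skipped = sulfur_shadow_costs(conditioned)
        _write_tsv(out / "sulfur_shadow_costs.tsv",
                   ["metabolite", "name", "sulfur_atoms", "shadow_price",
                    "price_per_sulfur"],
                   [(row["metabolite"], row["name"], row["sulfur_atoms"],
                     row["shadow_price"], row["price_per_sulfur"])
                    for row in table])
        artifacts["sulfur_costs"] = out / "sulfur_shadow_costs.tsv"
        report.append("## Sulfur shadow costs, DBT sole S source "
                      "(sulfur_shadow_costs.tsv)")
        for row in table[:5]:
            report.append(f"- {row['metabolite']} ({row['name']}): "
                          f"{row['shadow_price']:.6g}")
        if skipped:
            report.append(f"- skipped (no formula): {len(skipped)}")
        report.append("")

    @stage("pap_bypass")
    def _pap():
        needed = ("SULY", "APSK", "EX_pap")
        if not all(model.has_reaction(r) for r in needed):
            report.extend(["## PAP bypass", "- skipped: model lacks named "
                           "sulfate-activation reactions or PAP exchange", ""])
            return
        results = pap_bypass_scenario(model, ["SULY"], ["APSK"])
        _write_tsv(out / "pap_bypass.tsv",
                   ["scenario", "status", "growth_per_h", "dszb_flux"],
                   [(k, v.status, v.growth, v.tracked_fluxes.get("DSZB", 0.0))
                    for k, v in results.items()])
        artifacts["pap_bypass"] = out / "pap_bypass.tsv"
        report.append("## PAP-bypass strain design (pap_bypass.tsv)")
        for k, v in results.items():
            report.append(f"- {k}: growth {v.growth:.6g} /h")
        report.append("")

    @stage("essentiality")
    def _ess():
        calls = single_gene_deletion(
            model, threshold=config.essentiality_threshold)
        _write_tsv(out / "essentiality_calls.tsv",
                   ["gene", "wild_type_growth", "knockout_growth",
                    "growth_ratio", "class"],
                   [(c.gene, c.wild_type_growth, c.knockout_growth,
                     c.growth_ratio, c.call) for c in calls])
        artifacts["essentiality_calls"] = out / "essentiality_calls.tsv"
        omap, reference, planted = generate_reference(
            model,
            ReferenceConfig(agreement=config.reference_agreement,
                            seed=config.seed),
            calls=calls)
        cm = validate_against_reference(calls, omap, reference)
        (out / "essentiality_confusion.json").write_text(
            json.dumps({"observed": cm.as_dict(),
                        "planted": planted.as_dict()}, indent=2) + "\n")
        artifacts["essentiality_confusion"] = out / "essentiality_confusion.json"
        n_e = sum(1 for c in calls if c.essential)
        report.extend([
            "## Gene essentiality (essentiality_calls.tsv, "
            "essentiality_confusion.json)",
            f"- genes scanned: {len(calls)}, essential: {n_e}",
            f"- accuracy vs synthetic reference "
            f"(planted agreement {config.reference_agreement:.3f}): "
            f"{cm.accuracy:.1f}%", "",
        ])

    (out / "report.md").write_text("\n".join(report) + "\n")
    artifacts["report"] = out / "report.md"
    return artifacts
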