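"""End-to-end curation pipeline: stats -> gapfind -> gapfill -> FBA/FVA ->
pathway coverage -> LC-MS annotation -> cytotoxicity, from a single config.

Stages run in a fixed order; optional stages whose inputs are not configured
are marked ``skipped`` rather than aborting, so one config drives both a
network-only curation run and a full multi-omic contextualization.  The
report embeds the config and seed, making a run self-describing, and two
runs on identical inputs produce semantically identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .curation import (
    AliasTable,
    PathwaySpec,
    coverage_check,
    integrate_candidates,
    load_candidates,
    rename_candidates,
)
from .cytotox import load_plate, summarize_plate
from .fba import BiomassSpec, ScenarioConfig, attach_biomass, fba_optimize
from .gaps import active_blocked_fractions, classify_gaps
from .metabolomics import (
    annotate,
    class_summary,
    load_feature_table,
    load_library,
    relative_area,
)
from .network import load_network, topology_metrics

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    network: str
    candidates: str | None = None
    aliases: str | None = None
    biomass: str | None = None
    scenario: str | None = None
    pathways: str | None = None
    features: str | None = None
    library: str | None = None
    plate: str | None = None
    out_dir: str = "gemcurate_run"
    lp_tol: float = 1e-9
    ppm_tol: float = 10.0
    max_iter: int = 20
    viability_convention: str = "ratio"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        cfg = cls(**payload)
        if cfg.lp_tol <= 0 or cfg.ppm_tol <= 0:
            raise ValueError("tolerances must be positive")
        return cfg

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _load_biomass(path: str | Path) -> BiomassSpec:
    """biomass.tsv: metabolite_id <tab> coefficient."""
    components: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("metabolite_id"):
            continue
        met, _, coef = line.partition("\t")
        components[met.strip()] = float(coef)
    return BiomassSpec(components=components)


def _load_scenario(path: str | Path) -> ScenarioConfig:
    payload = json.loads(Path(path).read_text())
    return ScenarioConfig(
        name=payload["name"],
        bound_overrides={
            rid: (lo, hi) for rid, (lo, hi) in payload["overrides"].items()
        },
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the workflow and return (and write) the consolidated report."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": __version__,
    }

    net = load_network(cfg.network, dialect="tabular")
    logger.info(
        "stats: %d metabolites, %d reactions",
        len(net.metabolites),
        len(net.reactions),
    )
    topo = topology_metrics(net)
    report["topology"] = json.loads(topo.to_json())

    gaps_before = classify_gaps(net, cfg.lp_tol)
    logger.info("gapfind: %d production gaps", len(gaps_before.all_gaps))
    report["gaps_before"] = json.loads(gaps_before.to_json())

    if cfg.candidates:
        cands = load_candidates(cfg.candidates)
        if cfg.aliases:
            aliases = AliasTable.from_tsv(cfg.aliases)
            cands, unmapped = rename_candidates(cands, aliases, policy="skip")
        else:
            unmapped = []
        net, curation = integrate_candidates(
            net, cands, tol=cfg.lp_tol, max_iter=cfg.max_iter
        )
        curation.unmapped_candidates = [c.external_id for c in unmapped]
        logger.info(
            "gapfill: %d iterations, delta_active=%d",
            len(curation.iterations),
            curation.delta_active_reactions,
        )
        report["curation"] = json.loads(curation.to_json())
        gaps_after = classify_gaps(net, cfg.lp_tol)
        report["gaps_after"] = json.loads(gaps_after.to_json())
    else:
        report["curation"] = "skipped"
        report["gaps_after"] = "skipped"

    if cfg.biomass:
        spec = _load_biomass(cfg.biomass)
        scenario = _load_scenario(cfg.scenario) if cfg.scenario else None
        net_obj = attach_biomass(net, spec)
        result = fba_optimize(
            net_obj, spec.objective_id, scenario=scenario, tol=cfg.lp_tol
        )
        logger.info("fba: status=%s optimum=%s", result.status, result.objective_value)
        report["fba"] = result.to_dict()
    else:
        report["fba"] = "skipped"

    active, blocked = active_blocked_fractions(net, cfg.lp_tol)
    logger.info("fva: %.2f%% active, %.2f%% blocked", active, blocked)
    report["flux_fractions"] = {
        "active_percent": active,
        "blocked_percent": blocked,
    }

    if cfg.pathways:
        specs = PathwaySpec.from_tsv(cfg.pathways)
        coverage = {s.name: coverage_check(net, s) for s in specs}
        logger.info("coverage: %d pathways checked", len(coverage))
        report["coverage"] = coverage
    else:
        report["coverage"] = "skipped"

    if cfg.features and cfg.library:
        features = load_feature_table(cfg.features)
        library = load_library(cfg.library)
        per_feature = annotate(features, library, tol_ppm=cfg.ppm_tol)
        top_hits = [hits[0] for hits in per_feature if hits]
        areas = relative_area(features)
        summary = class_summary(top_hits)
        logger.info(
            "annotate-ms: %d/%d features annotated",
            len(top_hits),
            len(features),
        )
        report["annotation"] = {
            "n_features": len(features),
            "n_annotated": len(top_hits),
            "class_summary": {
                f"{cls}|{mode}": n for (cls, mode), n in summary.items()
            },
            "max_relative_area_percent": max(areas) if areas else 0.0,
        }
    else:
        report["annotation"] = "skipped"

    if cfg.plate:
        plate = load_plate(cfg.plate)
        viability = summarize_plate(plate, convention=cfg.viability_convention)
        logger.info("cytotox: %d strata", len(viability))
        report["viability"] = viability.to_dict(orient="records")
    else:
        report["viability"] = "skipped"

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "report.txt").write_text(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable one-section-per-stage rendering of a run report."""
    lines = [f"gemcurate run report (version {report['version']})", ""]
    topo = report["topology"]
    lines.append(
        f"network: {topo['n_metabolites']} metabolites x "
        f"{topo['n_reactions']} reactions, {topo['nnz']} non-zero entries "
        f"({topo['sparsity_percent']}% of {topo['total_entries']}), "
        f"{topo['n_transport']} transport reactions"
    )
    gb = report["gaps_before"]["counts"]
    lines.append(
        f"gaps before curation: allGaps={gb['allGaps']} "
        f"(root={gb['rootGaps']}, downstream={gb['downstreamGaps']})"
    )
    if report["gaps_after"] != "skipped":
        ga = report["gaps_after"]["counts"]
        cur = report["curation"]
        lines.append(
            f"gaps after curation: allGaps={ga['allGaps']}; "
            f"delta_active_reactions={cur['delta_active_reactions']}, "
            f"delta_metabolites={cur['delta_metabolites']}"
        )
    if report["fba"] != "skipped":
        lines.append(
            f"fba: status={report['fba']['status']}, "
            f"optimum={report['fba']['objective_value']}"
        )
    ff = report["flux_fractions"]
    lines.append(
        f"flux variability: {ff['active_percent']}% active, "
        f"{ff['blocked_percent']}% blocked"
    )
    for section in ("coverage", "annotation", "viability"):
        if report[section] == "skipped":
            lines.append(f"{section}: skipped")
    if report["annotation"] != "skipped":
        ann = report["annotation"]
        lines.append(
            f"annotation: {ann['n_annotated']}/{ann['n_features']} features "
            f"annotated within tolerance"
        )
    if report["viability"] != "skipped":
        lines.append(f"viability: {len(report['viability'])} strata summarized")
    return "\n".join(lines) + "\n"
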