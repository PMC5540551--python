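"""Pipeline orchestration: reconstruct -> compartmentalize -> curate ->
flux analysis -> topology, with a single validated configuration object.

Each stage writes its outputs before the next begins; summary tables are
written deterministically (two runs with identical config and inputs are
byte-identical), while wall-clock timings go to the log file only.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import (
    compartmentalization as cz,
    curation as cu,
    flux_analysis as fa,
    model_core as mc,
    network_topology as nt,
    reconstruction as rc,
)

log = logging.getLogger("metagem")

__all__ = ["PipelineConfig", "run_pipeline"]


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reconstruct: bool = True
    compartmentalize: bool = True
    curate: bool = True
    fba: bool = True
    topology: bool = True


class PipelineInputs(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reactions: str
    metabolites: str
    localization: str | None = None
    references: str | None = None
    transport_db: str | None = None
    candidate_db: str | None = None


class PipelineConfig(BaseModel):
    """All tunables of the five stages; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    inputs: PipelineInputs
    output_dir: str
    stages: StageToggles = Field(default_factory=StageToggles)
    seed: int = 0
    directionality_threshold: float = 30.0
    min_score: float = cz.DEFAULT_MIN_SCORE
    min_reactions: int = cz.DEFAULT_MIN_REACTIONS
    eps: float = 1e-3
    big_m: float = 1000.0
    active_flux_tolerance: float = fa.ACTIVE_FLUX_TOLERANCE
    upper_bound: float = mc.DEFAULT_UPPER_BOUND
    reversible_lower_bound: float = mc.REVERSIBLE_LOWER_BOUND
    objective: str = "boundary_secretion"
    exclude: list[str] = Field(default_factory=list)
    stabilize_fluxes: bool = True
    fit_k_min: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def _write_kv(path: Path, rows: list[tuple[str, Any]]) -> None:
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, sep="\t", index=False)


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages in order; returns in-memory results.

    With compartmentalization disabled, every metabolic reaction is kept in
    the cytoplasm and only extracellular exchange survives — the
    two-compartment (non-compartmentalized) variant of the same code path.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict[str, Any] = {}
    try:
        network = mc.read_network(config.inputs.reactions, config.inputs.metabolites)
        summary_rows: list[tuple[str, Any]] = [
            ("initial_reactions", len(network.reactions)),
            ("initial_metabolites", len(network.metabolite_ids())),
        ]

        if config.stages.reconstruct:
            with _stage("reconstruct"):
                network, removed = rc.remove_generic_reactions(network)
                summary_rows.append(("generic_reactions_removed", len(removed)))
                network, reports = rc.balance_network(network)
                rc.write_balance_reports(reports, out / "balance_report.tsv")
                summary_rows.append(
                    ("unbalanced_reactions", sum(r.status == "unbalanced" for r in reports))
                )
                policy = rc.DirectionalityPolicy(
                    threshold=config.directionality_threshold,
                    upper_bound=config.upper_bound,
                    reversible_lower_bound=config.reversible_lower_bound,
                )
                network = rc.assign_network_directionality(network, policy)
                mc.write_network(
                    network,
                    out / "reconstructed.reactions.tsv",
                    out / "reconstructed.metabolites.tsv",
                )
        results["reconstructed"] = network

        transport_templates: list[mc.Reaction] = []
        if config.inputs.transport_db:
            transport_templates = mc.read_reaction_table(config.inputs.transport_db)

        with _stage("compartmentalize"):
            metabolic = sorted(
                r for r, rx in network.reactions.items() if rx.rtype == "metabolic"
            )
            if config.stages.compartmentalize and config.inputs.localization:
                loc = cz.read_localization_table(config.inputs.localization)
                refs = (
                    cz.read_reference_table(config.inputs.references)
                    if config.inputs.references
                    else {}
                )
                assignments = cz.consensus_localization(
                    loc, refs, reaction_ids=metabolic, min_score=config.min_score
                )
                assignments, prune_report = cz.prune_compartments(
                    assignments, min_reactions=config.min_reactions, scores=loc
                )
                summary_rows.append(
                    ("pruned_compartments", ";".join(sorted(prune_report.discarded)))
                )
            else:
                assignments = {rid: {"c"} for rid in metabolic}
            network = cz.compartmentalize_network(network, assignments)
            network, added_t, t_counts = cz.inject_transport(
                network, cz.TransportDB(transport_templates)
            )
            summary_rows.extend(
                [
                    ("compartmentalized_reactions", len(network.reactions)),
                    ("compartmentalized_species", len(network.species)),
                    ("transport_added_c_e", t_counts["cytoplasm_extracellular"]),
                    ("transport_added_c_inner", t_counts["cytoplasm_inner"]),
                ]
            )
            by_comp = network.species_by_compartment()
            pd.DataFrame(
                [
                    {"compartment": mc.COMPARTMENT_NAMES[c], "metabolites": len(v)}
                    for c, v in sorted(by_comp.items())
                ]
            ).to_csv(out / "table_compartments.tsv", sep="\t", index=False)
            mc.write_network(
                network,
                out / "compartmentalized.reactions.tsv",
                out / "compartmentalized.metabolites.tsv",
            )
        results["compartmentalized"] = network

        if config.stages.curate:
            with _stage("curate"):
                candidate_db = (
                    mc.read_reaction_table(config.inputs.candidate_db)
                    if config.inputs.candidate_db
                    else []
                )
                gcfg = cu.GapConfig(eps=config.eps, M=config.big_m)
                gap_report = cu.gapfind(network, gcfg)
                _write_gap_report(out / "gap_report.tsv", gap_report)
                network, stats = cu.curate_compartmentalized(
                    network, candidate_db, transport_templates, gcfg
                )
                _write_curation_tables(out, stats)
                summary_rows.append(("curation_added_reactions", stats.total_added))
                mc.write_network(
                    network,
                    out / "curated.reactions.tsv",
                    out / "curated.metabolites.tsv",
                )
                mc.export_sbml(network, out / "curated.sbml")
                results["curation_stats"] = stats
        results["curated"] = network

        if config.stages.fba:
            with _stage("fba"):
                objective, unresolved = _resolve_objective(network, config.objective)
                if unresolved:
                    (out / "unresolved_templates.tsv").write_text(
                        "template_id\n" + "".join(f"{t}\n" for t in unresolved)
                    )
                problem = fa.build_problem(network, objective)
                if config.exclude:
                    problem = fa.exclude_reactions(problem, config.exclude)
                result = fa.solve(problem, stabilize=config.stabilize_fluxes)
                results["flux_result"] = result
                if result.status == "optimal":
                    scopes = _default_scopes(network)
                    fractions = fa.active_flux_fraction(
                        result, scopes, config.active_flux_tolerance
                    )
                    pd.DataFrame(
                        [
                            {"scope": k, "active_percent": "" if v is None else f"{v:.2f}"}
                            for k, v in sorted(fractions.items())
                        ]
                    ).to_csv(out / "active_fractions.tsv", sep="\t", index=False)
                    pd.DataFrame(
                        [
                            {
                                "reaction_id": r,
                                "flux": f"{v:.6f}",
                                "active": int(abs(v) > config.active_flux_tolerance),
                            }
                            for r, v in sorted(result.fluxes.items())
                        ]
                    ).to_csv(out / "fluxes.tsv", sep="\t", index=False)
                    summary_rows.append(("fba_objective", objective.name))
                    summary_rows.append(("fba_optimum", f"{result.Z:.6f}"))
                else:
                    summary_rows.append(("fba_status", result.status))

        if config.stages.topology:
            with _stage("topology"):
                graph = nt.build_metabolite_graph(network)
                nt.write_edge_list(graph, out / "metabolite_graph.tsv")
                nt.write_graphml(graph, out / "metabolite_graph.graphml")
                summary = nt.topology_summary(graph, fit_k_min=config.fit_k_min)
                matrix = mc.build_stoichiometric_matrix(network)
                ranking = nt.rank_central_metabolites(graph, matrix)
                ranking.to_csv(
                    out / "ranking.tsv", sep="\t", index=False, float_format="%.6g"
                )
                _write_kv(
                    out / "topology_summary.tsv",
                    [
                        ("clustering_coefficient", f"{summary.clustering_coefficient:.4f}"),
                        ("network_diameter", summary.network_diameter),
                        ("network_radius", summary.network_radius),
                        (
                            "characteristic_path_length",
                            f"{summary.characteristic_path_length:.4f}",
                        ),
                        ("avg_neighbors", f"{summary.avg_neighbors:.4f}"),
                        ("node_count", summary.node_count),
                        ("gamma_in", _fmt_opt(summary.gamma_in)),
                        ("gamma_out", _fmt_opt(summary.gamma_out)),
                    ],
                )
                results["topology_summary"] = summary
                results["ranking"] = ranking

        _write_kv(out / "summary.tsv", summary_rows)
        results["summary"] = summary_rows
        return results
    finally:
        log.removeHandler(handler)
        handler.close()


def _fmt_opt(v) -> str:
    return "" if v is None else f"{v:.4f}"


def _resolve_objective(network, name: str):
    library = fa.objective_library()
    if name in library:
        objective, unresolved = fa.instantiate_objective(network, library[name])
        if objective is not None:
            return objective, unresolved
        log.warning("objective %s fully unresolved; falling back", name)
    if name != "boundary_secretion" and name not in library:
        ids = [r for r in name.split(",") if r in network.reactions]
        if ids:
            return fa.ObjectiveFunction.for_reactions(name, ids), []
        raise mc.NetworkError(f"objective {name!r} matches no library block or reaction id")
    exchanges = sorted(
        r for r, rx in network.reactions.items() if rx.rtype == "exchange"
    )
    if not exchanges:
        raise mc.NetworkError("no exchange reactions available for the default objective")
    return fa.ObjectiveFunction.for_reactions("boundary_secretion", exchanges), []


def _default_scopes(network) -> dict[str, list[str]]:
    scopes: dict[str, list[str]] = {"network": sorted(network.reactions)}
    for comp in sorted(network.compartments()):
        scopes[f"compartment_{comp}"] = sorted(
            rid
            for rid, r in network.reactions.items()
            if r.compartments() == {comp}
        )
    scopes["transport"] = sorted(
        rid for rid, r in network.reactions.items() if r.rtype == "transport"
    )
    return scopes


def _write_gap_report(path: Path, report: cu.GapReport) -> None:
    rows = [
        {"species": s, "status": status}
        for status, group in (
            ("non_produced", report.non_produced),
            ("non_consumed", report.non_consumed),
        )
        for s in sorted(group)
    ]
    pd.DataFrame(rows, columns=["species", "status"]).to_csv(
        path, sep="\t", index=False
    )


def _write_curation_tables(out: Path, stats: cu.CurationStats) -> None:
    rows = []
    for comp in sorted(stats.per_compartment_before):
        b = stats.per_compartment_before[comp]
        a = stats.per_compartment_after[comp]
        rows.append(
            {
                "compartment": mc.COMPARTMENT_NAMES.get(comp, comp),
                "connected_before_percent": "NA" if b is None else f"{b:.2f}",
                "connected_after_percent": "NA" if a is None else f"{a:.2f}",
            }
        )
    pd.DataFrame(rows).to_csv(out / "curation_stats.tsv", sep="\t", index=False)
    gap_rows = [
        {"compartment_pair": f"{a}|{b}", "common_problem_metabolites": n}
        for (a, b), n in sorted(stats.common_gaps.items())
    ]
    pd.DataFrame(
        gap_rows, columns=["compartment_pair", "common_problem_metabolites"]
    ).to_csv(out / "common_gaps.tsv", sep="\t", index=False)
    add_rows = [
        {"step": step, "added": len(ids), "reaction_ids": ";".join(ids)}
        for step, ids in stats.added_by_step.items()
    ]
    pd.DataFrame(add_rows, columns=["step", "added", "reaction_ids"]).to_csv(
        out / "curation_additions.tsv", sep="\t", index=False
    )
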