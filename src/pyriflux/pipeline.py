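"""Config-driven orchestration of the flux and kinetics analyses.

The differential-flux run follows the modeling pipeline order: curate the
network (prune dead ends, insert sinks), rescale bounds per sample from
expression (gamma * GPR-mapped expression), run FVA at biomass fraction
alpha for each sample, average the per-reaction flux ranges within each
condition, and fold-change treated over control.  The knockout screen builds
condition-representative models (per-condition mean bounds), computes source
(treated) and target (control) FVA states and ranks gene knockouts by the
robust transformation score.  The kinetics run fits dose-response curves per
substrate level, calls the inhibition mode and extracts Tm/dTm from melt
curves.

Every run writes its artifacts plus a metadata JSON carrying the config
hash, seed and package version, so identical configs are verifiable and
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    ExpressionProfile,
    IntegrationConfig,
    apply_expression_bounds,
    map_expression_to_reactions,
    read_expression_tsv,
)
from .flux import (
    FVAResult,
    default_eps,
    flux_fold_change,
    flux_variability,
    optimize_biomass,
)
from .kinetics import (
    classify_inhibition_mode,
    delta_tm,
    fit_dose_response,
    fit_melting_temperature,
    read_assay_csv,
    read_melt_csv,
)
from .knockout import rank_gene_knockouts, scores_to_frame
from .network import MetabolicModel, add_sink_reaction, load_model, prune_dead_ends

__all__ = [
    "RunConfig",
    "RunReport",
    "curate_model",
    "condition_models",
    "aggregate_fva",
    "run_differential_flux",
    "run_knockout_screen",
    "run_kinetics_report",
]


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters of one pipeline run."""

    model_path: str = ""
    model_dialect: str = "cobra-json"
    expression_path: str = ""
    samples_path: str = ""
    out_dir: str = "out"
    raw_counts: bool = False
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    alpha: float = 1.0
    biomass_relaxed: bool = False
    prune: bool = False
    sink_metabolites: tuple[str, ...] = ()
    curation_order: str = "prune-then-sink"  # or "sink-then-prune"
    candidate_genes: tuple[str, ...] | None = None
    tau: float | None = None
    assay_paths: tuple[str, ...] = ()
    Km: float | None = None
    melt_apo_path: str = ""
    melt_holo_path: str = ""
    tm_method: str = "derivative"
    seed: int = 20250233

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.curation_order not in ("prune-then-sink", "sink-then-prune"):
            raise ValueError("curation_order must be prune-then-sink or sink-then-prune")

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        integ = IntegrationConfig(**raw.pop("integration", {}))
        for key in ("sink_metabolites", "assay_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("candidate_genes") is not None:
            raw["candidate_genes"] = tuple(raw["candidate_genes"])
        return cls(integration=integ, **raw)


@dataclass(frozen=True)
class RunReport:
    artifacts: Mapping[str, str]
    metadata_path: str

    def __post_init__(self):
        for name, p in self.artifacts.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"report artifact {name!r} missing: {p}")


def _write_metadata(config: RunConfig, out_dir: Path, stage: str,
                    extra: Mapping | None = None) -> str:
    meta = {
        "stage": stage,
        "config_hash": config.digest(),
        "seed": config.seed,
        "alpha": config.alpha,
        "gamma": config.integration.gamma,
        "pyriflux_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "scoring": "simplified-rMTA (robust score = min over MOMA and FBA engines)",
    }
    if extra:
        meta.update(extra)
    path = out_dir / f"{stage}_metadata.json"
    path.write_text(json.dumps(meta, indent=1, default=str) + "\n")
    return str(path)


def curate_model(model: MetabolicModel, config: RunConfig
                 ) -> tuple[MetabolicModel, list[str]]:
    """Apply the curation steps in the configured order."""
    log: list[str] = []

    def _prune(m):
        m2, removed = prune_dead_ends(m)
        log.extend(f"removed:{x}" for x in removed)
        return m2

    def _sink(m):
        for met in config.sink_metabolites:
            m = add_sink_reaction(m, met)
            log.append(f"sink:{met}")
        return m

    steps = (_prune, _sink) if config.curation_order == "prune-then-sink" else (_sink, _prune)
    if not config.prune:
        steps = tuple(s for s in steps if s is not _prune)
    for step in steps:
        model = step(model)
    return model, log


def _sample_model(model: MetabolicModel, profile: ExpressionProfile,
                  integration: IntegrationConfig) -> MetabolicModel:
    rmap = map_expression_to_reactions(model, profile, integration)
    return apply_expression_bounds(model, rmap, integration)


def condition_models(
    model: MetabolicModel,
    profiles: Sequence[ExpressionProfile],
    integration: IntegrationConfig,
) -> dict[str, MetabolicModel]:
    """One representative model per condition: mean of per-sample bounds."""
    out: dict[str, MetabolicModel] = {}
    for condition in ("control", "treated"):
        members = [p for p in profiles if p.condition == condition]
        if not members:
            continue
        sample_models = [_sample_model(model, p, integration) for p in members]
        bounds = {}
        for rid in model.reaction_ids:
            lbs = [m.reaction(rid).lb for m in sample_models]
            ubs = [m.reaction(rid).ub for m in sample_models]
            bounds[rid] = (float(np.mean(lbs)), float(np.mean(ubs)))
        out[condition] = model.with_bounds(bounds)
    return out


def aggregate_fva(results: Sequence[FVAResult]) -> FVAResult:
    """Element-wise mean of per-sample FVA ranges within one condition."""
    if not results:
        raise ValueError("no FVA results to aggregate")
    rids = set(results[0].ranges)
    if any(set(r.ranges) != rids for r in results):
        raise ValueError("FVA results cover different reaction sets")
    ranges = {
        rid: (
            float(np.mean([r.ranges[rid][0] for r in results])),
            float(np.mean([r.ranges[rid][1] for r in results])),
        )
        for rid in rids
    }
    return FVAResult(ranges, results[0].alpha,
                     float(np.mean([r.fmax_used for r in results])))


def _load_inputs(config: RunConfig):
    model = load_model(config.model_path, config.model_dialect)
    model, curation_log = curate_model(model, config)
    profiles = read_expression_tsv(config.expression_path, config.samples_path,
                                   raw_counts=config.raw_counts)
    return model, curation_log, profiles


def run_differential_flux(config: RunConfig) -> RunReport:
    """Curate, constrain, FVA per sample, aggregate and fold-change."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, curation_log, profiles = _load_inputs(config)
    per_condition: dict[str, list[FVAResult]] = {"control": [], "treated": []}
    sample_frames = []
    for profile in profiles:
        smodel = _sample_model(model, profile, config.integration)
        fva = flux_variability(smodel, config.alpha, config.biomass_relaxed)
        per_condition[profile.condition].append(fva)
        frame = fva.to_frame()
        frame.insert(0, "sample_id", profile.sample_id)
        frame.insert(1, "condition", profile.condition)
        sample_frames.append(frame)
    for condition in ("control", "treated"):
        if not per_condition[condition]:
            raise ValueError(f"no {condition} samples in the expression input")
    control = aggregate_fva(per_condition["control"])
    treated = aggregate_fva(per_condition["treated"])
    diff = flux_fold_change(treated, control, eps=default_eps(model))
    diff_path = out_dir / "differential_flux.tsv"
    diff.table.to_csv(diff_path, sep="\t", float_format="%.10g")
    samples_path = out_dir / "per_sample_fva.tsv"
    pd.concat(sample_frames).to_csv(samples_path, sep="\t", float_format="%.10g")
    meta = _write_metadata(config, out_dir, "differential_flux", {
        "curation_log": curation_log,
        "control_fmax": control.fmax_used,
        "treated_fmax": treated.fmax_used,
        "n_samples": len(profiles),
    })
    return RunReport({"differential_flux": str(diff_path),
                      "per_sample_fva": str(samples_path)}, meta)


def run_knockout_screen(config: RunConfig) -> RunReport:
    """Rank gene knockouts that move the treated state back toward control."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, curation_log, profiles = _load_inputs(config)
    cmodels = condition_models(model, profiles, config.integration)
    if set(cmodels) != {"control", "treated"}:
        raise ValueError("knockout screen needs both control and treated samples")
    source_model = cmodels["treated"]   # state to revert
    target_fva = flux_variability(cmodels["control"], config.alpha, config.biomass_relaxed)
    source_fva = flux_variability(source_model, config.alpha, config.biomass_relaxed)
    candidates = list(config.candidate_genes) if config.candidate_genes is not None else None
    scores, infeasible = rank_gene_knockouts(
        source_model, source_fva, target_fva,
        candidate_genes=candidates, tau=config.tau,
    )
    frame = scores_to_frame(scores, infeasible)
    rank_path = out_dir / "knockout_ranking.tsv"
    frame.to_csv(rank_path, sep="\t", index=False, float_format="%.10g")
    meta = _write_metadata(config, out_dir, "knockout_screen", {
        "curation_log": curation_log,
        "n_candidates": len(frame),
        "infeasible_genes": list(infeasible),
    })
    return RunReport({"knockout_ranking": str(rank_path)}, meta)


def run_kinetics_report(config: RunConfig) -> RunReport:
    """Dose-response fits, mode call, optional Ki, and melt-curve Tm/dTm."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    fit_rows = []
    per_substrate: dict[float, list[float]] = {}
    for path in config.assay_paths:
        for table in read_assay_csv(path):
            try:
                fit = fit_dose_response(table)
            except ValueError as exc:
                fit_rows.append({"substrate_uM": table.substrate_uM,
                                 "replicate": table.replicate, "Vmax": np.nan,
                                 "IC50_uM": np.nan, "h": np.nan,
                                 "converged": False, "message": str(exc)})
                continue
            fit_rows.append({"substrate_uM": table.substrate_uM,
                             "replicate": table.replicate, "Vmax": fit.Vmax,
                             "IC50_uM": fit.IC50, "h": fit.h,
                             "converged": fit.converged, "message": fit.message})
            if fit.converged:
                per_substrate.setdefault(table.substrate_uM, []).append(fit.IC50)
    fits_path = out_dir / "dose_response_fits.tsv"
    pd.DataFrame(fit_rows, columns=["substrate_uM", "replicate", "Vmax", "IC50_uM",
                                    "h", "converged", "message"]
                 ).to_csv(fits_path, sep="\t", index=False, float_format="%.10g")
    if len(per_substrate) >= 2:
        points = [(S, float(np.mean(ics))) for S, ics in sorted(per_substrate.items())]
        call = classify_inhibition_mode(points, Km=config.Km)
        summary["mode"] = call.mode
        summary["fold_shift"] = call.fold_shift
        summary["ic50_by_substrate_uM"] = list(call.ic50_by_substrate)
        if call.Ki is not None:
            summary["Ki_uM"] = call.Ki
            summary["Km_used_uM"] = call.Km_used
    elif fit_rows:
        summary["mode"] = "indeterminate"
        summary["note"] = "mode call needs fits at >= 2 substrate levels"
    if config.melt_apo_path:
        apo = read_melt_csv(config.melt_apo_path, label="apo")
        tm_apo = fit_melting_temperature(apo, config.tm_method)
        summary["Tm_apo_C"] = tm_apo
        if config.melt_holo_path:
            holo = read_melt_csv(config.melt_holo_path, label="holo")
            tm_holo = fit_melting_temperature(holo, config.tm_method)
            summary["Tm_holo_C"] = tm_holo
            summary["delta_Tm_C"] = delta_tm(tm_holo, tm_apo)
    if not fit_rows and "Tm_apo_C" not in summary:
        summary["note"] = "no kinetics inputs"
    summary_path = out_dir / "kinetics_summary.json"
    summary_path.write_text(json.dumps(summary, indent=1) + "\n")
    meta = _write_metadata(config, out_dir, "kinetics", {"n_fits": len(fit_rows)})
    return RunReport({"dose_response_fits": str(fits_path),
                      "kinetics_summary": str(summary_path)}, meta)
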