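"""One-command orchestration of the full analysis chain.

Stages (in dependency order):

    simulate -> fitness -> threshold -> {descriptives, outcomes, niches, abm}

``simulate`` writes a synthetic cohort panel; ``fitness`` fits the network
logit per analyzable wave and writes models and fitness surfaces;
``threshold`` calibrates the fitness threshold on pooled reported ties; the
remaining stages consume those artifacts.  Every run writes a manifest with
stage parameters, the global seed, and a sha256 checksum per artifact, so a
rerun with the same configuration is verifiably identical.

The global seed fans out to per-stage seeds through a fixed counter scheme
(stage k uses ``(seed * 1009 + k) mod 2**31``), so individual stages are
reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abm as abm_mod
from .descriptives import assortativity_table, coefficient_dispersion
from .fitness import TieFitnessModel, calibrate_threshold, retrieval_curve
from .niches import blockmodel_order, cell_states, dormant_ties, niche_density
from .outcomes import OUTCOMES, build_outcome_table, fit_outcome_model
from .panel import Panel, adjacency_matrix, read_panel, write_panel
from .synthetic import CohortConfig, GroundTruth, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fitness", "threshold", "descriptives", "outcomes",
          "niches", "abm")
_REQUIRES = {
    "simulate": (),
    "fitness": ("simulate",),
    "threshold": ("fitness",),
    "descriptives": ("fitness",),
    "outcomes": ("threshold",),
    "niches": ("threshold",),
    "abm": ("threshold",),
}

__all__ = ["PipelineConfig", "DependencyError", "run_pipeline", "stage_seed"]


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream stage."""


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + STAGES.index(stage)) % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str | Path = "netecol_out"
    panel_dir: str | Path | None = None  # read an existing panel instead of simulating
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    retrieval_target: float = 0.90
    threshold_override: float | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sim: abm_mod.SimConfig = field(default_factory=abm_mod.SimConfig)
    abm_runs: int = 2
    abm_iterations: int = 25

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


def _check_dependencies(stages: tuple[str, ...], have_panel: bool) -> None:
    done = set()
    if have_panel:
        done.add("simulate")
    for stage in STAGES:
        if stage not in stages:
            continue
        missing = [d for d in _REQUIRES[stage] if d not in done and d not in stages]
        if missing:
            raise DependencyError(
                f"stage {stage!r} requires {missing[0]!r}; run it first"
            )
        done.add(stage)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(s for s in STAGES if s in config.stages)
    _check_dependencies(stages, have_panel=config.panel_dir is not None)

    artifacts: list[Path] = []
    params: dict[str, dict] = {}
    panel: Panel | None = None
    results_by_wave: dict = {}
    surfaces: dict = {}
    threshold: float | None = config.threshold_override

    if config.panel_dir is not None:
        pdir = Path(config.panel_dir)
        panel = read_panel(pdir / "edges.csv", pdir / "nodes.csv")

    if "simulate" in stages:
        seed = stage_seed(config.seed, "simulate")
        cohort_cfg = CohortConfig(**{**asdict(config.cohort), "seed": seed})
        panel, truth = generate_cohort(cohort_cfg)
        paths = write_panel(panel, out / "panel")
        truth_path = out / "panel" / "truth.json"
        truth_path.write_text(json.dumps(
            {"coefficients": truth.coefficients.round(6).to_dict(orient="index")},
            indent=2, sort_keys=True,
        ))
        artifacts += [*paths.values(), truth_path]
        params["simulate"] = {"seed": seed, "n": cohort_cfg.n,
                              "n_waves": cohort_cfg.n_waves}

    if "fitness" in stages:
        assert panel is not None
        analysis_waves = panel.wave_labels[:-1]  # last wave has no tie future
        for wave in analysis_waves:
            res = TieFitnessModel.from_panel(panel, wave).fit()
            results_by_wave[wave] = res
            surfaces[wave] = res.fitness()
            mpath = out / f"model_{wave}.json"
            mpath.write_text(json.dumps(res.to_dict(), indent=2, sort_keys=True))
            spath = out / f"surface_{wave}.csv"
            surfaces[wave].to_csv(spath)
            artifacts += [mpath, spath]
        params["fitness"] = {"waves": analysis_waves}

    if "threshold" in stages:
        reported = [
            surfaces[w].reported_fitness(panel.wave(w).edge_set())
            for w in surfaces
        ]
        calib = calibrate_threshold(reported, config.retrieval_target)
        if threshold is None:
            threshold = calib.threshold
        tpath = out / "threshold.json"
        tpath.write_text(json.dumps(calib.to_dict(), indent=2, sort_keys=True))
        artifacts.append(tpath)
        params["threshold"] = {"retrieval_target": config.retrieval_target,
                               "threshold": threshold}

    if "descriptives" in stages:
        apath = out / "assortativity.csv"
        assortativity_table(panel).round(6).to_csv(apath)
        dpath = out / "coefficient_dispersion.csv"
        disp = coefficient_dispersion(list(results_by_wave.values()))
        disp.round(6).to_csv(dpath)
        artifacts += [apath, dpath]
        params["descriptives"] = {
            "reciprocity_clustering_corr":
                disp.attrs["reciprocity_clustering_corr"],
        }

    if "outcomes" in stages:
        table = build_outcome_table(panel, surfaces)
        coefs = {}
        curves = []
        for outcome in OUTCOMES:
            try:
                res = fit_outcome_model(table, outcome)
            except ValueError as exc:
                logger.warning("skipping %s model: %s", outcome, exc)
                continue
            coefs[outcome] = {
                "params": res.params.round(6).to_dict(),
                "cluster_robust_se": res.bse.round(6).to_dict(),
            }
            curve = res.marginal_effect_curve(np.linspace(0, 1, 21))
            curve.insert(0, "outcome", outcome)
            curves.append(curve)
        opath = out / "outcome_models.json"
        opath.write_text(json.dumps(coefs, indent=2, sort_keys=True))
        cpath = out / "marginal_effects.csv"
        pd.concat(curves, ignore_index=True).round(6).to_csv(cpath, index=False)
        artifacts += [opath, cpath]
        params["outcomes"] = {"n_records": len(table)}

    if "niches" in stages:
        wave = panel.wave_labels[len(panel.wave_labels) // 2 - 1]
        surface = surfaces[wave]
        R = adjacency_matrix(panel, wave)
        dormant = dormant_ties(surface, R, threshold, panel.roster)
        F = (surface.fitness_matrix(panel.roster) >= threshold)
        np.fill_diagonal(F, False)
        part = blockmodel_order(F.astype(int))
        dens = niche_density(part, F.astype(int))
        bpath = out / "blocks.csv"
        pd.DataFrame({
            "node": panel.roster,
            "block": part.blocks,
            "display_order": np.argsort(part.permutation),
        }).to_csv(bpath, index=False)
        npath = out / "niche_density.csv"
        dens.round(6).to_csv(npath, index=False)
        cpath = out / "cellstates.csv"
        cell_states(panel, wave, surface, threshold).to_csv(cpath, index=False)
        artifacts += [bpath, npath, cpath]
        params["niches"] = {
            "wave": wave,
            "n_dormant": len(dormant),
            "clustering_ratio": dens.attrs["clustering_ratio"],
        }

    if "abm" in stages:
        from dataclasses import replace

        wave = panel.wave_labels[0]
        sim_cfg = replace(
            config.sim,
            runs=config.abm_runs,
            iterations=config.abm_iterations,
            fitness_threshold=threshold,
            seed=stage_seed(config.seed, "abm"),
        )
        summary = abm_mod.run_experiment(
            [(panel, wave, results_by_wave[wave])], sim_cfg
        )
        spath = out / "abm_shares.csv"
        summary.round(6).to_csv(spath, index=False)
        artifacts.append(spath)
        params["abm"] = {"runs": sim_cfg.runs, "iterations": sim_cfg.iterations}

    manifest = {
        "seed": config.seed,
        "stages": list(stages),
        "parameters": params,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
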