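"""End-to-end study orchestration.

``run_study`` sequences the full analysis — benthic survey statistics,
scaled trophic positions with between-site tests and correlations, isotopic
niche metrics with between-site SEAc overlap, and the Bayesian mixing model
per trophic category — over a synthetic scenario or ingested CSV tables, and
writes one JSON report bundle plus a manifest (seeds, config hash, versions,
aggregated warnings). Every number in the bundle is produced by exactly one
module operation; the pipeline only assembles and serializes.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .data_model import (
    POST_TEF,
    StudyDataset,
    TrophicEnrichmentFactor,
    pool_sources,
    read_samples,
    read_transects,
)
from .errors import ConfigError, IsoNicheError
from .mixing_model import ChainConfig, fit_by_category, summarize_posterior
from .niche_metrics import category_metrics, ellipse_overlap
from .survey_stats import compare_sites, cover_summary, macroalgae_cover, rugosity
from .synthetic_reef import (
    DEFAULT_SOURCE_GROUPING,
    ReefScenario,
    default_scenario,
    generate_dataset,
    noise_free_scenario,
    scenario_from_yaml,
)
from .trophic_position import (
    DEFAULT_SCALING,
    ScalingParams,
    compare_species_between_sites,
    cross_site_correlation,
    estimate_species_tp,
    paired_taxon_values,
)

__all__ = ["AnalysisConfig", "run_study", "config_from_yaml"]


@dataclass
class AnalysisConfig:
    """One configuration for the whole study pipeline."""

    scenario: ReefScenario | None = None
    samples_path: str | None = None
    transect_points_path: str | None = None
    transect_chains_path: str | None = None
    baseline_taxon: str | None = None  # default: scenario's baseline
    scaling: ScalingParams = DEFAULT_SCALING
    tef: TrophicEnrichmentFactor = POST_TEF
    source_grouping: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_GROUPING)
    )
    mcmc: ChainConfig = field(default_factory=ChainConfig)
    sea_draws: int = 100_000
    niche_level: str = "species_means"
    seed: int = 1
    out_dir: str = "results"

    def resolve_baseline(self) -> str:
        if self.baseline_taxon:
            return self.baseline_taxon
        if self.scenario is not None:
            return self.scenario.baseline_taxon
        raise ConfigError("baseline_taxon is required when not using a scenario")


def config_from_yaml(path: str | Path) -> AnalysisConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    scenario = doc.pop("scenario", None)
    if scenario == "default":
        scenario = default_scenario()
    elif scenario == "noise_free":
        scenario = noise_free_scenario()
    elif isinstance(scenario, str):
        scenario = scenario_from_yaml(scenario)
    elif scenario is not None:
        raise ConfigError("scenario must be 'default', 'noise_free', or a file path")
    mcmc = ChainConfig(**doc.pop("mcmc", {}))
    tef = TrophicEnrichmentFactor(**doc.pop("tef")) if "tef" in doc else POST_TEF
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return AnalysisConfig(scenario=scenario, mcmc=mcmc, tef=tef, **doc)


def _config_hash(config: AnalysisConfig) -> str:
    def default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    doc = dataclasses.asdict(config)
    doc.pop("out_dir", None)  # the analysis is the same wherever it is written
    payload = json.dumps(doc, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _write_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def _load_dataset(config: AnalysisConfig) -> StudyDataset:
    if config.scenario is not None:
        return generate_dataset(config.scenario, seed=config.seed)
    if config.samples_path is None:
        raise ConfigError("provide either a scenario or samples_path")
    samples = read_samples(config.samples_path)
    transects = []
    if config.transect_points_path and config.transect_chains_path:
        transects = read_transects(config.transect_points_path, config.transect_chains_path)
    return StudyDataset(
        samples=samples, transects=transects, baseline_taxon=config.resolve_baseline()
    )


def _survey_stage(dataset: StudyDataset) -> dict:
    if not dataset.transects:
        return {"skipped": "no transects"}
    sites = sorted({t.site for t in dataset.transects})
    components = sorted({c for t in dataset.transects for c in t.point_components})
    summaries = cover_summary(dataset.transects, components)
    by_site = {s: [t for t in dataset.transects if t.site == s] for s in sites}
    out: dict[str, Any] = {
        "cover": [dataclasses.asdict(s) for s in summaries],
        "rugosity": {
            s: [rugosity(t) for t in group] for s, group in by_site.items()
        },
        "macroalgae_pct": {
            s: [macroalgae_cover(t) for t in group] for s, group in by_site.items()
        },
    }
    if len(sites) == 2:
        a, b = sites
        tests = {}
        coral_a = [
            100.0 * t.point_components.count("coral") / len(t.point_components)
            for t in by_site[a]
        ]
        coral_b = [
            100.0 * t.point_components.count("coral") / len(t.point_components)
            for t in by_site[b]
        ]
        tests["coral_cover"] = dataclasses.asdict(compare_sites(coral_a, coral_b))
        tests["rugosity"] = dataclasses.asdict(
            compare_sites(out["rugosity"][a], out["rugosity"][b])
        )
        tests["macroalgae"] = dataclasses.asdict(
            compare_sites(out["macroalgae_pct"][a], out["macroalgae_pct"][b])
        )
        out["tests"] = {"sites": [a, b], **tests}
    return out


def _tp_stage(dataset: StudyDataset, config: AnalysisConfig) -> dict:
    baseline = config.resolve_baseline()
    sites = dataset.sites()
    estimates = {
        site: estimate_species_tp(dataset.samples, baseline, site, config.scaling)
        for site in sites
    }
    out: dict[str, Any] = {
        "baseline_taxon": baseline,
        "params": dataclasses.asdict(config.scaling),
        "estimates": {
            site: [dataclasses.asdict(e) for e in ests] for site, ests in estimates.items()
        },
    }
    if len(sites) == 2:
        a, b = sites
        tp_a, tp_b, shared = paired_taxon_values(estimates[a], estimates[b])
        table, warn = compare_species_between_sites(
            dataset.samples, "TP", (a, b), baseline, config.scaling
        )
        c13_table, warn13 = compare_species_between_sites(dataset.samples, "d13C", (a, b))
        # per-taxon mean d13C for the cross-site correlation
        c13_a = c13_table["mean_a"].to_numpy()
        c13_b = c13_table["mean_b"].to_numpy()
        out["between_site_tests"] = {
            "TP": table.to_dict(orient="records"),
            "d13C": c13_table.to_dict(orient="records"),
        }
        out["correlations"] = {
            "TP": cross_site_correlation(tp_a, tp_b),
            "d13C": cross_site_correlation(c13_a, c13_b),
            "n_shared_taxa": len(shared),
        }
        out["warnings"] = warn + warn13
    return out


def _niche_stage(dataset: StudyDataset, config: AnalysisConfig, seed: int) -> dict:
    metrics = category_metrics(
        dataset.samples,
        dataset.category_map or None,
        level=config.niche_level,  # type: ignore[arg-type]
        sea_draws=config.sea_draws,
        seed=seed,
    )
    rows = {}
    for (category, site), m in metrics.items():
        sea_b = m.sea_b if m.sea_b is not None else np.array([])
        rows[f"{category}@{site}"] = {
            "n": m.n,
            "NR": m.nr,
            "CR": m.cr,
            "TA": m.ta,
            "SEA": m.sea,
            "SEAc": m.seac,
            "SEA_B_median": float(np.median(sea_b)) if sea_b.size else None,
            "SEA_B_ci95": (
                [float(q) for q in np.quantile(sea_b, [0.025, 0.975])] if sea_b.size else None
            ),
        }
    overlaps = {}
    categories = sorted({cat for cat, _ in metrics})
    sites = sorted({site for _, site in metrics})
    if len(sites) == 2:
        a, b = sites
        for category in categories:
            if (category, a) in metrics and (category, b) in metrics:
                ma, mb = metrics[(category, a)], metrics[(category, b)]
                res = ellipse_overlap(
                    ma.ellipse,
                    mb.ellipse,
                    scale_a=ma.seac / ma.sea,
                    scale_b=mb.seac / mb.sea,
                    label_a=f"{category}@{a}",
                    label_b=f"{category}@{b}",
                )
                overlaps[category] = dataclasses.asdict(res)
    return {"metrics": rows, "seac_overlap": overlaps}


def _mixing_stage(dataset: StudyDataset, config: AnalysisConfig, seed: int) -> dict:
    # source taxa without an entry in the grouping map stay their own group
    source_taxa = {s.taxon for s in dataset.samples if s.role.value == "source"}
    grouping = {t: t for t in source_taxa}
    grouping.update(
        {t: g for t, g in config.source_grouping.items() if t in source_taxa}
    )
    sources_by_site = {}
    for site in dataset.sites():
        site_sources = [s for s in dataset.samples if s.site == site and s.taxon in grouping]
        if site_sources:
            sources_by_site[site] = pool_sources(site_sources, grouping)
    posteriors, warnings = fit_by_category(
        dataset.samples,
        sources_by_site,
        config.tef,
        dataset.category_map or None,
        mcmc=config.mcmc,
        seed=seed,
    )
    out: dict[str, Any] = {"groups": {}, "warnings": warnings}
    for (site, category), post in sorted(posteriors.items()):
        out["groups"][f"{category}@{site}"] = {
            "summary": summarize_posterior(post),
            "acceptance": post.acceptance,
            "mcmc_warnings": post.warnings,
            "n_draws": int(post.draws.shape[0]),
        }
    return out


def run_study(config: AnalysisConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``config.out_dir``.

    Outputs: ``survey.json``, ``trophic_position.json``, ``niche.json``,
    ``mixing.json`` and ``manifest.json``. Stages run with seeds spawned
    deterministically from ``config.seed``, so a rerun with the same config
    yields byte-identical files. On any stage failure the partially written
    bundle is removed and the error re-raised with the stage name.
    """
    out_dir = Path(config.out_dir)
    staging = out_dir.with_name(out_dir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1, np.uint32)[0])
        for name, child in zip(("niche", "mixing"), seed_seq.spawn(2))
    }
    report: dict[str, Any] = {}
    stage = "load"
    try:
        dataset = _load_dataset(config)
        stage = "survey"
        report["survey"] = _survey_stage(dataset)
        _write_json(staging / "survey.json", report["survey"])
        stage = "trophic_position"
        report["trophic_position"] = _tp_stage(dataset, config)
        _write_json(staging / "trophic_position.json", report["trophic_position"])
        stage = "niche"
        report["niche"] = _niche_stage(dataset, config, stage_seeds["niche"])
        _write_json(staging / "niche.json", report["niche"])
        stage = "mixing"
        report["mixing"] = _mixing_stage(dataset, config, stage_seeds["mixing"])
        _write_json(staging / "mixing.json", report["mixing"])
        stage = "manifest"
        manifest = {
            "package": "isonicheweb",
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": stage_seeds,
            "config_sha256": _config_hash(config),
            "outputs": ["survey.json", "trophic_position.json", "niche.json", "mixing.json"],
            "warnings": (
                report["trophic_position"].get("warnings", [])
                + report["mixing"].get("warnings", [])
            ),
        }
        report["manifest"] = manifest
        _write_json(staging / "manifest.json", manifest)
    except IsoNicheError as exc:
        shutil.rmtree(staging, ignore_errors=True)
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
    return report
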