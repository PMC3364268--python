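"""End-to-end orchestration: simulate → fit → classify → scale → report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import allometry as allo_mod
from . import energetics as ener_mod
from . import hydrology as hydro_mod
from . import subsidy as sub_mod
from .allometry import AllometricModel, WetDryRecord
from .energetics import (CatchRecord, PelletRecord, SampleMetrics,
                         SpeciesEnergyDensity)
from .hydrology import PulseWindow, WaterLevelSeries
from .io import config_hash, write_table, write_water_levels
from .reporting import (EnvSummary, RunConfig, env_summary_frame,
                        render_report, summarize_environment)
from .subsidy import METRICS, PulseProportion, SubsidyEstimate
from .synthetic import (GroundTruth, default_allometry_truth,
                        default_calorimetry_truth, default_community_config,
                        default_hydro_config, default_pulse_windows,
                        generate_pellets, generate_sampling_campaign,
                        generate_water_levels, generate_wet_dry_individuals)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "build_sample_metrics", "fit_all_species",
           "aggregate_energies", "run_all", "write_outputs"]

# offsets applied to the run seed for the four independent generator streams
_SEED_HYDRO, _SEED_CAMPAIGN, _SEED_WETDRY, _SEED_PELLETS = 0, 101, 202, 303


@dataclass
class PipelineResult:
    """Everything a full run produced, ready to inspect or write out."""

    seed: int
    config: Dict[str, object]
    config_digest: str
    windows: List[PulseWindow]
    inflow: WaterLevelSeries
    reference: WaterLevelSeries
    samples: pd.DataFrame
    catches: List[CatchRecord]
    truth: GroundTruth
    wetdry: List[WetDryRecord]
    pellets: List[PelletRecord]
    models: Dict[str, AllometricModel]
    energies: Dict[str, SpeciesEnergyDensity]
    metrics: List[SampleMetrics]
    classification: pd.DataFrame
    proportions: Dict[str, List[PulseProportion]]
    estimates: List[SubsidyEstimate]
    env_summaries: List[EnvSummary]
    flooded: Dict[str, Dict[str, float]]
    report: str = field(repr=False, default="")


def fit_all_species(records: Sequence[WetDryRecord],
                    alpha: float = 0.05) -> Dict[str, AllometricModel]:
    """Fit one wet:dry model per species present in ``records``."""
    by_sp: Dict[str, List[WetDryRecord]] = {}
    for r in records:
        by_sp.setdefault(r.species, []).append(r)
    return {sp: allo_mod.fit_wet_dry(recs, alpha=alpha)
            for sp, recs in by_sp.items()}


def aggregate_energies(
    pellets: Sequence[PelletRecord],
) -> Dict[str, SpeciesEnergyDensity]:
    by_sp: Dict[str, List[PelletRecord]] = {}
    for p in pellets:
        by_sp.setdefault(p.species, []).append(p)
    return {sp: ener_mod.mean_energy_density(ps) for sp, ps in by_sp.items()}


def build_sample_metrics(
    samples: pd.DataFrame,
    catches: Sequence[CatchRecord],
    models: Dict[str, AllometricModel],
    energies: Dict[str, SpeciesEnergyDensity],
    included_species: Optional[set] = None,
) -> List[SampleMetrics]:
    """Per-sample standing stock; samples with no catch contribute zeros."""
    by_sample: Dict[str, List[CatchRecord]] = {
        sid: [] for sid in samples["sample_id"]}
    for c in catches:
        if c.sample_id not in by_sample:
            raise KeyError(f"catch references unknown sample {c.sample_id}")
        by_sample[c.sample_id].append(c)
    out = []
    for sid in samples["sample_id"]:
        recs = by_sample[sid]
        if recs:
            out.append(ener_mod.sample_metrics(recs, models, energies,
                                               included_species))
        else:
            out.append(SampleMetrics(sid, 0.0, 0.0, 0.0))
    return out


def _species_stock_table(samples: pd.DataFrame,
                         metrics: Sequence[SampleMetrics],
                         windows: Sequence[PulseWindow],
                         species: Sequence[str]) -> pd.DataFrame:
    """Per-pulse per-species mean±SE density and energy (zeros included)."""
    by_id = {m.sample_id: m for m in metrics}
    rows = []
    for w in windows:
        sids = samples.loc[samples["pulse_id"] == w.pulse_id, "sample_id"]
        if len(sids) == 0:
            continue
        for sp in species:
            dens = np.array([by_id[s].by_species_density.get(sp, 0.0)
                             for s in sids])
            ener = np.array([by_id[s].by_species_energy.get(sp, 0.0)
                             for s in sids])
            rows.append({
                "pulse_id": w.pulse_id, "species": sp,
                "density_mean": dens.mean(),
                "density_se": (dens.std(ddof=1) / np.sqrt(len(dens))
                               if len(dens) > 1 else 0.0),
                "energy_mean": ener.mean(),
                "energy_se": (ener.std(ddof=1) / np.sqrt(len(ener))
                              if len(ener) > 1 else 0.0),
                "n": len(dens),
            })
    return pd.DataFrame(rows)


def run_all(seed: int = 0, config: Optional[RunConfig] = None) -> PipelineResult:
    """Run the whole synthetic study and analysis for one seed."""
    cfg = config or RunConfig(seed=seed)
    cfg.seed = seed

    hydro_cfg = default_hydro_config(seed + _SEED_HYDRO)
    if cfg.hydro:
        over = dict(cfg.hydro)
        if "pulse_windows" in over:
            over["pulse_windows"] = tuple(
                (pd.Timestamp(s), pd.Timestamp(e))
                for s, e in over["pulse_windows"])
        hydro_cfg = replace(hydro_cfg, **over)
    comm_cfg = default_community_config(seed + _SEED_CAMPAIGN)
    if cfg.community:
        comm_cfg = replace(comm_cfg, **dict(cfg.community))
    allo_truth = default_allometry_truth(seed + _SEED_WETDRY)
    calo_truth = default_calorimetry_truth(seed + _SEED_PELLETS)
    windows = cfg.windows() or default_pulse_windows()

    inflow, reference = generate_water_levels(hydro_cfg)
    samples, catches, truth = generate_sampling_campaign(
        comm_cfg, (inflow, reference), windows, allo_truth, calo_truth)
    wetdry = generate_wet_dry_individuals(allo_truth)
    pellets = generate_pellets(calo_truth)

    models = fit_all_species(wetdry, alpha=cfg.alpha)
    energies = aggregate_energies(pellets)
    included = (set(cfg.included_species) if cfg.included_species
                else set(ener_mod.DOMINANT_SPECIES))
    metrics = build_sample_metrics(samples, catches, models, energies,
                                   included)

    classification = hydro_mod.classify_samples(samples, inflow, reference,
                                                windows)
    flags = dict(zip(classification["sample_id"],
                     classification["subsidized"]))

    by_pulse: Dict[str, List[SampleMetrics]] = {w.pulse_id: [] for w in windows}
    for m, pid in zip(metrics, samples["pulse_id"]):
        by_pulse[pid].append(m)

    proportions: Dict[str, List[PulseProportion]] = {}
    estimates: List[SubsidyEstimate] = []
    for metric in METRICS:
        props = [sub_mod.pulse_proportion(by_pulse[w.pulse_id], flags,
                                          metric, w.pulse_id)
                 for w in windows if by_pulse[w.pulse_id]]
        proportions[metric] = props
        Y, Y_err = sub_mod.cross_pulse_mean(props)
        X, X_err = sub_mod.inflow_mean(metrics, metric)
        estimates.append(sub_mod.subsidy_estimate(
            X, X_err, Y, Y_err, metric=metric, error_rule=cfg.error_rule))

    env_summaries = [s for w in windows
                     if (samples["pulse_id"] == w.pulse_id).any()
                     for s in summarize_environment(samples, w)]
    flooded = {w.pulse_id: {
        "inflow": hydro_mod.flooded_fraction(inflow, w),
        "reference": hydro_mod.flooded_fraction(reference, w),
    } for w in windows}
    sub_counts = {
        w.pulse_id: (
            int(classification.loc[classification["pulse_id"] == w.pulse_id,
                                   "subsidized"].sum()),
            int((classification["pulse_id"] == w.pulse_id).sum()))
        for w in windows}

    config_dict = cfg.to_dict()
    digest = config_hash(config_dict)
    species_stock = _species_stock_table(samples, metrics, windows,
                                         sorted(included))
    report = render_report(
        config=config_dict, seed=seed, config_digest=digest,
        env_summaries=env_summaries, flooded=flooded,
        subsidized_counts=sub_counts, species_stock=species_stock,
        estimates=estimates,
        record_counts={
            "water level readings": 2 * len(inflow.times),
            "samples": len(samples),
            "catch records": len(catches),
            "wet/dry individuals": len(wetdry),
            "pellets": len(pellets),
        })

    return PipelineResult(
        seed=seed, config=config_dict, config_digest=digest,
        windows=windows, inflow=inflow, reference=reference,
        samples=samples, catches=catches, truth=truth, wetdry=wetdry,
        pellets=pellets, models=models, energies=energies, metrics=metrics,
        classification=classification, proportions=proportions,
        estimates=estimates, env_summaries=env_summaries, flooded=flooded,
        report=report)


def write_outputs(result: PipelineResult, out_dir: Path | str) -> Path:
    """Write every stage's table plus the rendered report to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": result.seed, "config_hash": result.config_digest}

    write_water_levels([result.inflow, result.reference],
                       out / "water_levels.csv", meta)
    write_table(result.samples, out / "samples.csv", meta)
    write_table(pd.DataFrame([{
        "sample_id": c.sample_id, "species": c.species, "count": c.count,
        "wet_weight_g": c.wet_weight_g} for c in result.catches]),
        out / "catch.csv", meta)
    write_table(pd.DataFrame([{
        "species": r.species, "individual_id": i + 1, "wet_g": r.wet_g,
        "dry_g": r.dry_g} for i, r in enumerate(result.wetdry)]),
        out / "wetdry.csv", meta)
    write_table(pd.DataFrame([{
        "species": p.species, "replicate": p.replicate,
        "cal_per_g_dw": p.energy} for p in result.pellets]),
        out / "pellets.csv", meta)
    write_table(result.truth.to_frame(), out / "truth.csv", meta)
    write_table(result.classification, out / "classification.csv", meta)

    write_table(pd.DataFrame([{
        "species": m.species, "slope": m.slope,
        "intercept": np.nan if m.intercept is None else m.intercept,
        "intercept_dropped": m.intercept_dropped, "r2": m.r_squared,
        "n": m.n, "water_content_mean": m.mean_water_content,
        "water_content_se": (np.nan if m.water_content_se is None
                             else m.water_content_se)}
        for m in result.models.values()]), out / "allometry.csv", meta)

    rows = []
    for m in result.metrics:
        row = {"sample_id": m.sample_id, "density_ind_m2": m.density,
               "biomass_gdw_m2": m.biomass_dw, "energy_cal_m2":
               m.energy_density}
        for sp, v in m.by_species_density.items():
            row[f"density.{sp}"] = v
        for sp, v in m.by_species_biomass.items():
            row[f"biomass.{sp}"] = v
        for sp, v in m.by_species_energy.items():
            row[f"energy.{sp}"] = v
        rows.append(row)
    write_table(pd.DataFrame(rows).fillna(0.0), out / "sample_metrics.csv",
                meta)

    write_table(pd.DataFrame([{
        "metric": e.metric, "inflow_mean": e.inflow_mean,
        "inflow_se": e.inflow_se, "proportion_pct": e.proportion_pct,
        "proportion_se": e.proportion_se, "subsidy": e.subsidy,
        "subsidy_se": e.subsidy_se} for e in result.estimates]),
        out / "subsidy.csv", meta)
    write_table(env_summary_frame(result.env_summaries),
                out / "env_summary.csv", meta)

    (out / "report.md").write_text(result.report)
    logger.info("wrote outputs to %s", out)
    return out
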