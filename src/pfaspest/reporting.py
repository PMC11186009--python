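"""Pipeline orchestration and descriptive/model table emission.

``run_pipeline`` chains generate -> mass -> exposure -> demographics ->
inference and writes CSV/JSON artifacts plus a run manifest.  The descriptive
table mirrors a regional summary: system counts, population served,
per-analyte mean areal densities, population-weighted racial/ethnic and
poverty composition (denominator: regional population served) and the
unweighted mean % rented across systems.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import demographics as demog
from . import exposure as expo
from . import inference as infer
from . import mass as massmod
from .landscape import Landscape, LandscapeConfig, generate_landscape

log = logging.getLogger("pfaspest")

PCT_COLUMNS = ("pct_nl_white", "pct_latinx", "pct_nl_black", "pct_nl_asian",
               "pct_nl_native", "pct_nl_other", "pct_poverty")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    buffer_radius_m: float = expo.DEFAULT_BUFFER_RADIUS_M
    study_years: tuple[int, ...] = (2019, 2020, 2021)
    analyte_exclude: tuple[str, ...] = ()
    poverty_denominator: str = "households"
    resolve_service_areas: bool = False   # generated areas are already disjoint
    model: dict = field(default_factory=dict)
    run_sensitivity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.buffer_radius_m > 0:
            raise ValueError("buffer radius must be > 0")
        if not self.study_years:
            raise ValueError("study period must be non-empty")


def build_system_table(landscape: Landscape, config: RunConfig) -> pd.DataFrame:
    """Exposure + demographics joined per system (the modelling table)."""
    areas = landscape.service_areas
    if config.resolve_service_areas:
        resolved = expo.resolve_overlaps(areas)
    else:
        resolved = areas
    masses = massmod.compute_section_mass(
        landscape.applications,
        massmod.products_from_frame(landscape.products),
        period=config.study_years)
    totals = massmod.total_pfas(masses, exclude=config.analyte_exclude)
    all_masses = pd.concat([masses, totals], ignore_index=True)

    buffers = expo.buffer_wells(landscape.wells, config.buffer_radius_m)
    exposures = expo.allocate_mass(buffers, landscape.sections, all_masses)

    demo = demog.apportion(resolved, landscape.block_groups,
                           poverty_denominator=config.poverty_denominator)
    popest = demog.estimate_population(
        resolved, landscape.population_grid, landscape.admin_records,
        landscape.domestic_wells)
    pop_density = demog.population_density(
        resolved, popest.set_index("system_id")["population_served"])

    meta_cols = ["system_id", "region", "centroid_lat", "centroid_lon"]
    meta = resolved[[c for c in meta_cols if c in resolved.columns]]
    table = (
        exposures
        .merge(meta, on="system_id", how="left")
        .merge(demo, on="system_id", how="left")
        .merge(popest, on="system_id", how="left")
        .merge(pop_density.rename("pop_density"), on="system_id", how="left")
    )
    log.info("system table: %d systems, %d positive",
             len(table), int((table["density_mg_per_km2"] > 0).sum()))
    return table


def descriptive_table(table: pd.DataFrame,
                      region_column: str = "region") -> pd.DataFrame:
    """Regional + statewide descriptives in the style of a Table-1 summary.

    Composition percentages are population-weighted (the denominator is the
    regional population served); mean % rented is an unweighted mean across
    systems; densities are unweighted means across systems.
    """
    df = table.copy()
    if region_column not in df.columns:
        df[region_column] = "unassigned"
    df[region_column] = df[region_column].fillna("unassigned")

    density_cols = [c for c in df.columns if c.startswith("density_")
                    and c.endswith("_mg_km2")] + ["density_mg_per_km2"]

    def summarize(group: pd.DataFrame) -> dict:
        pop = group["population_served"].to_numpy(dtype=float)
        wsum = pop.sum()
        row = {
            "n_systems": len(group),
            "population_served": wsum,
        }
        for col in density_cols:
            label = (col.replace("density_", "mean_density_")
                     .replace("_mg_km2", "_mg_per_km2"))
            if col == "density_mg_per_km2":
                label = "mean_density_total_mg_per_km2"
            row[label] = float(group[col].mean())
        for col in PCT_COLUMNS:
            if col in group.columns:
                vals = group[col].to_numpy(dtype=float)
                ok = ~np.isnan(vals)
                row[col] = (float((vals[ok] * pop[ok]).sum() / pop[ok].sum())
                            if pop[ok].sum() > 0 else np.nan)
        if "pct_rented" in group.columns:
            row["mean_pct_rented"] = float(group["pct_rented"].mean())
        return row

    rows = []
    for region, group in df.groupby(region_column, sort=True):
        rows.append({"region": region, **summarize(group)})
    rows.append({"region": "statewide", **summarize(df)})
    return pd.DataFrame(rows)


def format_density(value: float) -> str:
    """Presentation rounding: one decimal, scientific below 1e-2."""
    if value == 0:
        return "0.0"
    if abs(value) < 1e-2:
        return f"{value:.1e}"
    return f"{value:.1f}"


def _model_records(result: infer.TwoPartResult) -> dict:
    out: dict = {"n_total": result.n_total, "n_positive": result.n_positive,
                 "n_zero": result.n_zero, "skipped": result.skipped}
    for part in (result.gaussian, result.logistic):
        if part is None:
            continue
        entry = {
            "n": part.n, "aic": part.aic, "log_likelihood": part.log_likelihood,
            "coefficients": part.summary.to_dict(orient="records"),
        }
        if part.morans is not None:
            entry["morans_i"] = {
                "statistic": part.morans.statistic,
                "expected": part.morans.expected,
                "p_permutation": part.morans.p_permutation,
                "p_analytic": part.morans.p_analytic,
            }
        out[part.kind] = entry
    return out


def run_pipeline(config: RunConfig, outdir: str | Path,
                 write_layers: bool = True) -> dict:
    """Run generate -> mass -> exposure -> demographics -> fit -> report.

    Writes the exposure/demographics system table, descriptive table, model
    tables (main + PFOS-exclusion sensitivity) and a manifest; returns the
    in-memory artifacts.  Deterministic given the config seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        landscape = generate_landscape(
            dataclasses.replace(config.landscape, seed=config.seed))
        if write_layers:
            landscape.write(outdir / "landscape")
        stage = "exposure"
        table = build_system_table(landscape, config)
        table.to_csv(outdir / "system_table.csv", index=False)
        stage = "descriptives"
        desc = descriptive_table(table)
        desc.to_csv(outdir / "descriptive_table.csv", index=False)
        pretty = desc.copy()
        for col in pretty.columns:
            if col.startswith("mean_density_"):
                pretty[col] = pretty[col].map(format_density)
        pretty.to_csv(outdir / "descriptive_table_formatted.csv", index=False)
        stage = "fit"
        est = infer.TwoPartGAM(random_state=config.seed, **config.model)
        est.fit(table)
        main = est.result_
        est.summary_.to_csv(outdir / "model_main.csv", index=False)
        (outdir / "model_main.json").write_text(
            json.dumps(_model_records(main), indent=2, default=float))
        sens = None
        if config.run_sensitivity:
            stage = "sensitivity"
            sens = infer.sensitivity_excl_pfos(table, estimator=est)
            (outdir / "model_sensitivity.json").write_text(
                json.dumps(_model_records(sens), indent=2, default=float))
            sens.summary.to_csv(outdir / "model_sensitivity.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {
            "systems": int(len(table)),
            "positive_systems": int((table["density_mg_per_km2"] > 0).sum()),
            "sections": int(len(landscape.sections)),
            "applications": int(len(landscape.applications)),
            "block_groups": int(len(landscape.block_groups)),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", manifest["stages"])
    return {"landscape": landscape, "table": table, "descriptives": desc,
            "main": main, "sensitivity": sens, "manifest": manifest}
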