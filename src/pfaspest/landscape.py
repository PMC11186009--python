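"""Seeded generator of a self-consistent synthetic study region.

The generator emulates the joint structure of the study's inputs: community
water systems (CWSs) with public supply wells nested in service areas,
~1-mile-square pesticide reporting sections tiling the region, census block
groups with spatially autocorrelated demographic gradients, a gridded
residential-population layer, administrative population/connection records and
domestic-well points.  Crucially it carries a *known ground truth*: section
application masses are constructed by inverting the downstream exposure
computation, so each system's areal PFAS density follows an exact two-part
model in its own apportioned covariates,

    any_s     ~ Bernoulli(logit^-1(a0 + b_L * latinx10_s + b_W * n_wells_s + g_l(x, y)))
    ln dens_s = g0 + c_L * latinx10_s + h(popdens_s) + g_g(x, y) + eps,   eps ~ N(0, s2)

with ``latinx10`` the percent Latinx divided by 10 (centred), so that
exp(c_L) and exp(b_L) are the generating geometric-mean ratio and odds ratio
per 10-percentage-point increase.  The intercept ``a0`` is calibrated so the
marginal zero fraction matches ``application_zero_fraction``.

Geometry is planar (projected metres).  System seed points sit on a jittered
lattice so that each system's dissolved 1-km well buffer — and every section
it touches — stays inside the system's own neighbourhood; under the uniform
density-per-section construction the area-weighted allocation then returns
each system's generating density exactly, keeping the ground truth exact
under the full pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from . import demographics as demog
from . import exposure as expo
from . import mass as massmod
from .geotable import geometry_array, write_geojson

# planar-to-"degree" scaling for the centroid latitude/longitude stand-ins
_LAT_ORIGIN_DEG, _M_PER_DEG_LAT = 32.5, 111_320.0
_LON_ORIGIN_DEG, _M_PER_DEG_LON = -124.5, 92_000.0


@dataclass(frozen=True)
class LandscapeConfig:
    """Tunable parameters of the synthetic study region.

    Defaults echo the real study's scale: 2,444 groundwater-reliant systems,
    ~1-mile reporting sections, a 70% zero fraction (1,712 of 2,444 systems
    without nearby application), generating disparity parameters GMR 1.27 and
    OR 1.60 per 10 percentage points Latinx, an odds ratio 1.07 per supply
    well, and a 28.4-million regional population.
    """

    n_systems: int = 2444
    region_extent: tuple[float, float, float, float] | None = None
    system_spacing_m: float = 5500.0
    wells_per_system_mean: float = 2.9
    wells_per_system_dispersion: float = 1.6
    well_spread_m: float = 150.0
    section_size_m: float = 1609.34
    n_block_groups: int = 3000
    grid_cell_m: float = 1000.0
    regional_population: int = 28_400_000
    application_zero_fraction: float = 0.7
    disparity_beta_latinx: float = float(np.log(1.27))
    logit_beta_latinx: float = float(np.log(1.60))
    beta_n_wells: float = float(np.log(1.07))
    log_density_intercept: float = 0.5
    sigma_log_density: float = 2.5
    spatial_amp_gaussian: float = 0.5
    spatial_amp_logit: float = 0.4
    pop_density_effect: float = 0.15
    spatial_range_m: float = 40_000.0
    latinx_mean: float = 0.365
    latinx_scale: float = 0.8
    white_share_of_remainder: float = 0.62
    white_share_scale: float = 0.5
    poverty_mean: float = 0.27
    poverty_scale: float = 0.5
    poverty_latinx_corr: float = 0.5
    rented_mean: float = 0.31
    rented_scale: float = 0.4
    rented_latinx_corr: float = 0.3
    persons_per_household: float = 2.8
    pfos_mass_share: float = 0.999803
    pfbs_pfba_mass_ratio: float = 32.7 / 10.4
    overlap_margin_m: float = 0.0
    missing_admin_fraction: float = 0.023
    n_domestic_wells: int = 1500
    persons_per_domestic_well: float = 3.0
    buffer_radius_m: float = expo.DEFAULT_BUFFER_RADIUS_M
    study_years: tuple[int, ...] = (2019, 2020, 2021)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.application_zero_fraction <= 1.0:
            raise ValueError("application_zero_fraction must be in [0, 1]")
        for name in ("n_systems", "n_block_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.section_size_m > 0:
            raise ValueError("section_size_m must be > 0")
        if self.region_extent is not None:
            x0, y0, x1, y1 = self.region_extent
            if not (x1 > x0 and y1 > y0):
                raise ValueError(f"degenerate region extent {self.region_extent}")
        if not 0.0 <= self.pfos_mass_share <= 1.0:
            raise ValueError("pfos_mass_share must be in [0, 1]")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        if self.region_extent is not None:
            return self.region_extent
        side = int(np.ceil(np.sqrt(self.n_systems))) * self.system_spacing_m
        return (0.0, 0.0, side, side)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_years"] = list(self.study_years)
        if d["region_extent"] is not None:
            d["region_extent"] = list(d["region_extent"])
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of a generated landscape, reproducible from (config, seed)."""

    betas: dict
    systems: pd.DataFrame          # per-system covariates, p_positive, density_true
    block_groups: pd.DataFrame     # generating demographic counts
    zero_fraction: float


@dataclass
class Landscape:
    """Bundle of all generated layers plus the generating truth."""

    config: LandscapeConfig
    wells: pd.DataFrame
    service_areas: pd.DataFrame
    sections: pd.DataFrame
    applications: pd.DataFrame
    products: pd.DataFrame
    block_groups: pd.DataFrame
    population_grid: pd.DataFrame
    domestic_wells: pd.DataFrame
    admin_records: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        """Persist all layers (GeoJSON + CSV) with a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_geojson(self.wells, outdir / "wells.geojson")
        write_geojson(self.service_areas, outdir / "service_areas.geojson")
        write_geojson(self.sections, outdir / "sections.geojson")
        write_geojson(self.block_groups, outdir / "block_groups.geojson")
        for name in ("applications", "products", "population_grid",
                     "domestic_wells", "admin_records"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        cfg = self.config.to_dict()
        manifest = {
            "config": cfg,
            "seed": self.config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
            "rows": {name: int(len(getattr(self, name))) for name in (
                "wells", "service_areas", "sections", "applications",
                "block_groups", "population_grid", "domestic_wells",
                "admin_records")},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


class _SmoothField:
    """Gaussian-kernel-smoothed white noise on a lattice, unit variance.

    Approximates a Gaussian random field with correlation length of order
    ``range_m``; only smoothness and cross-layer coupling matter here, not the
    exact covariance family.
    """

    def __init__(self, extent, range_m: float, rng: np.random.Generator):
        x0, y0, x1, y1 = extent
        h = max(range_m / 4.0, 200.0)
        nx = int(np.ceil((x1 - x0) / h)) + 5
        ny = int(np.ceil((y1 - y0) / h)) + 5
        noise = rng.standard_normal((ny, nx))
        sigma = range_m / h / np.sqrt(2.0)
        smooth = ndimage.gaussian_filter(noise, sigma, mode="wrap")
        smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
        xs = x0 + (np.arange(nx) - 2) * h
        ys = y0 + (np.arange(ny) - 2) * h
        self._interp = RegularGridInterpolator(
            (ys, xs), smooth, bounds_error=False, fill_value=None)

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        return self._interp(np.c_[xy[:, 1], xy[:, 0]])


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``, exact sum."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _voronoi_cells(points: np.ndarray, extent) -> np.ndarray:
    """Voronoi cells of ``points`` clipped to the extent, aligned to ``points``."""
    x0, y0, x1, y1 = extent
    region = box(x0, y0, x1, y1)
    raw = np.asarray(list(voronoi_diagram(
        MultiPoint(points), envelope=region).geoms), dtype=object)
    tree = STRtree(raw)
    cells = np.empty(len(points), dtype=object)
    pts = shapely.points(points)
    idx_pt, idx_cell = tree.query(pts, predicate="within")
    cells[idx_pt] = raw[idx_cell]
    missing = np.array([c is None for c in cells])
    if missing.any():  # points exactly on a cell edge: nearest cell
        for i in np.flatnonzero(missing):
            cells[i] = raw[tree.nearest(pts[i])]
    return shapely.intersection(cells, region)


def _pfas_products(config: LandscapeConfig) -> pd.DataFrame:
    """Two synthetic formulations carrying the configured analyte mix.

    A PFOS-dominant insecticide and a PFBS/PFBA-bearing herbicide whose
    concentration ratio fixes the PFBS:PFBA mass ratio landscape-wide.
    """
    x_pfbs = 1130.0
    rows = [
        {"product_id": "SYN-AM-1100", "analyte": "PFOS",
         "ng_per_L": 3_920_000.0, "lbs_per_gal": 9.0},
        {"product_id": "SYN-FG-220", "analyte": "PFBS",
         "ng_per_L": x_pfbs, "lbs_per_gal": 8.5},
        {"product_id": "SYN-FG-220", "analyte": "PFBA",
         "ng_per_L": x_pfbs / config.pfbs_pfba_mass_ratio, "lbs_per_gal": 8.5},
    ]
    return pd.DataFrame(rows)


def _masses_to_applications(
    sec_ids: np.ndarray,
    total_mass: np.ndarray,
    products: pd.DataFrame,
    config: LandscapeConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Invert the mass formula: product pounds per (section, year) from target mass."""
    prods = massmod.products_from_frame(products)
    conv = massmod.LITERS_PER_GALLON * massmod.MG_PER_NG  # mg per (ng/L * gal)
    share_pfos = config.pfos_mass_share
    r = config.pfbs_pfba_mass_ratio
    w_pfos = share_pfos * total_mass
    w_pfbs = (1.0 - share_pfos) * total_mass * r / (1.0 + r)

    rows = []
    for pid, w_target, analyte in (
        ("SYN-AM-1100", w_pfos, "PFOS"),
        ("SYN-FG-220", w_pfbs, "PFBS"),
    ):
        if not np.any(w_target > 0):
            continue
        p = prods[pid]
        z = w_target * p.density_lbs_per_gal / (p.concentrations[analyte] * conv)
        nz = z > 0
        # split the cumulative pounds across study years
        shares = rng.gamma(2.0, size=(int(nz.sum()), len(config.study_years)))
        shares /= shares.sum(axis=1, keepdims=True)
        for k, year in enumerate(config.study_years):
            rows.append(pd.DataFrame({
                "section_id": sec_ids[nz],
                "product_id": pid,
                "year": year,
                "pounds_applied": z[nz] * shares[:, k],
            }))
    if not rows:
        return pd.DataFrame(columns=["section_id", "product_id", "year", "pounds_applied"])
    return (pd.concat(rows, ignore_index=True)
            .sort_values(["section_id", "product_id", "year"])
            .reset_index(drop=True))


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate all layers of a synthetic study region from a seeded config."""
    rng = np.random.default_rng(config.seed)
    x0, y0, x1, y1 = config.extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate region extent")

    # --- system seed points on a jittered lattice ------------------------
    n_side = int(np.ceil(np.sqrt(config.n_systems)))
    sx = (x1 - x0) / n_side
    sy = (y1 - y0) / n_side
    gx, gy = np.meshgrid(x0 + (np.arange(n_side) + 0.5) * sx,
                         y0 + (np.arange(n_side) + 0.5) * sy)
    lattice = np.c_[gx.ravel(), gy.ravel()]
    keep = rng.choice(len(lattice), size=config.n_systems, replace=False)
    keep.sort()
    seeds = lattice[keep] + rng.uniform(-0.1, 0.1, (config.n_systems, 2)) * [sx, sy]
    system_ids = np.array([f"CWS-{i:04d}" for i in range(config.n_systems)])

    # --- service areas: Voronoi cells, optional induced overlap + rule ---
    cells = _voronoi_cells(seeds, config.extent)
    if config.overlap_margin_m > 0:
        inflated = shapely.intersection(
            shapely.buffer(cells, config.overlap_margin_m, quad_segs=4),
            box(x0, y0, x1, y1))
        areas = pd.DataFrame({"system_id": system_ids, "geometry": inflated})
        areas = expo.resolve_overlaps(areas)
        cells = geometry_array(areas)
    centroids = shapely.get_coordinates(shapely.centroid(cells))
    mid_x, mid_y = (x0 + x1) / 2, (y0 + y1) / 2
    region_label = np.where(
        seeds[:, 1] >= mid_y,
        np.where(seeds[:, 0] < mid_x, "NW", "NE"),
        np.where(seeds[:, 0] < mid_x, "SW", "SE"))
    service_areas = pd.DataFrame({
        "system_id": system_ids,
        "region": region_label,
        "centroid_lat": _LAT_ORIGIN_DEG + centroids[:, 1] / _M_PER_DEG_LAT,
        "centroid_lon": _LON_ORIGIN_DEG + centroids[:, 0] / _M_PER_DEG_LON,
        "geometry": cells,
    })

    # --- wells ------------------------------------------------------------
    m = max(config.wells_per_system_mean - 1.0, 1e-9)
    if config.wells_per_system_dispersion > 1.0 + 1e-9:
        size = m / (config.wells_per_system_dispersion - 1.0)
        extra = rng.negative_binomial(size, size / (size + m), config.n_systems)
    else:
        extra = rng.poisson(m, config.n_systems)
    n_wells = 1 + extra
    owner = np.repeat(np.arange(config.n_systems), n_wells)
    pos = seeds[owner] + rng.normal(0.0, config.well_spread_m, (len(owner), 2))
    inside = shapely.contains_xy(cells[owner], pos[:, 0], pos[:, 1])
    for _ in range(8):
        if inside.all():
            break
        redo = ~inside
        pos[redo] = seeds[owner[redo]] + rng.normal(
            0.0, config.well_spread_m / 2, (int(redo.sum()), 2))
        inside = shapely.contains_xy(cells[owner], pos[:, 0], pos[:, 1])
    if not inside.all():
        pos[~inside] = shapely.get_coordinates(
            shapely.point_on_surface(cells[owner[~inside]]))
    wells = pd.DataFrame({
        "well_id": [f"W-{i:05d}" for i in range(len(owner))],
        "system_id": system_ids[owner],
        "x": pos[:, 0], "y": pos[:, 1],
        "geometry": shapely.points(pos),
    })

    # --- sections tiling the region --------------------------------------
    s = config.section_size_m
    nsx = int(np.ceil((x1 - x0) / s))
    nsy = int(np.ceil((y1 - y0) / s))
    bx, by = np.meshgrid(x0 + np.arange(nsx) * s, y0 + np.arange(nsy) * s)
    sec_boxes = shapely.box(bx.ravel(), by.ravel(),
                            np.minimum(bx.ravel() + s, x1),
                            np.minimum(by.ravel() + s, y1))
    sections = pd.DataFrame({
        "section_id": [f"S-{i:06d}" for i in range(len(sec_boxes))],
        "geometry": sec_boxes,
    })

    # --- smooth latent fields ---------------------------------------------
    f_latinx = _SmoothField(config.extent, config.spatial_range_m, rng)
    f_white = _SmoothField(config.extent, config.spatial_range_m, rng)
    f_pov = _SmoothField(config.extent, config.spatial_range_m, rng)
    f_rent = _SmoothField(config.extent, config.spatial_range_m, rng)
    f_pop = _SmoothField(config.extent, config.spatial_range_m, rng)
    f_app = _SmoothField(config.extent, config.spatial_range_m, rng)

    # --- residential population grid --------------------------------------
    g = config.grid_cell_m
    ngx = int(np.floor((x1 - x0) / g))
    ngy = int(np.floor((y1 - y0) / g))
    cx, cy = np.meshgrid(x0 + (np.arange(ngx) + 0.5) * g,
                         y0 + (np.arange(ngy) + 0.5) * g)
    cell_xy = np.c_[cx.ravel(), cy.ravel()]
    pop_counts = _largest_remainder(
        np.exp(1.2 * f_pop(cell_xy)), config.regional_population)
    population_grid = pd.DataFrame({
        "cell_id": np.arange(len(cell_xy)),
        "x": cell_xy[:, 0], "y": cell_xy[:, 1],
        "population": pop_counts,
    })

    # --- block groups ------------------------------------------------------
    bg_seeds = np.c_[rng.uniform(x0, x1, config.n_block_groups),
                     rng.uniform(y0, y1, config.n_block_groups)]
    bg_cells = _voronoi_cells(bg_seeds, config.extent)
    bg_ids = np.array([f"BG-{i:05d}" for i in range(config.n_block_groups)])
    cell_bg = cKDTree(bg_seeds).query(cell_xy)[1]  # Voronoi containment
    bg_pop = np.zeros(config.n_block_groups, dtype=np.int64)
    np.add.at(bg_pop, cell_bg, pop_counts)

    u = f_latinx(bg_seeds)
    p_lat = _sigmoid(np.log(config.latinx_mean / (1 - config.latinx_mean))
                     + config.latinx_scale * u)
    wsr = _sigmoid(
        np.log(config.white_share_of_remainder / (1 - config.white_share_of_remainder))
        + config.white_share_scale * f_white(bg_seeds))
    p_white = (1 - p_lat) * wsr
    poc_split = np.array([0.198, 0.630, 0.025, 0.147])  # Black/Asian/Native/Other
    shares = np.c_[p_lat, p_white,
                   np.outer((1 - p_lat) * (1 - wsr), poc_split)]
    race = np.vstack([_largest_remainder(shares[i], int(bg_pop[i]))
                      for i in range(config.n_block_groups)])

    hh_total = np.maximum(np.round(bg_pop / config.persons_per_household), 0).astype(np.int64)
    rho_r, rho_p = config.rented_latinx_corr, config.poverty_latinx_corr
    z_rent = rho_r * u + np.sqrt(1 - rho_r**2) * f_rent(bg_seeds)
    z_pov = rho_p * u + np.sqrt(1 - rho_p**2) * f_pov(bg_seeds)
    p_rent = _sigmoid(np.log(config.rented_mean / (1 - config.rented_mean))
                      + config.rented_scale * z_rent)
    p_pov = _sigmoid(np.log(config.poverty_mean / (1 - config.poverty_mean))
                     + config.poverty_scale * z_pov)
    block_groups = pd.DataFrame({
        "bg_id": bg_ids,
        "total_pop": bg_pop,
        "latinx": race[:, 0], "nl_white": race[:, 1], "nl_black": race[:, 2],
        "nl_asian": race[:, 3], "nl_native": race[:, 4], "nl_other": race[:, 5],
        "households_total": hh_total,
        "households_rented": np.round(hh_total * p_rent).astype(np.int64),
        "households_poverty": np.round(hh_total * p_pov).astype(np.int64),
        "persons_poverty": np.round(bg_pop * p_pov).astype(np.int64),
        "geometry": bg_cells,
    })

    # --- administrative records & domestic wells ---------------------------
    sys_of_cell = cKDTree(seeds).query(cell_xy)[1]
    sys_pop = np.zeros(config.n_systems)
    np.add.at(sys_pop, sys_of_cell, pop_counts)
    sdwis = np.round(sys_pop * rng.lognormal(0.0, 0.1, config.n_systems))
    missing = rng.random(config.n_systems) < config.missing_admin_fraction
    admin_records = pd.DataFrame({
        "system_id": system_ids,
        "sdwis_population": np.where(missing, np.nan, sdwis),
        "service_connections": np.maximum(np.round(sys_pop / 2.7), 1).astype(np.int64),
    })
    domestic_wells = pd.DataFrame({
        "x": rng.uniform(x0, x1, config.n_domestic_wells),
        "y": rng.uniform(y0, y1, config.n_domestic_wells),
        "persons": np.full(config.n_domestic_wells, config.persons_per_domestic_well),
    })

    # --- system-level covariates via the package's own pipeline ------------
    demo = demog.apportion(service_areas, block_groups)
    popest = demog.estimate_population(service_areas, population_grid,
                                       admin_records, domestic_wells)
    pop_served = popest.set_index("system_id")["population_served"]
    pop_density = demog.population_density(service_areas, pop_served)

    latinx10 = demo.set_index("system_id")["pct_latinx"].reindex(system_ids).to_numpy() / 10.0
    # systems apportioning zero population (possible in tiny test regions)
    latinx10 = np.where(np.isnan(latinx10), np.nanmean(latinx10), latinx10)
    latinx10_c = latinx10 - np.nanmean(latinx10)
    wells_c = n_wells - n_wells.mean()
    log_pd = np.log(pop_density.reindex(system_ids).to_numpy() + 1e-6)
    log_pd_c = log_pd - log_pd.mean()

    # additive low-frequency spatial trends (representable by lat+lon splines)
    ph = rng.uniform(0, 2 * np.pi, 4)
    lx, ly = (x1 - x0), (y1 - y0)

    def trend(amp, p1, p2):
        return amp / np.sqrt(2.0) * (
            np.sin(2 * np.pi * centroids[:, 0] / lx + p1)
            + np.sin(2 * np.pi * centroids[:, 1] / ly + p2))

    g_logit = trend(config.spatial_amp_logit, ph[0], ph[1])
    g_gauss = trend(config.spatial_amp_gaussian, ph[2], ph[3])

    eta = (config.logit_beta_latinx * latinx10_c
           + config.beta_n_wells * wells_c + g_logit)
    zf = config.application_zero_fraction
    if zf >= 1.0:
        p_pos = np.zeros(config.n_systems)
    elif zf <= 0.0:
        p_pos = np.ones(config.n_systems)
    else:
        a0 = brentq(lambda a: _sigmoid(a + eta).mean() - (1.0 - zf), -40.0, 40.0)
        p_pos = _sigmoid(a0 + eta)
    any_true = rng.random(config.n_systems) < p_pos

    log_dens = (config.log_density_intercept
                + config.disparity_beta_latinx * latinx10_c
                + config.pop_density_effect * log_pd_c
                + g_gauss
                + rng.normal(0.0, config.sigma_log_density, config.n_systems))
    density_true = np.where(any_true, np.exp(log_dens), 0.0)

    # --- section masses: invert buffering + allocation ----------------------
    buffers = expo.buffer_wells(wells, config.buffer_radius_m)
    buf_geoms = geometry_array(buffers)
    sec_tree = STRtree(sec_boxes)
    qb, qsec = sec_tree.query(buf_geoms, predicate="intersects")
    sec_area = shapely.area(sec_boxes)
    if len(qb):
        overlap = shapely.area(shapely.intersection(buf_geoms[qb], sec_boxes[qsec]))
        pairs = pd.DataFrame({"sys": qb, "sec": qsec, "overlap": overlap})
        owner_of_sec = pairs.loc[pairs.groupby("sec")["overlap"].idxmax()]
        shared = pairs.groupby("sec")["sys"].nunique()
        n_shared = int((shared > 1).sum())
    else:
        owner_of_sec = pd.DataFrame(columns=["sys", "sec", "overlap"])
        n_shared = 0

    sec_mass = np.zeros(len(sec_boxes))
    touched = np.zeros(len(sec_boxes), dtype=bool)
    if len(owner_of_sec):
        osec = owner_of_sec["sec"].to_numpy()
        osys = owner_of_sec["sys"].to_numpy()
        touched[osec] = True
        sec_mass[osec] = density_true[osys] * sec_area[osec] / 1e6  # km2

    # background applications away from any buffer, spatially clustered
    bg_secs = np.flatnonzero(~touched)
    if len(bg_secs) and zf < 1.0:
        sec_centers = shapely.get_coordinates(shapely.centroid(sec_boxes[bg_secs]))
        score = f_app(sec_centers) + 0.5 * rng.standard_normal(len(bg_secs))
        n_active = int(np.floor((1.0 - zf) * len(bg_secs)))
        if n_active > 0:
            active = bg_secs[np.argsort(-score, kind="stable")[:n_active]]
            med = config.log_density_intercept + np.log(sec_area[active] / 1e6)
            sec_mass[active] = rng.lognormal(med, config.sigma_log_density)

    products = _pfas_products(config)
    nz = sec_mass > 0
    applications = _masses_to_applications(
        sections["section_id"].to_numpy()[nz], sec_mass[nz], products, config, rng)

    truth_systems = pd.DataFrame({
        "system_id": system_ids,
        "x": seeds[:, 0], "y": seeds[:, 1],
        "n_wells": n_wells,
        "pct_latinx": latinx10 * 10.0,
        "pop_density": pop_density.reindex(system_ids).to_numpy(),
        "population_served": pop_served.reindex(system_ids).to_numpy(),
        "spatial_logit": g_logit, "spatial_gauss": g_gauss,
        "p_positive": p_pos, "any_true": any_true,
        "density_true": density_true,
    })
    truth = SyntheticTruth(
        betas={
            "gmr_latinx": float(np.exp(config.disparity_beta_latinx)),
            "or_latinx": float(np.exp(config.logit_beta_latinx)),
            "or_wells": float(np.exp(config.beta_n_wells)),
            "disparity_beta_latinx": config.disparity_beta_latinx,
            "logit_beta_latinx": config.logit_beta_latinx,
            "beta_n_wells": config.beta_n_wells,
        },
        systems=truth_systems,
        block_groups=block_groups.drop(columns="geometry").copy(),
        zero_fraction=zf,
    )
    if n_shared:
        warnings.warn(
            f"{n_shared} sections touched by buffers of multiple systems; "
            "their allocated densities deviate slightly from the generating truth",
            stacklevel=2)

    return Landscape(
        config=config, wells=wells, service_areas=service_areas,
        sections=sections, applications=applications, products=products,
        block_groups=block_groups, population_grid=population_grid,
        domestic_wells=domestic_wells, admin_records=admin_records,
        truth=truth,
    )
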