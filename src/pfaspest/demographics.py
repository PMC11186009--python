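"""Tiered CWS population estimation and areal apportionment of demographics.

Service population follows a tiered fallback chain: (1) sum of gridded
residential population whose cell centroids fall inside the service area;
(2) if that sum is below 25 (the technical definition of a community water
system) substitute the administrative SDWIS population; (3) if that is
missing, 3 persons per service connection.  Persons attributed to domestic
wells inside the boundary are then subtracted, flooring at zero.

Block-group sociodemographic counts are assigned to systems by areal
apportionment: block group ``b`` contributes its counts to system ``s`` with
weight area(b ∩ s) / area(b).  Percentages are recomputed from apportioned
numerators and denominators — persons for race/ethnicity, households for
tenure, and (configurably) households or persons for poverty.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .geotable import geometry_array

#: Below this tier-1 population the administrative substitution fires.
CWS_POPULATION_THRESHOLD = 25

#: Persons assumed per service connection when SDWIS population is missing.
PERSONS_PER_CONNECTION = 3

RACE_COUNT_COLUMNS = ("latinx", "nl_white", "nl_black", "nl_asian", "nl_native", "nl_other")
POC_COUNT_COLUMNS = ("nl_black", "nl_asian", "nl_native", "nl_other")


def estimate_population(
    areas: pd.DataFrame,
    population_grid: pd.DataFrame,
    admin: pd.DataFrame,
    domestic_wells: pd.DataFrame | None = None,
    threshold: int = CWS_POPULATION_THRESHOLD,
    persons_per_connection: float = PERSONS_PER_CONNECTION,
) -> pd.DataFrame:
    """Tiered service-population estimate per system.

    Parameters
    ----------
    areas
        Resolved (disjoint) service areas: ``system_id``, ``geometry``.
    population_grid
        Grid-cell centroids with counts: columns ``x``, ``y``, ``population``.
    admin
        Administrative records: ``system_id``, ``sdwis_population`` (nullable)
        and ``service_connections``.
    domestic_wells
        Optional point table ``x``, ``y``, ``persons``; persons at wells
        inside a boundary are subtracted from its estimate.

    Returns
    -------
    DataFrame ``system_id``, ``population_served``, ``tier`` where tier is
    1 (grid sum), 2 (SDWIS substitution) or 3 (connection count).
    """
    area_geoms = geometry_array(areas)
    pts = shapely.points(np.c_[population_grid["x"].to_numpy(),
                               population_grid["y"].to_numpy()])
    counts = population_grid["population"].to_numpy(dtype=float)
    tree = STRtree(pts)
    grid_sum = np.zeros(len(areas))
    qa, qp = tree.query(area_geoms, predicate="contains")
    np.add.at(grid_sum, qa, counts[qp])

    admin_idx = admin.set_index("system_id")
    dom_sub = np.zeros(len(areas))
    if domestic_wells is not None and len(domestic_wells):
        dpts = shapely.points(np.c_[domestic_wells["x"].to_numpy(),
                                    domestic_wells["y"].to_numpy()])
        dpersons = domestic_wells["persons"].to_numpy(dtype=float)
        dtree = STRtree(dpts)
        qa, qd = dtree.query(area_geoms, predicate="contains")
        np.add.at(dom_sub, qa, dpersons[qd])

    rows = []
    for i, system_id in enumerate(areas["system_id"]):
        pop = grid_sum[i]
        tier = 1
        if pop < threshold:
            rec = admin_idx.loc[system_id] if system_id in admin_idx.index else None
            sdwis = None if rec is None else rec["sdwis_population"]
            if sdwis is not None and not pd.isna(sdwis):
                pop, tier = float(sdwis), 2
            elif rec is not None and not pd.isna(rec["service_connections"]):
                pop, tier = persons_per_connection * float(rec["service_connections"]), 3
            else:
                warnings.warn(
                    f"system {system_id}: no grid coverage and no administrative "
                    "record; population set to 0", stacklevel=2)
                pop, tier = 0.0, 1
        pop = max(pop - dom_sub[i], 0.0)
        rows.append({"system_id": system_id, "population_served": pop, "tier": tier})
    return pd.DataFrame(rows)


def apportionment_weights(
    areas: pd.DataFrame,
    block_groups: pd.DataFrame,
) -> pd.DataFrame:
    """Long table of areal-apportionment weights w = area(bg ∩ system)/area(bg).

    For each block group the weights over all systems plus the uncovered
    remainder sum to 1 (systems are disjoint after overlap resolution).
    """
    bg_geoms = geometry_array(block_groups)
    bg_area = shapely.area(bg_geoms)
    if (bg_area <= 0).any():
        bad = block_groups.loc[bg_area <= 0, "bg_id"].tolist()[:5]
        raise ValueError(f"zero-area block groups: {bad}")
    sys_geoms = geometry_array(areas)
    tree = STRtree(bg_geoms)
    qs, qb = tree.query(sys_geoms, predicate="intersects")
    weight = np.zeros(len(qs))
    if len(qs):
        inter = shapely.intersection(sys_geoms[qs], bg_geoms[qb])
        weight = shapely.area(inter) / bg_area[qb]
    out = pd.DataFrame({
        "system_id": areas["system_id"].to_numpy()[qs],
        "bg_id": block_groups["bg_id"].to_numpy()[qb],
        "weight": weight,
    })
    return out[out["weight"] > 0].reset_index(drop=True)


def apportion(
    areas: pd.DataFrame,
    block_groups: pd.DataFrame,
    poverty_denominator: str = "households",
) -> pd.DataFrame:
    """Apportion block-group counts to systems and recompute percentages.

    Parameters
    ----------
    areas
        Resolved service areas (disjoint polygons).
    block_groups
        Geotable with ``bg_id``, ``geometry``, ``total_pop``, the race counts
        ``latinx``/``nl_white``/``nl_black``/``nl_asian``/``nl_native``/
        ``nl_other``, ``households_total``, ``households_rented``,
        ``households_poverty`` and (optionally) ``persons_poverty``.
    poverty_denominator
        ``"households"`` (default; households under 2x the federal poverty
        level over total households) or ``"persons"`` (requires the
        ``persons_poverty`` column).

    Returns
    -------
    One row per system with apportioned counts plus ``pct_latinx``,
    ``pct_nl_white``, ``pct_nl_poc``, ``pct_poverty`` and ``pct_rented``
    (percentages in [0, 100]; NaN where a denominator apportions to zero).
    """
    if poverty_denominator not in ("households", "persons"):
        raise ValueError(f"poverty_denominator must be 'households' or 'persons', "
                         f"got {poverty_denominator!r}")
    count_cols = ["total_pop", *RACE_COUNT_COLUMNS,
                  "households_total", "households_rented", "households_poverty"]
    if poverty_denominator == "persons":
        if "persons_poverty" not in block_groups.columns:
            raise ValueError("persons_poverty column required for poverty_denominator='persons'")
        count_cols.append("persons_poverty")

    weights = apportionment_weights(areas, block_groups)
    bg = block_groups.set_index("bg_id")
    merged = weights.merge(bg[count_cols], left_on="bg_id", right_index=True)
    for col in count_cols:
        merged[col] = merged[col] * merged["weight"]
    agg = merged.groupby("system_id", sort=False)[count_cols].sum()
    agg = agg.reindex(areas["system_id"]).fillna(0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        pop = agg["total_pop"].to_numpy()
        hh = agg["households_total"].to_numpy()
        pct = pd.DataFrame(index=agg.index)
        pct["pct_latinx"] = 100 * agg["latinx"] / pop
        pct["pct_nl_white"] = 100 * agg["nl_white"] / pop
        pct["pct_nl_poc"] = 100 * agg[list(POC_COUNT_COLUMNS)].sum(axis=1) / pop
        for col in POC_COUNT_COLUMNS:
            pct[f"pct_{col}"] = 100 * agg[col] / pop
        if poverty_denominator == "households":
            pct["pct_poverty"] = 100 * agg["households_poverty"] / hh
        else:
            pct["pct_poverty"] = 100 * agg["persons_poverty"] / pop
        pct["pct_rented"] = 100 * agg["households_rented"] / hh

    out = pd.concat([agg, pct], axis=1).reset_index()
    return out


def population_density(
    areas: pd.DataFrame,
    population_served: pd.Series | dict,
) -> pd.Series:
    """People per 100 m² of service area: population / (area_m2 / 100)."""
    area_m2 = shapely.area(geometry_array(areas))
    if (area_m2 <= 0).any():
        bad = areas.loc[area_m2 <= 0, "system_id"].tolist()[:5]
        raise ValueError(f"zero-area service areas: {bad}")
    pop = pd.Series(population_served)
    pop = pop.reindex(areas["system_id"]).to_numpy(dtype=float)
    return pd.Series(pop / (area_m2 / 100.0),
                     index=pd.Index(areas["system_id"], name="system_id"),
                     name="pop_density")
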