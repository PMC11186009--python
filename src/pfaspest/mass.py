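"""Convert pesticide-product applications (lbs) into per-section PFAS mass (mg).

California's Pesticide Use Reporting program records pounds of formulated
product applied per PLSS section (~1 square mile).  Laboratory studies report
PFAS analyte concentrations in those products in ng per litre of formulation.
The mass of analyte ``a`` applied in a section over the study period is

    W_mg = sum_products  X_ngL * (Z_lbs / Y_lbs_per_gal) * 3.785411784 L/gal * 1e-6 mg/ng

where ``X`` is the analyte concentration in the product (ng/L), ``Y`` the
product density (lbs/gal) and ``Z`` the cumulative pounds of product applied
in the section across the study years.  ``Z/Y`` is the applied volume in
gallons; the gallon-to-litre constant is the US liquid gallon.

The analytes tracked are PFBS, PFBA, PFOS, PFHpS, PFOA and HFPO-DA; in the
Californian record only the first three appear in applied products.  "Total
PFAS" is the per-section sum over a configurable analyte set (default: all
present), with an ``exclude`` option used by the PFOS-exclusion sensitivity
analysis.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

#: US liquid gallon in litres; fixes the unit chain of the mass formula.
LITERS_PER_GALLON = 3.785411784

#: ng -> mg
MG_PER_NG = 1e-6

#: PFAS analytes with reported concentrations in pesticide products.
KNOWN_ANALYTES = frozenset(
    {"PFBS", "PFBA", "PFOS", "PFHpS", "PFOA", "HFPO-DA"}
)

#: Name of the derived per-section sum column/pseudo-analyte.
TOTAL_PFAS = "total_pfas"


@dataclass(frozen=True)
class PfasProduct:
    """A pesticide product with measured PFAS contamination.

    Parameters
    ----------
    product_id
        Label, e.g. a registered brand name.
    concentrations
        Analyte -> concentration in ng of analyte per litre of formulated
        product (``X`` in the mass formula).
    density_lbs_per_gal
        Product density ``Y`` in lbs per US gallon; must be positive.
    """

    product_id: str
    concentrations: Mapping[str, float] = field(default_factory=dict)
    density_lbs_per_gal: float = 8.34

    def __post_init__(self) -> None:
        if not self.density_lbs_per_gal > 0:
            raise ValueError(
                f"product {self.product_id!r}: density must be > 0 lbs/gal, "
                f"got {self.density_lbs_per_gal}"
            )
        for analyte, conc in self.concentrations.items():
            if analyte not in KNOWN_ANALYTES:
                raise ValueError(
                    f"product {self.product_id!r}: unknown analyte {analyte!r}; "
                    f"expected one of {sorted(KNOWN_ANALYTES)}"
                )
            if conc < 0:
                raise ValueError(
                    f"product {self.product_id!r}: negative concentration for {analyte}"
                )


def products_from_frame(frame: pd.DataFrame) -> dict[str, PfasProduct]:
    """Build a product map from a long table (product_id, analyte, ng_per_L, lbs_per_gal)."""
    products: dict[str, PfasProduct] = {}
    for product_id, group in frame.groupby("product_id", sort=True):
        densities = group["lbs_per_gal"].unique()
        if len(densities) != 1:
            raise ValueError(f"product {product_id!r}: inconsistent densities {densities}")
        conc = dict(zip(group["analyte"], group["ng_per_L"].astype(float)))
        products[str(product_id)] = PfasProduct(
            product_id=str(product_id),
            concentrations=conc,
            density_lbs_per_gal=float(densities[0]),
        )
    return products


def products_to_frame(products: Mapping[str, PfasProduct]) -> pd.DataFrame:
    """Inverse of :func:`products_from_frame`."""
    rows = [
        {"product_id": p.product_id, "analyte": analyte,
         "ng_per_L": x, "lbs_per_gal": p.density_lbs_per_gal}
        for p in products.values()
        for analyte, x in sorted(p.concentrations.items())
    ]
    return pd.DataFrame(rows, columns=["product_id", "analyte", "ng_per_L", "lbs_per_gal"])


def compute_section_mass(
    applications: pd.DataFrame,
    products: Mapping[str, PfasProduct],
    period: Iterable[int] = range(2019, 2022),
    keep_zero_sections: bool = False,
) -> pd.DataFrame:
    """Per-section, per-analyte PFAS mass in mg over a study period.

    Parameters
    ----------
    applications
        Columns ``section_id``, ``product_id``, ``year``, ``pounds_applied``.
        Pounds are summed across all years inside ``period`` (cumulative-sum
        convention of the source reporting program).
    products
        product_id -> :class:`PfasProduct`.  Every referenced product must be
        present; an unknown product is a hard error, as is a non-positive
        density.
    period
        Years included in the cumulative sum (default 2019-2021).
    keep_zero_sections
        If True, emit explicit zero-mass rows for sections whose applications
        are entirely zero; otherwise such rows are dropped.

    Returns
    -------
    DataFrame with columns ``section_id``, ``analyte``, ``mass_mg``, sorted by
    (section_id, analyte).  Analytes absent from every product yield no rows.
    """
    required = {"section_id", "product_id", "year", "pounds_applied"}
    missing = required - set(applications.columns)
    if missing:
        raise ValueError(f"applications table missing columns: {sorted(missing)}")
    years = set(int(y) for y in period)
    if not years:
        raise ValueError("empty study period")
    if (applications["pounds_applied"] < 0).any():
        raise ValueError("negative pounds_applied")

    unknown = set(applications["product_id"].unique()) - set(products)
    if unknown:
        raise KeyError(f"applications reference unknown products: {sorted(unknown)}")

    inside = applications[applications["year"].astype(int).isin(years)]
    if inside.empty:
        return pd.DataFrame(columns=["section_id", "analyte", "mass_mg"])

    # cumulative Z per (section, product) across the period
    z = (
        inside.groupby(["section_id", "product_id"], sort=True)["pounds_applied"]
        .sum()
        .reset_index()
    )

    # per-product mg of analyte per lb of product: X * (1/Y) * L/gal * mg/ng
    conv_rows = [
        {"product_id": pid, "analyte": analyte,
         "mg_per_lb": x / p.density_lbs_per_gal * LITERS_PER_GALLON * MG_PER_NG}
        for pid, p in products.items()
        for analyte, x in p.concentrations.items()
    ]
    conv = pd.DataFrame(conv_rows, columns=["product_id", "analyte", "mg_per_lb"])

    merged = z.merge(conv, on="product_id", how="inner")
    merged["mass_mg"] = merged["pounds_applied"] * merged["mg_per_lb"]
    out = (
        merged.groupby(["section_id", "analyte"], sort=True)["mass_mg"]
        .sum()
        .reset_index()
    )
    if not keep_zero_sections:
        nonzero_sections = set(out.loc[out["mass_mg"] > 0, "section_id"])
        out = out[out["section_id"].isin(nonzero_sections)].reset_index(drop=True)
    return out


def total_pfas(
    masses: pd.DataFrame,
    exclude: Iterable[str] = (),
    include: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-section total-PFAS mass: the sum over an analyte set.

    By default every analyte present is summed (in the Californian record that
    is PFBS + PFBA + PFOS).  ``exclude={"PFOS"}`` reproduces the sensitivity
    exposure in which only PFBA + PFBS are retained.  ``include`` restricts the
    sum to a whitelist before exclusions are applied.
    """
    exclude = set(exclude)
    kept = masses[~masses["analyte"].isin(exclude)]
    if include is not None:
        kept = kept[kept["analyte"].isin(set(include))]
    out = kept.groupby("section_id", sort=True)["mass_mg"].sum().reset_index()
    out.insert(1, "analyte", TOTAL_PFAS)
    return out
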