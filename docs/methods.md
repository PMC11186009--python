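# Methods

## Problem and pipeline

`pfaspest` estimates the potential threat that PFAS-contaminated pesticide
applications pose to community water systems (CWSs) that rely on groundwater,
and tests whether that burden is unevenly distributed across community
sociodemographics.  The pipeline has five stages:

1. **Mass conversion.**  Pesticide-use records report pounds of formulated
   product applied per reporting section (~1 square mile).  Laboratory
   analyses report PFAS analyte concentrations (ng per litre of formulation)
   and product density (lbs per gallon).  The applied analyte mass is

   `W_mg = X_ng/L × (Z_lbs / Y_lbs/gal) × 3.785411784 L/gal × 10⁻⁶ mg/ng`,

   with pounds summed across the study years (2019–2021 by default).  The
   gallon constant is the US liquid gallon; pounds enter only through the
   volume ratio `Z/Y`, so no pound-to-gram conversion arises.  Concentrations
   are treated as constant over the study period.  Tracked analytes are PFOS,
   PFBS, PFBA (plus PFHpS, PFOA, HFPO-DA, which never appear in applied
   products here); "total PFAS" is their per-section sum.

2. **Exposure.**  Each system's impact zone is the union of 1-km disks around
   its public supply wells (64-segment arcs; the inscribed-polygon area
   deficit is ~0.16%, well below the 1% geometric tolerance used in
   verification).  Section mass is assumed uniformly spread within its
   section, so the mass assigned to a buffer is the area-weighted sum
   `Σ mass(section) × area(section ∩ buffer) / area(section)`, and the
   exposure metric is that mass divided by the *buffer* area (mg/km²), not
   the service-area area.  Buffers of different systems may overlap the same
   section; exposure deliberately double-counts shared mass rather than
   partitioning it.  Service-area polygons are preprocessed with the state
   boundary-data rule: regions claimed by several systems go to the system
   with the smallest pre-resolution area.

3. **Demographics.**  Service population uses a tiered fallback: the sum of
   gridded residential population (cells assigned by centroid containment —
   cells are small relative to systems, so area-weighting cells would change
   estimates negligibly); below 25 persons the administrative (SDWIS-style)
   population substitutes; if that is missing, 3 persons per service
   connection; finally persons attributed to domestic wells inside the
   boundary are subtracted, flooring at zero.  Block-group counts are
   assigned to systems by areal apportionment (weight = intersected share of
   the block-group area) and percentages recomputed from apportioned
   numerators and denominators.  Poverty (< 2× the federal poverty level) is
   measured at the household level by default; a person-level denominator is
   available because the source tables are ambiguous on this point.

4. **Inference.**  A two-part GAM: a binomial-logit part for "any PFAS within
   1 km" over all systems (adjusted for the number of supply wells as a
   buffer-size proxy) and a Gaussian-identity part for ln(density) over
   positive systems.  Composition predictors (% Latinx, % non-Latinx POC,
   % poverty, % rented; non-Latinx White is the reference) are divided by 10,
   so exp(β) is a geometric mean ratio or odds ratio per 10-percentage-point
   increase; 95% CIs are Wald on the link scale, exponentiated.  Penalized
   cubic B-spline smooths (df 10 each) of population density (people/100 m²)
   and of the service-area centroid latitude and longitude absorb size and
   spatial confounding.  Residual spatial autocorrelation is screened with
   Moran's I on row-standardized 8-nearest-neighbour weights (999
   permutations, one-sided against positive autocorrelation, with a
   normal-approximation p as cross-check; under the null E[I] = −1/(n−1)).
   A sensitivity analysis excludes PFOS and retains PFBA+PFBS; when that
   exposure is identically zero the refit is skipped with a diagnostic.

5. **Reporting.**  Regional descriptives: population-weighted composition
   percentages (denominator: regional population served), unweighted mean
   % rented across systems, unweighted mean densities; presentation rounding
   is one decimal with scientific notation below 10⁻², while machine outputs
   keep full precision.

## Numerical choices

- **Smoothing penalty.**  statsmodels' raw cubic-B-spline curvature penalty
  scales with the covariate's units, so penalty weights are normalized by
  `n / trace(S)` per smooth, making `alpha` unitless.  The default is
  `alpha = 0.1` (light).  A calibration study (100 synthetic replicates at
  n = 2,444) showed that heavier fixed penalties shrink the spatial smooths
  and — because the composition predictors are themselves spatially smooth —
  transfer part of the spatial signal into the linear coefficients,
  understating their Wald SEs by ~9% and dropping logistic CI coverage to
  89%; at `alpha = 0.1` the z-scores are calibrated (sd ≈ 1.04) and coverage
  is 93–96%.  Data-driven selection (`penalty="gcv"` via generalized
  cross-validation) is available but costs ~10 s per fit, so it is not the
  default.
- **Spatial basis.**  Latitude and longitude enter as two separate univariate
  smooths by default; a low-rank tensor-product surface is available
  (`spatial_smooth="bivariate"`).
- **Degenerate inputs.**  Zero-area sections, block groups or service areas
  are hard errors; fewer than 30 positive systems skips the Gaussian part
  with a diagnostic; a single-class any-PFAS outcome skips the logistic
  part; complete separation and rank deficiency raise errors naming the
  offending terms.  Overlap-rule ties (equal areas) break deterministically
  by system id.
- **Moran residuals.**  Deviance residuals by default; response residuals are
  available (the two coincide for the Gaussian part).

## The synthetic landscape

No statewide input datasets are redistributable, so the generator builds a
self-consistent study region with known ground truth, at the real study's
scale by default: 2,444 systems, ~2.9 wells each, 1609.34-m sections tiling
the region, 3,000 block groups, a 28.4-million-person gridded population
(1-km cells; the real gridded product is far finer, but only the sums over
service areas matter here), administrative records with ~2% missing
population counts, and domestic-well points.

Key constructions:

- **Geometry.**  Planar metres throughout; "latitude/longitude" are affine
  rescalings of the planar coordinates, which is all the spline terms need.
  System seed points sit on a jittered lattice (spacing 5.5 km) rather than
  a uniform Poisson scatter so that each system's dissolved well buffer — and
  every section it touches — stays inside the system's own Voronoi
  neighbourhood.  Service areas are Voronoi cells clipped to the region
  (optionally inflated to induce overlaps and exercise the smaller-system
  rule).  Real CWS geographies are irregular; the lattice is a deliberate
  idealization that buys an exact ground truth (below).
- **Demographic fields.**  Gaussian-kernel-smoothed lattice noise
  (correlation length ≈ 40 km) drives block-group % Latinx (logistic
  transform around 36.5%), the non-Latinx White share of the remainder,
  poverty and tenure (correlated 0.5 / 0.3 with the Latinx field), and the
  population surface.  Counts use largest-remainder rounding so race counts
  sum exactly to block-group population and the grid sums exactly to the
  configured regional population.
- **Exact two-part truth.**  Each system's apportioned covariates are
  computed first (with the package's own apportionment code); the any-PFAS
  indicator is drawn from a logistic model (OR 1.60 per 10 points % Latinx,
  OR 1.07 per well, a low-frequency additive spatial trend, intercept
  calibrated by root-finding so the marginal zero fraction is 70%, echoing
  the 1,712 / 732 split), and positive systems draw
  ln(density) = intercept + ln(1.27)·latinx10 + smooth terms + N(0, 2.5²).
  Section masses are then constructed by *inverting* the allocation: every
  section a positive system's buffer touches gets that system's density
  times the section area.  Because sections tile the plane and buffers stay
  within their own neighbourhood, the downstream area-weighted allocation
  returns each generating density to ~1e-14 relative error, and the
  generating coefficients are the exact estimands of the downstream fit.
  Product pounds per section-year are recovered by inverting the mass
  formula for a PFOS-dominant product (99.9803% of mass) and a PFBS/PFBA
  product with a fixed 32.7 : 10.4 concentration ratio, so the sensitivity
  exposure is proportional to the main one.  Away from any buffer,
  zero-inflated, spatially clustered background applications fill the region
  at the configured zero fraction.
- **Spatial trends are additive** (sinusoids in x plus y), so the default
  additive spline basis can represent them; the spatial-confounding
  experiment injects a strong trend (amplitude 3.0 vs noise sd 1.5) and
  checks that Moran's I flags residuals only when the coordinate smooths are
  dropped.

**What the generator does not emulate:** real geographic irregularity
(coastlines, sprawling rural systems), ACS margins of error, survey
measurement error in the covariates, non-proportional analyte mixes across
products, and spatial correlation in the *noise* of the density model.
Passing tests therefore demonstrate that the pipeline's algebra, geometry and
estimation are correct and calibrated under the stated data-generating
model — not that the substantive disparity findings would replicate on the
real records.

## Problem sizes used in verification

Unit and property tests run on 150-system landscapes; the parameter-recovery
study uses 100 replicates at the full 2,444-system scale; the geometric
oracle uses 50 five-system landscapes checked against a 10-m grid-sampling
oracle (agreement within 1%; observed ≲0.05%); the spatial-confounding
experiment uses 600 systems.  `scripts/acceptance.py` performs one full
study-scale run plus the oracle re-derivations and finishes in well under a
minute on one CPU.

## Known limitations

- The exposure metric is proximity-based; no hydrogeological transport,
  capture zones or decay.  Watershed-scale buffers used elsewhere in the
  literature would enlarge the exposed universe.
- Wald CIs ignore smoothing-parameter uncertainty; with the light default
  penalty this is small (see the calibration study) but not zero.
- The overlap-resolution rule assigns contested area wholesale to the
  smaller system; no population re-weighting of contested slivers.
- `estimate_population` trusts the administrative population when the grid
  sum is below 25 even when both are poor; no reconciliation beyond the
  tier order.
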