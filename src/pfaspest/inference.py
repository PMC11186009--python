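"""Two-part generalized additive model of PFAS burden vs. sociodemographics.

The outcome — areal PFAS density within 1 km of a system's supply wells — is
zero for most systems and continuous-positive otherwise, so it is modelled in
two parts:

* a **logistic part** over all systems for the binary "any PFAS applied"
  outcome (binomial family, logit link); exponentiated coefficients are odds
  ratios (OR).  It adjusts for the number of supply wells, a proxy for buffer
  size.
* a **Gaussian part** over positive systems only, for the natural log of the
  density (identity link); exponentiated coefficients are geometric mean
  ratios (GMR).  The wells term is omitted here because the outcome is
  already an areal density.

Percent composition predictors (% Latinx, % non-Latinx POC, % poverty,
% rented; non-Latinx White is the omitted reference) are divided by 10, so
each ratio is per 10-percentage-point increase.  Penalized cubic B-spline
smooths of population density and of the service-area centroid latitude and
longitude absorb system-size and spatial confounding; residual spatial
autocorrelation is checked with Moran's I on k-nearest-neighbour weights.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``); module-level helpers mirror the individual pipeline steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator
from statsmodels.gam.api import BSplines, GLMGam

DEFAULT_LINEAR_TERMS = ("pct_latinx", "pct_nl_poc", "pct_poverty", "pct_rented")
DEFAULT_SMOOTH_TERMS = ("pop_density", "centroid_lat", "centroid_lon")

#: systems below this count in the positive subset cannot support the
#: Gaussian part; the fit is skipped with a diagnostic.
MIN_POSITIVE_N = 30


class TwoPartFitError(RuntimeError):
    """Raised for rank deficiency, separation or other fit failures."""


@dataclass
class MoranResult:
    """Moran's I statistic with permutation and analytic p-values."""

    statistic: float
    expected: float
    p_permutation: float
    p_analytic: float
    n: int
    permutations: int
    applicable: bool = True
    note: str = ""


@dataclass
class PartFit:
    """One part (Gaussian or logistic) of a two-part fit."""

    kind: str                      # "gaussian" | "logistic"
    result: object                 # statsmodels results object
    terms: list
    summary: pd.DataFrame          # estimate/SE/CI/ratio per linear term
    n: int
    aic: float
    log_likelihood: float
    residuals: np.ndarray
    coords: np.ndarray
    morans: MoranResult | None = None
    smoother: object | None = None
    linear_terms: tuple = ()
    smooth_cols: tuple = ()
    exog_columns: tuple = ()

    def linear_predictor(self, X: pd.DataFrame, scale_divisor: float = 10.0) -> np.ndarray:
        """Evaluate eta on new data using the training spline basis."""
        cols = [np.ones(len(X))]
        for term in self.linear_terms:
            v = X[term].to_numpy(dtype=float)
            if term.startswith("pct_"):
                v = v / scale_divisor
            cols.append(v)
        mats = [np.column_stack(cols)]
        if self.smoother is not None:
            mats.append(self.smoother.transform(
                X[list(self.smooth_cols)].to_numpy(dtype=float)))
        return np.hstack(mats) @ np.asarray(self.result.params, dtype=float)


@dataclass
class TwoPartResult:
    """Container mirroring a published two-part model table."""

    gaussian: PartFit | None
    logistic: PartFit | None
    n_total: int
    n_positive: int
    n_zero: int
    skipped: dict = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        frames = []
        for part in (self.gaussian, self.logistic):
            if part is not None:
                frames.append(part.summary.assign(part=part.kind))
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


def split_two_part(exposures: pd.DataFrame,
                   density_column: str = "density_mg_per_km2"):
    """Partition systems into the positive-density subset and the full set.

    Returns ``(positive, full)`` where ``full`` carries a boolean ``any_pfas``
    column (recomputed as density > 0).  The subsets are disjoint and their
    union is the input.
    """
    full = exposures.copy()
    full["any_pfas"] = full[density_column].to_numpy() > 0
    positive = full[full["any_pfas"]].copy()
    return positive, full


def _knn_weights(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized k-nearest-neighbour weights as (neighbour index, weight)."""
    n = len(coords)
    if n <= k:
        raise ValueError(f"need more than k={k} observations, got {n}")
    _, idx = cKDTree(coords).query(coords, k=k + 1)
    neigh = idx[:, 1:]  # drop self
    w = np.full(neigh.shape, 1.0 / k)
    return neigh, w


def morans_i(
    residuals: np.ndarray,
    coords: np.ndarray,
    k: int = 8,
    permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with row-standardized KNN weights.

    The permutation p-value is one-sided against positive autocorrelation
    (the alternative of interest when screening regression residuals for
    un-modelled spatial structure); the analytic p uses the normal
    approximation under the randomization assumption, also one-sided.
    Under the null E[I] = -1/(n-1).
    """
    z = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError(f"Moran's I needs >= 10 observations, got {n}")
    if np.ptp(z) == 0:
        return MoranResult(np.nan, -1.0 / (n - 1), np.nan, np.nan, n,
                           permutations, applicable=False,
                           note="all residuals identical")
    zc = z - z.mean()
    neigh, w = _knn_weights(coords, k)
    s0 = w.sum()

    def stat(v):
        lag = (w * v[neigh]).sum(axis=1)
        return (n / s0) * (v @ lag) / (v @ v)

    i_obs = stat(zc)
    e_i = -1.0 / (n - 1)

    # analytic variance under randomization (standard closed form)
    wi_in = np.zeros(n)  # column sums of W
    np.add.at(wi_in, neigh.ravel(), w.ravel())
    wi_out = w.sum(axis=1)  # row sums (=1)
    # S1 = 1/2 sum_{i!=j} (w_ij + w_ji)^2; each unordered pair appears twice
    pair: dict[tuple[int, int], float] = {}
    for i in range(n):
        for jj in range(neigh.shape[1]):
            j = neigh[i, jj]
            key = (i, j) if i < j else (j, i)
            pair[key] = pair.get(key, 0.0) + w[i, jj]
    s1 = sum(v * v for v in pair.values())
    s2 = ((wi_in + wi_out) ** 2).sum()
    m2 = (zc ** 2).sum() / n
    m4 = (zc ** 4).sum() / n
    b2 = m4 / m2 ** 2
    a = n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
    b = b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2)
    c = (n - 1) * (n - 2) * (n - 3) * s0 ** 2
    var_i = (a - b) / c - e_i ** 2
    zscore = (i_obs - e_i) / np.sqrt(max(var_i, 1e-300))
    p_analytic = float(stats.norm.sf(zscore))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        if stat(rng.permutation(zc)) >= i_obs:
            count += 1
    p_perm = (count + 1) / (permutations + 1)
    return MoranResult(float(i_obs), float(e_i), float(p_perm), p_analytic,
                       n, permutations)


def _tensor_basis(a: np.ndarray, b: np.ndarray, df: int = 5) -> np.ndarray:
    """Low-rank tensor-product cubic B-spline basis for a bivariate surface."""
    from statsmodels.gam.smooth_basis import BSplines as _BS
    ba = _BS(a.reshape(-1, 1), df=[df], degree=[3]).basis
    bb = _BS(b.reshape(-1, 1), df=[df], degree=[3]).basis
    return np.einsum("ij,ik->ijk", ba, bb).reshape(len(a), -1)


def _build_design(X: pd.DataFrame, linear_terms, smooth_terms, scale_divisor,
                  spatial_smooth, spline_df, spline_degree):
    """(exog DataFrame, smoother or None, smooth-term list) for a part."""
    lin = pd.DataFrame(index=X.index)
    for term in linear_terms:
        col = X[term].to_numpy(dtype=float)
        if term.startswith("pct_"):
            col = col / scale_divisor
        lin[term] = col
    exog = sm.add_constant(lin, has_constant="add")

    smooth_cols = list(smooth_terms)
    if spatial_smooth == "bivariate":
        spatial = [t for t in smooth_cols if t in ("centroid_lat", "centroid_lon")]
        smooth_cols = [t for t in smooth_cols if t not in spatial]
        if len(spatial) == 2:
            tb = _tensor_basis(X[spatial[0]].to_numpy(dtype=float),
                               X[spatial[1]].to_numpy(dtype=float))
            for j in range(tb.shape[1]):
                exog[f"space_tp_{j}"] = tb[:, j]
    smoother = None
    if smooth_cols:
        mat = X[smooth_cols].to_numpy(dtype=float)
        smoother = BSplines(mat, df=[spline_df] * len(smooth_cols),
                            degree=[spline_degree] * len(smooth_cols))
    return exog, smoother, smooth_cols


def _check_rank(exog: pd.DataFrame) -> None:
    mat = exog.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        corr = np.corrcoef(mat[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        cols = list(exog.columns[1:])
        raise TwoPartFitError(
            f"design matrix rank deficient ({rank} < {mat.shape[1]}); most "
            f"collinear terms: {cols[i]!r} and {cols[j]!r}")


def _fit_part(kind, y, X, linear_terms, smooth_terms, scale_divisor,
              spatial_smooth, spline_df, spline_degree, alpha, penalty,
              maxiter=100):
    exog, smoother, smooth_cols = _build_design(
        X, linear_terms, smooth_terms, scale_divisor,
        spatial_smooth, spline_df, spline_degree)
    _check_rank(exog)
    family = sm.families.Gaussian() if kind == "gaussian" else sm.families.Binomial()
    alphas = list(np.broadcast_to(alpha, len(smooth_cols))) if smooth_cols else []
    if smoother is not None:
        # normalize the curvature penalty per smooth so `alpha` is unitless:
        # raw penalty magnitudes scale with the covariate's inverse cube range
        for j, pmat in enumerate(smoother.penalty_matrices):
            tr = float(np.trace(pmat))
            if tr > 0:
                alphas[j] = alphas[j] * len(y) / tr
        model = GLMGam(np.asarray(y, dtype=float), exog, smoother=smoother,
                       alpha=alphas, family=family)
    else:
        model = sm.GLM(np.asarray(y, dtype=float), exog, family=family)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(maxiter=maxiter)
            if penalty == "gcv" and smoother is not None:
                alphas = model.select_penweight()[0]
                model = GLMGam(np.asarray(y, dtype=float), exog, smoother=smoother,
                               alpha=list(alphas), family=family)
                result = model.fit(maxiter=maxiter)
    except PerfectSeparationError as exc:
        raise TwoPartFitError(
            f"{kind} part: complete separation — the outcome is perfectly "
            f"predicted by the covariates ({exc})") from exc

    params = np.asarray(result.params, dtype=float)
    if kind == "logistic" and np.abs(params[:exog.shape[1]]).max() > 30:
        raise TwoPartFitError(
            "logistic part: coefficient magnitudes suggest complete "
            "separation; check the any-PFAS outcome against the predictors")

    names = list(exog.columns)
    ratio_label = "GMR" if kind == "gaussian" else "OR"
    rows = []
    for term in linear_terms:
        j = names.index(term)
        est, se = params[j], float(np.asarray(result.bse)[j])
        lo, hi = est - 1.96 * se, est + 1.96 * se
        rows.append({
            "term": term, "estimate": est, "se": se,
            "ci_low": lo, "ci_high": hi,
            "ratio_type": ratio_label,
            "ratio": float(np.exp(est)),
            "ratio_ci_low": float(np.exp(lo)),
            "ratio_ci_high": float(np.exp(hi)),
        })
    summary = pd.DataFrame(rows)

    if kind == "gaussian":
        resid = np.asarray(y, dtype=float) - np.asarray(result.fittedvalues)
        resid_dev = resid
    else:
        mu = np.asarray(result.fittedvalues)
        resid = np.asarray(y, dtype=float) - mu
        with np.errstate(divide="ignore", invalid="ignore"):
            yv = np.asarray(y, dtype=float)
            dev = 2 * (np.where(yv > 0, np.log(1 / np.clip(mu, 1e-12, None)), 0)
                       + np.where(yv < 1, np.log(1 / np.clip(1 - mu, 1e-12, None)), 0))
        resid_dev = np.sign(resid) * np.sqrt(np.clip(dev, 0, None))

    coords = X[["centroid_lon", "centroid_lat"]].to_numpy(dtype=float) \
        if {"centroid_lat", "centroid_lon"} <= set(X.columns) else None
    return PartFit(
        kind=kind, result=result, terms=list(linear_terms) + smooth_cols,
        summary=summary, n=len(y), aic=float(result.aic),
        log_likelihood=float(result.llf),
        residuals=resid_dev, coords=coords,
        smoother=smoother, linear_terms=tuple(linear_terms),
        smooth_cols=tuple(smooth_cols), exog_columns=tuple(names),
    ), resid


class TwoPartGAM(BaseEstimator):
    """Two-part penalized-spline GAM for zero-inflated areal PFAS density.

    Parameters
    ----------
    linear_terms : tuple of str
        Percent-composition predictors; any column starting with ``pct_`` is
        divided by ``scale_divisor`` so ratios are per 10-point increase.
    smooth_terms : tuple of str
        Columns receiving penalized cubic B-spline smooths.
    wells_term : str or None
        Extra linear term for the logistic part only (proxy for buffer size).
    spline_df, spline_degree : int
        Basis dimension and degree per smooth.
    alpha : float
        Penalty weight per smooth when ``penalty="fixed"`` (unitless; the raw
        curvature penalty is normalized by its trace).  The default is light:
        heavier fixed penalties shrink the spatial smooths and, through
        concurvity with spatially structured composition predictors, bias the
        linear coefficients and understate their Wald uncertainty.
    penalty : {"fixed", "gcv"}
        ``"gcv"`` re-selects penalty weights by generalized cross-validation
        (slower).
    spatial_smooth : {"additive", "bivariate"}
        Separate univariate smooths of centroid latitude and longitude
        (default) or a single low-rank tensor-product surface.
    residual_type : {"deviance", "response"}
        Residuals handed to Moran's I.
    morans_k, morans_permutations : int
        KNN weight order and permutation count for the Moran test.
    min_positive : int
        Minimum positive-density systems for the Gaussian part.
    random_state : int or None
        Seed for the Moran permutation test.

    Attributes (after ``fit``)
    --------------------------
    result_ : TwoPartResult
    summary_ : DataFrame of GMR/OR with 95% CIs for both parts
    n_positive_, n_zero_ : int
    morans_i_ : dict part -> MoranResult (when coordinates are available)
    """

    def __init__(self, linear_terms=DEFAULT_LINEAR_TERMS,
                 smooth_terms=DEFAULT_SMOOTH_TERMS, wells_term="n_wells",
                 scale_divisor=10.0, spline_df=10, spline_degree=3,
                 alpha=0.1, penalty="fixed", spatial_smooth="additive",
                 residual_type="deviance", morans_k=8,
                 morans_permutations=999, min_positive=MIN_POSITIVE_N,
                 compute_morans=True, random_state=None):
        self.linear_terms = linear_terms
        self.smooth_terms = smooth_terms
        self.wells_term = wells_term
        self.scale_divisor = scale_divisor
        self.spline_df = spline_df
        self.spline_degree = spline_degree
        self.alpha = alpha
        self.penalty = penalty
        self.spatial_smooth = spatial_smooth
        self.residual_type = residual_type
        self.morans_k = morans_k
        self.morans_permutations = morans_permutations
        self.min_positive = min_positive
        self.compute_morans = compute_morans
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, density_column="density_mg_per_km2"):
        """Fit both parts.

        ``X`` is a joined system-level table (exposure + demographics);
        ``y`` is the areal density vector (zeros included); if omitted, the
        ``density_column`` of ``X`` is used.
        """
        X = pd.DataFrame(X).reset_index(drop=True)
        dens = np.asarray(X[density_column] if y is None else y, dtype=float)
        if len(dens) != len(X):
            raise ValueError("X and y lengths differ")
        any_pfas = dens > 0
        pos = np.flatnonzero(any_pfas)
        skipped: dict[str, str] = {}

        gaussian = None
        if len(pos) >= self.min_positive:
            gaussian, g_resp = _fit_part(
                "gaussian", np.log(dens[pos]), X.iloc[pos],
                self.linear_terms, self.smooth_terms, self.scale_divisor,
                self.spatial_smooth, self.spline_df, self.spline_degree,
                self.alpha, self.penalty)
            if self.residual_type == "response":
                gaussian.residuals = g_resp
        else:
            skipped["gaussian"] = (
                f"only {len(pos)} positive-density systems "
                f"(< {self.min_positive}); Gaussian part skipped")

        logistic = None
        if 0 < any_pfas.sum() < len(dens):
            log_lin = list(self.linear_terms)
            if self.wells_term:
                log_lin = log_lin + [self.wells_term]
            logistic, l_resp = _fit_part(
                "logistic", any_pfas.astype(float), X,
                log_lin, self.smooth_terms, self.scale_divisor,
                self.spatial_smooth, self.spline_df, self.spline_degree,
                self.alpha, self.penalty)
            if self.residual_type == "response":
                logistic.residuals = l_resp
        else:
            skipped["logistic"] = (
                "any-PFAS outcome has a single class; logistic part skipped")

        morans = {}
        if self.compute_morans:
            for part in (gaussian, logistic):
                if part is not None and part.coords is not None and part.n >= 10:
                    part.morans = morans_i(
                        part.residuals, part.coords, k=self.morans_k,
                        permutations=self.morans_permutations,
                        seed=self.random_state)
                    morans[part.kind] = part.morans

        self.result_ = TwoPartResult(
            gaussian=gaussian, logistic=logistic, n_total=len(dens),
            n_positive=int(any_pfas.sum()), n_zero=int((~any_pfas).sum()),
            skipped=skipped)
        self.summary_ = self.result_.summary
        self.n_positive_ = self.result_.n_positive
        self.n_zero_ = self.result_.n_zero
        self.morans_i_ = morans
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted probability of any PFAS application (logistic part)."""
        if self.spatial_smooth == "bivariate":
            raise NotImplementedError("prediction with a bivariate spatial smooth")
        res = self.result_
        if res.logistic is None:
            raise TwoPartFitError("logistic part was not fitted")
        eta = res.logistic.linear_predictor(pd.DataFrame(X).reset_index(drop=True),
                                            self.scale_divisor)
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected density: P(any) * E[density | positive] (log-normal mean)."""
        res = self.result_
        if res.gaussian is None:
            raise TwoPartFitError("Gaussian part was not fitted")
        X = pd.DataFrame(X).reset_index(drop=True)
        p_any = self.predict_proba(X)
        mu_log = res.gaussian.linear_predictor(X, self.scale_divisor)
        scale = float(res.gaussian.result.scale)
        return p_any * np.exp(mu_log + scale / 2.0)


def fit_gaussian_part(positive: pd.DataFrame, outcome="density_mg_per_km2",
                      **params) -> PartFit:
    """Penalized additive fit of ln(density) on the positive subset."""
    est = TwoPartGAM(**params)
    dens = np.asarray(positive[outcome], dtype=float)
    if (dens <= 0).any():
        raise ValueError("Gaussian part requires strictly positive densities")
    if len(dens) < est.min_positive:
        raise ValueError(
            f"need >= {est.min_positive} positive observations, got {len(dens)}")
    part, resp = _fit_part(
        "gaussian", np.log(dens), positive.reset_index(drop=True),
        est.linear_terms, est.smooth_terms, est.scale_divisor,
        est.spatial_smooth, est.spline_df, est.spline_degree,
        est.alpha, est.penalty)
    if est.residual_type == "response":
        part.residuals = resp
    return part


def fit_logistic_part(full: pd.DataFrame, outcome="any_pfas", **params) -> PartFit:
    """Penalized additive logistic fit of the any-PFAS indicator."""
    est = TwoPartGAM(**params)
    y = np.asarray(full[outcome], dtype=float)
    if y.min() == y.max():
        raise ValueError("any-PFAS outcome has a single class")
    lin = list(est.linear_terms) + ([est.wells_term] if est.wells_term else [])
    part, resp = _fit_part(
        "logistic", y, full.reset_index(drop=True),
        lin, est.smooth_terms, est.scale_divisor,
        est.spatial_smooth, est.spline_df, est.spline_degree,
        est.alpha, est.penalty)
    if est.residual_type == "response":
        part.residuals = resp
    return part


def sensitivity_excl_pfos(
    table: pd.DataFrame,
    estimator: TwoPartGAM | None = None,
    pfbs_column="density_PFBS_mg_km2",
    pfba_column="density_PFBA_mg_km2",
) -> TwoPartResult:
    """Refit the two-part model on the PFBA+PFBS exposure (PFOS excluded).

    If the PFBA+PFBS density is identically zero (e.g. only PFOS was ever
    present in applied products) the refit is skipped and the returned result
    carries a diagnostic in ``skipped``.
    """
    cols = [c for c in (pfbs_column, pfba_column) if c in table.columns]
    dens = (table[cols].sum(axis=1).to_numpy(dtype=float)
            if cols else np.zeros(len(table)))
    if not np.any(dens > 0):
        return TwoPartResult(
            gaussian=None, logistic=None, n_total=len(table),
            n_positive=0, n_zero=len(table),
            skipped={"sensitivity": "PFBA+PFBS exposure identically zero; "
                                    "sensitivity refit skipped"})
    est = estimator if estimator is not None else TwoPartGAM()
    est = est.__class__(**est.get_params())
    est.fit(table, y=dens)
    return est.result_
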