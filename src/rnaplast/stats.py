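"""Statistical layer: free-energy-vs-length regression and catalog summaries.

The central object is :class:`DeltaGLengthRegressor`, a scikit-learn style
estimator for the ordinary least squares fit of hairpin MFE free energy
(kcal/mol) on hairpin length (nt).  It exposes the quantities designers use:
slope, intercept, R^2, the F statistic on (1, n-2) degrees of freedom, its
p-value, residual standard error, and prediction intervals for a *new*
hairpin at a given length (the "retention band").

Module-level functions (:func:`fit_dg_length`, :func:`predict_dg`,
:func:`slope_by_group`, :func:`ape_vs_dg_ratio`, :func:`apical_loop_summary`)
are thin wrappers over the estimator and over pandas group-bys of a
generated catalog.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class StatsError(ValueError):
    """Raised for degenerate regression input or invalid summary parameters."""


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit of free energy on length, with what inference needs.

    ``x_mean`` and ``sxx`` (sum of squared deviations of the lengths) are
    retained so prediction intervals can be formed without the raw data.
    """

    slope: float
    intercept: float
    r2: float
    f_stat: float
    p_value: float
    residual_se: float
    n: int
    x_mean: float
    sxx: float

    @classmethod
    def from_summary(
        cls,
        slope: float,
        intercept: float,
        x_values: "list[float] | np.ndarray",
        f_stat: float,
    ) -> "RegressionFit":
        """Reconstruct a fit from published summary statistics.

        Given the fitted line, the x design (lengths) and the F statistic,
        the residual standard error follows from
        F = slope^2 * Sxx / s^2.  Useful for applying a published
        regression as a reference band when the raw responses are not
        available.
        """
        x = np.asarray(x_values, dtype=float)
        n = len(x)
        if n < 3:
            raise StatsError("need >= 3 x values to reconstruct inference")
        if f_stat <= 0:
            raise StatsError("F statistic must be positive")
        sxx = float(((x - x.mean()) ** 2).sum())
        s2 = slope**2 * sxx / f_stat
        r2 = f_stat / (f_stat + (n - 2))
        p = float(sps.f.sf(f_stat, 1, n - 2))
        return cls(
            slope=float(slope),
            intercept=float(intercept),
            r2=r2,
            f_stat=float(f_stat),
            p_value=p,
            residual_se=math.sqrt(s2),
            n=n,
            x_mean=float(x.mean()),
            sxx=sxx,
        )


@dataclass(frozen=True)
class PredictionResult:
    """Point prediction and interval for a new observation at one length."""

    x: float
    point: float
    lower: float
    upper: float
    level: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)


class DeltaGLengthRegressor(RegressorMixin, BaseEstimator):
    """OLS regression of hairpin MFE free energy on hairpin length.

    Parameters
    ----------
    level : float, default 0.95
        Confidence level used by :meth:`predict_interval`.

    Attributes (after :meth:`fit`)
    ------------------------------
    slope_, intercept_ : fitted line (kcal/mol per nt, kcal/mol)
    r2_, f_stat_, p_value_ : goodness of fit and its F test on (1, n-2) df
    residual_se_ : residual standard error (kcal/mol)
    n_ : number of observations
    fit_ : the frozen :class:`RegressionFit` summary
    """

    def __init__(self, level: float = 0.95):
        self.level = level

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise StatsError("exactly one feature (length) is supported")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise StatsError("X and y lengths differ")
        n = len(X)
        if n < 2:
            raise StatsError("need at least 2 points")
        sxx = float(((X - X.mean()) ** 2).sum())
        if sxx == 0:
            raise StatsError("lengths have zero variance; cannot fit a slope")
        import statsmodels.api as sm

        res = sm.OLS(y, sm.add_constant(X)).fit()
        self.intercept_, self.slope_ = (float(v) for v in res.params)
        self.n_ = n
        self.x_mean_ = float(X.mean())
        self.sxx_ = sxx
        if n > 2 and res.mse_resid > 0:
            self.r2_ = float(res.rsquared)
            self.f_stat_ = float(res.fvalue)
            self.p_value_ = float(res.f_pvalue)
            self.residual_se_ = float(np.sqrt(res.mse_resid))
        else:  # saturated (n == 2) or exactly collinear fit: no residual noise
            self.r2_ = 1.0
            self.f_stat_ = float("inf")
            self.p_value_ = 0.0 if n > 2 else float("nan")
            self.residual_se_ = 0.0
        self.fit_ = RegressionFit(
            slope=self.slope_,
            intercept=self.intercept_,
            r2=self.r2_,
            f_stat=self.f_stat_,
            p_value=self.p_value_,
            residual_se=self.residual_se_,
            n=self.n_,
            x_mean=self.x_mean_,
            sxx=self.sxx_,
        )
        return self

    @classmethod
    def from_fit(cls, fit: RegressionFit, level: float = 0.95) -> "DeltaGLengthRegressor":
        """Wrap a frozen :class:`RegressionFit` (e.g. from published summaries)."""
        est = cls(level=level)
        est.slope_ = fit.slope
        est.intercept_ = fit.intercept
        est.r2_ = fit.r2
        est.f_stat_ = fit.f_stat
        est.p_value_ = fit.p_value
        est.residual_se_ = fit.residual_se
        est.n_ = fit.n
        est.x_mean_ = fit.x_mean
        est.sxx_ = fit.sxx
        est.fit_ = fit
        return est

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        flat = X[:, 0] if X.ndim == 2 else X
        return self.intercept_ + self.slope_ * flat

    def predict_interval(self, x: float, level: float | None = None) -> PredictionResult:
        """Prediction interval for a *new* hairpin of length x.

        point +/- t_{1-(1-level)/2, n-2} * s * sqrt(1 + 1/n + (x-xbar)^2/Sxx)
        """
        check_is_fitted(self, "slope_")
        if level is None:
            level = self.level
        if self.n_ < 3:
            raise StatsError("prediction interval requires n >= 3 observations")
        point = self.intercept_ + self.slope_ * x
        t = sps.t.ppf(1 - (1 - level) / 2, self.n_ - 2)
        half = t * self.residual_se_ * math.sqrt(
            1 + 1 / self.n_ + (x - self.x_mean_) ** 2 / self.sxx_
        )
        return PredictionResult(x=float(x), point=float(point),
                                lower=float(point - half), upper=float(point + half),
                                level=float(level))

    def mean_se(self, x) -> np.ndarray:
        """Pointwise standard error of the fitted mean over an x grid."""
        check_is_fitted(self, "slope_")
        x = np.asarray(x, dtype=float)
        return self.residual_se_ * np.sqrt(1 / self.n_ + (x - self.x_mean_) ** 2 / self.sxx_)


def fit_dg_length(points) -> RegressionFit:
    """OLS fit of free energy on length from (length, delta_g) pairs."""
    pts = list(points)
    if len(pts) < 2:
        raise StatsError("need at least 2 (length, delta_g) points")
    x = [p[0] for p in pts]
    y = [p[1] for p in pts]
    return DeltaGLengthRegressor().fit(x, y).fit_


def predict_dg(fit: RegressionFit, length: float, level: float = 0.95) -> PredictionResult:
    """Point prediction and prediction interval at one length.

    With n < 3 only the point is defined; requesting the interval then
    raises.  (A zero-width "interval" is returned at the point for exactly
    collinear fits with residual SE 0.)
    """
    est = DeltaGLengthRegressor.from_fit(fit, level=level)
    if fit.n >= 3:
        return est.predict_interval(length, level=level)
    point = fit.intercept + fit.slope * length
    raise StatsError("prediction interval requires n >= 3; point prediction is "
                     f"{point:.2f} via fit.intercept + fit.slope * length")


def catalog_frame(catalog) -> pd.DataFrame:
    """Accept a HairpinCatalog or an already-tabular DataFrame."""
    if isinstance(catalog, pd.DataFrame):
        return catalog
    return catalog.to_frame()


def slope_by_group(
    catalog,
    group_key: str = "complementarity",
    x_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-group free-energy-vs-length OLS fits with mean-SE bands.

    Returns (table, bands): the table has one row per group (slope,
    intercept, r2, f, p, residual_se, n); ``bands`` maps group ->
    (x_grid, fitted mean, SE of mean).  Groups with fewer than 2 distinct
    lengths are skipped with a warning.
    """
    df = catalog_frame(catalog)
    rows = []
    bands: dict = {}
    for key, g in df.groupby(group_key):
        x = g["length"].to_numpy(dtype=float)
        y = g["delta_g"].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            warnings.warn(f"group {key!r} skipped: fewer than 2 distinct lengths")
            continue
        est = DeltaGLengthRegressor().fit(x, y)
        rows.append(
            {
                group_key: key,
                "slope": est.slope_,
                "intercept": est.intercept_,
                "r2": est.r2_,
                "f_stat": est.f_stat_,
                "p_value": est.p_value_,
                "residual_se": est.residual_se_,
                "n": est.n_,
            }
        )
        grid = x_grid if x_grid is not None else np.linspace(x.min(), x.max(), 25)
        bands[key] = (grid, est.predict(grid), est.mean_se(grid))
    return pd.DataFrame(rows), bands


def ape_vs_dg_ratio(
    catalog,
    n_bins: int = 20,
    eps: float = 0.01,
    r_max: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Binned relationship between delta_g/length and APE.

    Hairpins are binned by the ratio r = delta_g/length (kcal/mol/nt,
    <= 0); the table reports per-bin mean ratio and mean APE.  A
    descriptive least-squares curve APE = a + b*ln(r_max - r + eps) is
    fitted to the bin means, and a Spearman correlation between bin ratio
    and bin-mean APE is returned as the monotonicity diagnostic (positive:
    APE rises as the ratio approaches 0).
    """
    if n_bins < 2:
        raise StatsError("n_bins must be >= 2")
    df = catalog_frame(catalog).copy()
    df["ratio"] = df["delta_g"] / df["length"]
    edges = np.linspace(df["ratio"].min(), df["ratio"].max() + 1e-12, n_bins + 1)
    df["bin"] = pd.cut(df["ratio"], bins=edges, include_lowest=True)
    binned = (
        df.groupby("bin", observed=True)
        .agg(ratio=("ratio", "mean"), ape=("ape", "mean"), n=("ape", "size"))
        .dropna()
        .reset_index(drop=True)
    )
    r = binned["ratio"].to_numpy()
    a = binned["ape"].to_numpy()
    if len(binned) >= 2:
        z = np.log(r_max - r + eps)
        coef = np.polyfit(z, a, 1)
        curve = {"a": float(coef[1]), "b": float(coef[0]), "eps": eps, "r_max": r_max}
        rho = float(sps.spearmanr(r, a).statistic)
    else:
        curve = {"a": float(a.mean()) if len(a) else float("nan"), "b": 0.0,
                 "eps": eps, "r_max": r_max}
        rho = float("nan")
    curve["spearman"] = rho
    return binned, curve


def apical_loop_summary(catalog, group_key: str = "complementarity") -> pd.DataFrame:
    """Mean +/- standard error of apical-loop counts per group.

    SE is the sample standard deviation over sqrt(n), pooled over stem
    lengths within each group by default.  Empty groups are skipped with a
    warning.
    """
    df = catalog_frame(catalog)
    rows = []
    for key, g in df.groupby(group_key):
        counts = g["apical_loops"].to_numpy(dtype=float)
        if len(counts) == 0:
            warnings.warn(f"group {key!r} skipped: empty")
            continue
        mean = float(counts.mean())
        se = float(counts.std(ddof=1) / math.sqrt(len(counts))) if len(counts) > 1 else 0.0
        rows.append({group_key: key, "mean_apical_loops": mean, "se": se, "n": len(counts)})
    return pd.DataFrame(rows)
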