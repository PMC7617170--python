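"""Volumetric multi-site harmonisation and trend statistics.

ComBat-style location/scale harmonisation of per-subject tissue-volume
features: each feature v is modelled as

    y_ijv = alpha_v + X_ij beta_v + gamma_iv + delta_iv eps_ijv

with additive (gamma) and multiplicative (delta) site effects around a
shared covariate model.  Estimation is method-of-moments per site (no
empirical-Bayes shrinkage: with only three volume features there is
nothing to shrink across): each site's covariate fit supplies its
location, per-site residual scatter supplies delta relative to the
pooled within-site scale, and alpha/beta are the subject-count-weighted
means of the per-site coefficients.  Harmonised values are

    y_harm = (y - alpha - X beta - gamma_i) / delta_i + alpha + X beta,

which removes site location/scale effects while preserving covariate
(e.g. age) trends.  This construction makes harmonisation exactly
idempotent: refitting the model on harmonised data recovers gamma = 0
and delta = 1 identically.

Also provided: per-site linear age trends with across-site spread
statistics, Levene's test on trend residual spreads, and a
cross-validated age-regression check that harmonisation has not erased
age-related biological variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "ComBatModel",
    "TrendStats",
    "combat_fit",
    "combat_apply",
    "site_trends",
    "levene_test",
    "age_regression_rmse",
]

FEATURE_COLUMNS = ["vol_csf", "vol_gm", "vol_wm"]


def _design(table: pd.DataFrame, covariates) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(table))]
        + [np.asarray(table[c], dtype=np.float64) for c in covariates]
    )
    return X


@dataclass
class ComBatModel:
    covariates: list
    features: list
    coef: dict  # feature -> pooled (1 + n_cov,): intercept alpha_v then beta_v
    site_coef: dict  # feature -> DataFrame (site x coef) per-site fits
    gamma: pd.DataFrame  # site x feature additive effects (intercept offsets)
    delta: pd.DataFrame  # site x feature multiplicative effects
    resid_scale: dict  # feature -> pooled within-site residual sd

    @property
    def sites(self) -> list:
        return list(self.gamma.index)

    def alpha(self, feature: str) -> float:
        return float(self.coef[feature][0])

    def beta(self, feature: str) -> np.ndarray:
        return np.asarray(self.coef[feature][1:])


def combat_fit(
    table: pd.DataFrame,
    covariates=("age",),
    features=None,
    min_subjects_per_site: int = 3,
    min_sites: int = 2,
) -> ComBatModel:
    """Fit the location/scale site-effect model.

    ``table`` needs columns ``site``, the covariates, and the features
    (default ``vol_csf, vol_gm, vol_wm``).  Each site gets its own OLS
    covariate fit; alpha/beta are the subject-count-weighted means of the
    per-site coefficients, gamma_i is the site fit minus the shared fit
    evaluated at the grand covariate mean (its subject-count-weighted
    mean over sites is exactly zero), and delta_i is the within-site
    residual sd relative to the ANOVA-pooled within-site sd.
    """
    features = list(features or FEATURE_COLUMNS)
    covariates = list(covariates)
    sites = list(table["site"].unique())
    if len(sites) < min_sites:
        raise ValueError(f"need at least {min_sites} sites")
    counts = table["site"].value_counts()
    needed = max(min_subjects_per_site, len(covariates) + 2)
    if (counts < needed).any():
        small = counts[counts < needed].index.tolist()
        raise ValueError(f"sites with fewer than {needed} subjects: {small}")

    X = _design(table, covariates)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular covariate design matrix")
    site_col = table["site"].to_numpy()
    n_total = len(table)

    coef, site_coef, gamma, delta, resid_scale = {}, {}, {}, {}, {}
    site_index = pd.Index(sites, name="site")
    for f in features:
        y = np.asarray(table[f], dtype=np.float64)
        if (y <= 0).any():
            raise ValueError(f"non-positive volumes in feature {f!r}")
        cs = np.empty((len(sites), p))
        ss2 = np.empty(len(sites))
        ns = np.empty(len(sites))
        for i, s in enumerate(sites):
            m = site_col == s
            Xi = X[m]
            if np.linalg.matrix_rank(Xi) < p:
                raise ValueError(f"singular covariate design at site {s!r}")
            ci, *_ = np.linalg.lstsq(Xi, y[m], rcond=None)
            ui = y[m] - Xi @ ci
            cs[i] = ci
            ns[i] = m.sum()
            ss2[i] = (ui**2).sum() / (ns[i] - p)
        w = ns / n_total
        cbar = w @ cs
        pooled = np.sqrt(((ns - p) * ss2).sum() / (n_total - len(sites) * p))
        coef[f] = cbar
        site_coef[f] = pd.DataFrame(cs, index=site_index)
        # additive site effect measured at the grand covariate mean,
        # where the per-site fits are best determined
        xbar = X.mean(axis=0)
        gamma[f] = (cs - cbar) @ xbar
        delta[f] = np.sqrt(ss2) / pooled
        resid_scale[f] = float(pooled)
    return ComBatModel(
        covariates=covariates,
        features=features,
        coef=coef,
        site_coef=site_coef,
        gamma=pd.DataFrame(gamma, index=site_index),
        delta=pd.DataFrame(delta, index=site_index),
        resid_scale=resid_scale,
    )


def combat_apply(model: ComBatModel, table: pd.DataFrame) -> pd.DataFrame:
    """Return the harmonised feature table.

    Subtracts each site's own covariate fit, rescales the residual by
    1/delta_i, and adds back the shared fit alpha + X beta.
    """
    unseen = set(table["site"].unique()) - set(model.sites)
    if unseen:
        raise ValueError(f"sites not in the fitted model: {sorted(unseen)}")
    out = table.copy()
    X = _design(table, model.covariates)
    site = table["site"].to_numpy()
    for f in model.features:
        y = np.asarray(table[f], dtype=np.float64)
        shared = X @ model.coef[f]
        site_fit = np.einsum(
            "np,np->n", X, model.site_coef[f].loc[site].to_numpy()
        )
        d = model.delta[f].loc[site].to_numpy()
        out[f] = (y - site_fit) / d + shared
    return out


@dataclass
class TrendStats:
    """Per-site linear trends of feature vs age, with across-site spread."""

    per_site: pd.DataFrame  # columns: cohort, site, feature, intercept, gradient
    summary: pd.DataFrame  # columns: cohort, feature, stat x {mean, sd}

    def residuals(self, cohort: str, feature: str) -> list:
        """Per-site residual sets for the given cohort/feature."""
        rows = self.per_site[
            (self.per_site["cohort"] == cohort)
            & (self.per_site["feature"] == feature)
        ]
        return [np.asarray(r) for r in rows["residuals"]]


def site_trends(
    table: pd.DataFrame,
    features=None,
    young_max_mean_age: float = 16.0,
    old_min_mean_age: float = 22.0,
) -> TrendStats:
    """Per-site OLS lines of feature vs age within age cohorts.

    Sites are partitioned by mean age into "Young" (< ``young_max``) and
    "Old" (> ``old_min``); sites between the thresholds are excluded, as
    are sites with fewer than 3 subjects (with a warning).
    """
    features = list(features or FEATURE_COLUMNS)
    rows = []
    for site, g in table.groupby("site"):
        if len(g) < 3:
            warnings.warn(f"site {site!r} has fewer than 3 subjects; excluded")
            continue
        mean_age = g["age"].mean()
        if mean_age < young_max_mean_age:
            cohort = "Young"
        elif mean_age > old_min_mean_age:
            cohort = "Old"
        else:
            continue
        x = g["age"].to_numpy(dtype=np.float64)
        for f in features:
            y = g[f].to_numpy(dtype=np.float64)
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            rows.append(
                {
                    "cohort": cohort,
                    "site": site,
                    "feature": f,
                    "intercept": float(intercept),
                    "gradient": float(slope),
                    "residuals": resid,
                }
            )
    per_site = pd.DataFrame(rows)
    summ = []
    if len(per_site):
        for (cohort, f), g in per_site.groupby(["cohort", "feature"]):
            summ.append(
                {
                    "cohort": cohort,
                    "feature": f,
                    "intercept_mean": g["intercept"].mean(),
                    "intercept_sd": g["intercept"].std(ddof=1),
                    "gradient_mean": g["gradient"].mean(),
                    "gradient_sd": g["gradient"].std(ddof=1),
                    "n_sites": len(g),
                }
            )
    return TrendStats(per_site=per_site, summary=pd.DataFrame(summ))


def levene_test(groups) -> tuple[float, float]:
    """Classic Levene test (ANOVA on absolute deviations from group means).

    ``groups``: sequence of >= 2 value sets, each with >= 2 values.
    Returns ``(statistic, p_value)``.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Levene's test needs >= 2 groups of >= 2 values")
    stat, p = stats.levene(*groups, center="mean")
    return float(stat), float(p)


def age_regression_rmse(
    table: pd.DataFrame,
    features=None,
    n_folds: int = 10,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """K-fold RMSE (years) of a linear age model on the tissue features.

    A harmonisation that preserves biology keeps this error low; one that
    scrubs covariate structure pushes it towards sd(age).
    """
    features = list(features or FEATURE_COLUMNS)
    if "age" not in table.columns:
        raise ValueError("table must have an 'age' column")
    if n_folds > len(table):
        raise ValueError("more folds than subjects")
    seed = (
        rng if isinstance(rng, (int, np.integer)) or rng is None
        else int(rng.integers(2**31))
    )
    X = table[features].to_numpy(dtype=np.float64)
    y = table["age"].to_numpy(dtype=np.float64)
    rmses = []
    for tr, te in KFold(n_folds, shuffle=True, random_state=seed).split(X):
        model = LinearRegression().fit(X[tr], y[tr])
        pred = model.predict(X[te])
        rmses.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
    return np.asarray(rmses)
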