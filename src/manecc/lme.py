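"""Per-feature linear mixed-effects age models for accelerated longitudinal
designs.

Model per feature (region, edge, or centrality):

    value ~ 1 + age + sex + site + motion + (1 | subject)

estimated by restricted maximum likelihood.  Because the analyses fit the
same design to hundreds or thousands of features, the default engine is a
profiled-REML random-intercept solver specialized to this model: for a given
variance ratio lambda = sigma_b^2 / sigma_e^2 the GLS solution is closed-form
through the blocked Woodbury identity, and the REML criterion is minimized
over the single scalar lambda.  ``engine="statsmodels"`` fits the identical
model with statsmodels MixedLM.  Degrees of freedom for the age contrast use
a Satterthwaite-style approximation by default (finite-difference gradient of
the contrast variance against the numerically evaluated REML information);
``df_method`` may also be "residual" or "normal".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .datatypes import VisitRecord, visits_to_frame

AGE_BINS = ((-np.inf, 17.0), (17.0, 19.0), (19.0, 21.0), (21.0, 23.0), (23.0, np.inf))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _design(visits_df: pd.DataFrame, terms=("age", "sex", "site", "motion"),
            center_age: bool = False, quadratic: bool = False):
    """Fixed-effects design matrix; degenerate categorical terms are dropped."""
    cols, names = [np.ones(len(visits_df))], ["intercept"]
    age = visits_df["age"].to_numpy(float)
    if center_age or quadratic:
        age = age - age.mean()  # collinearity guard for the quadratic model
    if "age" in terms:
        cols.append(age)
        names.append("age")
    if quadratic:
        cols.append(age**2)
        names.append("age2")
    for cat in ("sex", "site"):
        if cat not in terms:
            continue
        levels = sorted(visits_df[cat].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"dropping degenerate term '{cat}' (single level)")
            continue
        for lv in levels[1:]:  # reference coding
            cols.append((visits_df[cat].astype(str) == lv).to_numpy(float))
            names.append(f"{cat}[{lv}]")
    if "motion" in terms:
        m = visits_df["motion"].to_numpy(float)
        if np.ptp(m) == 0:
            warnings.warn("dropping degenerate term 'motion' (constant)")
        else:
            cols.append(m)
            names.append("motion")
    x = np.column_stack(cols)
    return x, names


def _group_codes(visits_df: pd.DataFrame) -> np.ndarray:
    return pd.factorize(visits_df["subject_id"])[0]


# ---------------------------------------------------------------------------
# profiled-REML random-intercept solver
# ---------------------------------------------------------------------------

class _REMLDesign:
    """Precomputations shared by every feature fit on one design."""

    def __init__(self, x: np.ndarray, groups: np.ndarray):
        self.x = x
        self.n, self.p = x.shape
        self.groups = groups
        self.n_groups = groups.max() + 1
        self.m = np.bincount(groups).astype(float)  # group sizes
        self.xtx = x.T @ x
        self.gx = np.zeros((self.n_groups, self.p))
        np.add.at(self.gx, groups, x)

    def solve(self, y: np.ndarray, lam: float):
        """GLS quantities at variance ratio lam (V = I + lam Z Z')."""
        w = lam / (1.0 + self.m * lam)
        gy = np.bincount(self.groups, weights=y, minlength=self.n_groups)
        a = self.xtx - self.gx.T @ (w[:, None] * self.gx)
        b = self.x.T @ y - self.gx.T @ (w * gy)
        yvy = y @ y - w @ gy**2
        beta = np.linalg.solve(a, b)
        rss = max(yvy - beta @ b, 1e-300)
        return a, beta, rss

    def neg2_reml(self, y: np.ndarray, lam: float) -> float:
        a, _, rss = self.solve(y, lam)
        sign, logdet_a = np.linalg.slogdet(a)
        logdet_v = np.log1p(self.m * lam).sum()
        return ((self.n - self.p) * np.log(rss / (self.n - self.p))
                + logdet_v + logdet_a)


def _fit_one(design: _REMLDesign, y: np.ndarray, coef_idx: int,
             df_method: str = "satterthwaite"):
    """REML fit of one feature; returns (beta, se, t, p, df, lam, sigma2)."""
    obj = lambda u: design.neg2_reml(y, np.exp(u))
    res = minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    if obj(-30.0) < res.fun:  # boundary check: no subject variance
        lam = 0.0
    a, beta, rss = design.solve(y, lam)
    n, p = design.n, design.p
    sigma2 = rss / (n - p)
    ainv = np.linalg.inv(a)
    se = np.sqrt(sigma2 * ainv[coef_idx, coef_idx])
    t = beta[coef_idx] / se

    if df_method == "normal":
        pval = 2 * stats.norm.sf(abs(t))
        df = np.inf
    elif df_method == "residual":
        df = n - p
        pval = 2 * stats.t.sf(abs(t), df)
    else:
        df = _satterthwaite_df(design, y, lam, sigma2, coef_idx)
        pval = 2 * stats.t.sf(abs(t), df)
    return beta[coef_idx], se, t, pval, df, lam, sigma2


def _satterthwaite_df(design: _REMLDesign, y: np.ndarray, lam: float,
                      sigma2: float, coef_idx: int) -> float:
    """Satterthwaite df for one coefficient via numeric REML information.

    Parameterized in theta = (sigma_e^2, sigma_b^2); the contrast variance is
    h(theta) = sigma_e^2 [A(lambda)^-1]_cc with lambda = sigma_b^2/sigma_e^2.
    """
    n, p = design.n, design.p
    th = np.array([sigma2, lam * sigma2])

    def h(theta):
        se2, sb2 = max(theta[0], 1e-12), max(theta[1], 0.0)
        a, _, _ = design.solve(y, sb2 / se2)
        return se2 * np.linalg.inv(a)[coef_idx, coef_idx]

    def m2ll(theta):
        se2, sb2 = max(theta[0], 1e-12), max(theta[1], 0.0)
        l = sb2 / se2
        a, _, rss = design.solve(y, l)
        _, logdet_a = np.linalg.slogdet(a)
        return ((n - p) * np.log(se2) + np.log1p(design.m * l).sum()
                + logdet_a + rss / se2)

    eps = np.maximum(1e-4 * np.abs(th), 1e-10)
    grad = np.empty(2)
    hess = np.empty((2, 2))
    for i in range(2):
        ei = np.eye(2)[i] * eps[i]
        grad[i] = (h(th + ei) - h(np.maximum(th - ei, 0))) / (eps[i] * 2)
    f0 = m2ll(th)
    for i in range(2):
        ei = np.eye(2)[i] * eps[i]
        for j in range(i, 2):
            ej = np.eye(2)[j] * eps[j]
            fpp = m2ll(th + ei + ej)
            fpm = m2ll(np.maximum(th + ei - ej, 0))
            fmp = m2ll(np.maximum(th - ei + ej, 0))
            fmm = m2ll(np.maximum(th - ei - ej, 0))
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps[i] * eps[j])
    hess *= 0.5  # information of -2 log L -> of -log L
    try:
        cov = np.linalg.inv(hess)
        denom = grad @ cov @ grad
        if denom <= 0:
            return float(n - p)
        df = 2.0 * h(th)**2 / denom
    except np.linalg.LinAlgError:
        return float(n - p)
    return float(np.clip(df, 1.0, n - p))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class LMEResult:
    """Per-feature age-effect table with FDR-adjusted significance."""

    table: pd.DataFrame  # feature_id, beta_age, t, p, q, significant
    model_terms: dict

    def significant_features(self) -> np.ndarray:
        return self.table.loc[self.table.significant.fillna(False).astype(bool),
                              "feature_id"].to_numpy()


def fdr_correct(p_values: np.ndarray, q_threshold: float = 0.05):
    """Benjamini-Hochberg adjusted q-values and significance mask."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        _, q[ok], _, _ = multipletests(p[ok], method="fdr_bh")
    mask = q < q_threshold
    return q, mask


def fit_lme_per_feature(features: np.ndarray, visits: list[VisitRecord] | pd.DataFrame,
                        feature_ids=None, q_threshold: float = 0.05,
                        engine: str = "fast", df_method: str = "satterthwaite",
                        terms=("age", "sex", "site", "motion"),
                        quadratic: bool = False) -> LMEResult:
    """Fit value ~ age + sex + site + motion + (1|subject) per feature column.

    ``features`` is (n_visit_rows x n_features), row-aligned with the visit
    records.  Constant features get absent (NaN) statistics.  Reported
    statistics are for the age term, or the age^2 term when ``quadratic``.
    """
    vdf = visits if isinstance(visits, pd.DataFrame) else visits_to_frame(visits)
    features = np.atleast_2d(np.asarray(features, float))
    if features.shape[0] != len(vdf):
        raise ValueError("feature rows must align with visit records")
    if vdf.groupby("subject_id").size().median() < 2:
        raise ValueError("a majority of subjects must have >= 2 visits")
    x, names = _design(vdf, terms=terms, quadratic=quadratic)
    coef_name = "age2" if quadratic else "age"
    coef_idx = names.index(coef_name)
    groups = _group_codes(vdf)
    n_feat = features.shape[1]
    if feature_ids is None:
        feature_ids = np.arange(n_feat)

    betas = np.full(n_feat, np.nan)
    ts = np.full(n_feat, np.nan)
    ps = np.full(n_feat, np.nan)
    if engine == "fast":
        design = _REMLDesign(x, groups)
        for j in range(n_feat):
            y = features[:, j]
            if np.ptp(y) == 0:
                continue
            betas[j], _, ts[j], ps[j], _, _, _ = _fit_one(
                design, y, coef_idx, df_method=df_method)
    elif engine == "statsmodels":
        import statsmodels.regression.mixed_linear_model as mlm
        for j in range(n_feat):
            y = features[:, j]
            if np.ptp(y) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = mlm.MixedLM(y, x, groups=groups).fit(reml=True)
            betas[j] = fit.params[coef_idx]
            ts[j] = fit.tvalues[coef_idx]
            ps[j] = fit.pvalues[coef_idx]
    else:
        raise ValueError(f"unknown engine '{engine}'")

    q, mask = fdr_correct(ps, q_threshold)
    table = pd.DataFrame(dict(feature_id=feature_ids, beta_age=betas, t=ts,
                              p=ps, q=q, significant=mask))
    table.loc[table.p.isna(), "significant"] = False
    return LMEResult(table=table,
                     model_terms=dict(fixed=names, random="1|subject",
                                      engine=engine, df_method=df_method,
                                      coefficient=coef_name,
                                      q_threshold=q_threshold))


def fit_quadratic_age(features, visits, **kwargs) -> LMEResult:
    """Age + age^2 model (ages centered first); reports the age^2 term."""
    return fit_lme_per_feature(features, visits, quadratic=True, **kwargs)


def residualize_features(features: np.ndarray, nodal_covariates: list[np.ndarray]
                         ) -> np.ndarray:
    """Per-feature OLS residuals on aligned nodal covariates (with intercept)."""
    features = np.asarray(features, float)
    resid = np.empty_like(features)
    for j in range(features.shape[1]):
        cols = [np.ones(features.shape[0])]
        for cov in nodal_covariates:
            c = np.asarray(cov, float)[:, j] if np.asarray(cov).ndim == 2 else np.asarray(cov, float)
            if np.ptp(c) == 0:
                warnings.warn(f"dropping constant covariate for feature {j}")
                continue
            cols.append(c)
        xc = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(xc, features[:, j], rcond=None)
        resid[:, j] = features[:, j] - xc @ beta
    return resid


def stratify_map(statistic_map: np.ndarray, classes: np.ndarray) -> pd.DataFrame:
    """Per-class mean and SD of a parcel-wise statistic map."""
    m = np.asarray(statistic_map, float)
    cl = np.asarray(classes)
    if len(m) != len(cl):
        raise ValueError("map and class labels must align")
    if pd.isna(cl).any():
        raise ValueError("unlabeled parcel in class vector")
    df = pd.DataFrame({"value": m, "class": cl})
    out = df.groupby("class", sort=True)["value"].agg(["mean", "std", "count"])
    return out.reset_index().rename(columns={"std": "sd", "count": "n"})


def interaction_test(features: np.ndarray, visits: list[VisitRecord] | pd.DataFrame,
                     moderator: str, engine: str = "fast",
                     df_method: str = "satterthwaite"):
    """Age x moderator interaction on a single (region-mean) feature.

    Returns (beta, t, p) for the interaction term of a two-level moderator,
    or the largest-|t| interaction term with a Bonferroni-adjusted p when the
    moderator has more levels.
    """
    vdf = visits if isinstance(visits, pd.DataFrame) else visits_to_frame(visits)
    y = np.asarray(features, float).ravel()
    mod = vdf[moderator]
    if moderator == "tanner":  # early/late pubertal group split at the median
        filled = mod.groupby(vdf.subject_id).transform(lambda s: s.ffill().bfill())
        keep = ~filled.isna()
        vdf, y, mod = vdf[keep].copy(), y[keep.to_numpy()], filled[keep]
        mod = (mod > mod.median()).map({False: "early", True: "late"})
        vdf = vdf.assign(tanner_group=mod)
        moderator = "tanner_group"
    levels = sorted(mod.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"moderator '{moderator}' is constant")
    base_terms = [t for t in ("age", "sex", "site", "motion") if t != moderator]
    x, names = _design(vdf, terms=tuple(base_terms))
    age = vdf["age"].to_numpy(float)
    inter_idx = []
    for lv in levels[1:]:
        ind = (mod.astype(str) == lv).to_numpy(float)
        x = np.column_stack([x, ind, age * ind])
        names += [f"{moderator}[{lv}]", f"age:{moderator}[{lv}]"]
        inter_idx.append(x.shape[1] - 1)
    design = _REMLDesign(x, _group_codes(vdf))
    results = [_fit_one(design, y, ci, df_method=df_method) for ci in inter_idx]
    best = max(results, key=lambda r: abs(r[2]))
    p = min(best[3] * len(results), 1.0)
    return best[0], best[2], p


def age_bin_stratify(features: np.ndarray, visits: list[VisitRecord] | pd.DataFrame,
                     bins=AGE_BINS) -> pd.DataFrame:
    """Mean feature value per discretized age bin (empty bins reported NaN)."""
    vdf = visits if isinstance(visits, pd.DataFrame) else visits_to_frame(visits)
    y = np.asarray(features, float).ravel()
    rows = []
    for lo, hi in bins:
        in_bin = (vdf["age"].to_numpy(float) >= lo) & (vdf["age"].to_numpy(float) < hi)
        rows.append(dict(bin=f"[{lo},{hi})", n=int(in_bin.sum()),
                         mean=float(y[in_bin].mean()) if in_bin.any() else np.nan))
    return pd.DataFrame(rows)
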