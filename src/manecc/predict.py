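"""Elastic-net prediction of follow-up IQ from manifold features.

Nested cross-validation: an outer 10-fold split measures performance; within
every outer training set an inner 10-fold loop tunes the elastic-net penalty
(mixing ratio fixed at 0.5).  The elastic net acts purely as a feature
selector; a plain linear model on the selected features plus nuisance
covariates (age, sex, site, motion) produces the predictions.  The whole
procedure is repeated with reshuffled folds to average out split composition,
and compared against a training-mean baseline predictor with Meng's z-test
for correlated correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold


@dataclass
class PredictionResult:
    per_repetition_r: np.ndarray
    per_repetition_mae: np.ndarray
    selection_probability: np.ndarray
    mean_n_selected: float
    baseline_r: float = np.nan
    baseline_mae: float = np.nan
    meng_z: float = np.nan
    meng_p: float = np.nan
    permutation_p: float = np.nan
    r_ci: tuple = field(default=(np.nan, np.nan))  # empirical 95% interval

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.per_repetition_r))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.per_repetition_mae))


def _standardize(train, test):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _alpha_grid(x_std, y_c, l1_ratio, n_alphas):
    alpha_max = np.abs(x_std.T @ y_c).max() / (len(y_c) * l1_ratio)
    alpha_max = max(alpha_max, 1e-8)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3), n_alphas)


def _linear_predict(x_tr, y_tr, x_te):
    xd = np.column_stack([np.ones(len(x_tr)), x_tr])
    beta, *_ = np.linalg.lstsq(xd, y_tr, rcond=None)
    return np.column_stack([np.ones(len(x_te)), x_te]) @ beta


def _fit_fold(x, y, cov, tr, te, l1_ratio, n_alphas, n_inner, rs):
    """One outer fold: inner tuning of alpha, refit, outer prediction."""
    inner = KFold(n_splits=n_inner, shuffle=True, random_state=rs)
    grid = None
    mae = np.zeros(n_alphas)
    for itr, ite in inner.split(tr):
        a_tr, a_te = tr[itr], tr[ite]
        xs_tr, xs_te = _standardize(x[a_tr], x[a_te])
        y_mu = y[a_tr].mean()
        y_c = y[a_tr] - y_mu
        if grid is None:
            grid = _alpha_grid(xs_tr, y_c, l1_ratio, n_alphas)
        _, coefs, _ = enet_path(xs_tr, y_c, alphas=grid, l1_ratio=l1_ratio)
        for ai in range(n_alphas):
            sel = np.flatnonzero(coefs[:, ai])
            cols_tr = [x[a_tr][:, sel]] if len(sel) else []
            cols_te = [x[a_te][:, sel]] if len(sel) else []
            if cov is not None:
                cols_tr.append(cov[a_tr])
                cols_te.append(cov[a_te])
            if cols_tr:
                pred = _linear_predict(np.column_stack(cols_tr), y[a_tr],
                                       np.column_stack(cols_te))
            else:
                pred = np.full(len(a_te), y[a_tr].mean())
            mae[ai] += np.abs(pred - y[a_te]).mean()
    best_alpha = grid[np.argmin(mae)]
    xs_tr, xs_te = _standardize(x[tr], x[te])
    _, coefs, _ = enet_path(xs_tr, y[tr] - y[tr].mean(),
                            alphas=[best_alpha], l1_ratio=l1_ratio)
    sel = np.flatnonzero(coefs[:, 0])
    if len(sel) == 0:
        warnings.warn("empty elastic-net selection; covariate-only model used")
    cols_tr = [x[tr][:, sel]] if len(sel) else []
    cols_te = [x[te][:, sel]] if len(sel) else []
    if cov is not None:
        cols_tr.append(cov[tr])
        cols_te.append(cov[te])
    if cols_tr:
        pred = _linear_predict(np.column_stack(cols_tr), y[tr],
                               np.column_stack(cols_te))
    else:
        pred = np.full(len(te), y[tr].mean())
    return pred, sel


def nested_elasticnet_predict(features: np.ndarray, target: np.ndarray,
                              covariates: np.ndarray | None = None,
                              n_outer: int = 10, n_inner: int = 10,
                              n_reps: int = 100, l1_ratio: float = 0.5,
                              n_alphas: int = 20, seed: int = 0,
                              compare_baseline: bool = True) -> PredictionResult:
    """Nested elastic-net prediction with repeated reshuffled folds."""
    x = np.asarray(features, float)
    y = np.asarray(target, float)
    cov = None if covariates is None else np.asarray(covariates, float)
    n, p = x.shape
    if y.std() == 0:
        raise ValueError("constant target")
    if n < 2 * n_outer:
        raise ValueError("need at least 2 subjects per outer fold")

    rs = np.random.RandomState(seed)
    rep_r = np.empty(n_reps)
    rep_mae = np.empty(n_reps)
    sel_counts = np.zeros(p)
    n_selected = []
    base_r, base_mae = [], []
    r12 = []
    for rep in range(n_reps):
        outer = KFold(n_splits=n_outer, shuffle=True,
                      random_state=rs.randint(2**31 - 1))
        preds = np.empty(n)
        base_preds = np.empty(n)
        for tr, te in outer.split(x):
            pred, sel = _fit_fold(x, y, cov, tr, te, l1_ratio, n_alphas,
                                  n_inner, rs.randint(2**31 - 1))
            preds[te] = pred
            base_preds[te] = y[tr].mean()
            sel_counts[sel] += 1
            n_selected.append(len(sel))
        rep_r[rep] = np.corrcoef(preds, y)[0, 1] if preds.std() > 0 else np.nan
        rep_mae[rep] = np.abs(preds - y).mean()
        if compare_baseline:
            base_mae.append(np.abs(base_preds - y).mean())
            base_r.append(np.corrcoef(base_preds, y)[0, 1]
                          if base_preds.std() > 0 else np.nan)
            if preds.std() > 0 and base_preds.std() > 0:
                r12.append(np.corrcoef(preds, base_preds)[0, 1])

    result = PredictionResult(
        per_repetition_r=rep_r, per_repetition_mae=rep_mae,
        selection_probability=sel_counts / (n_reps * n_outer),
        mean_n_selected=float(np.mean(n_selected)),
        r_ci=(float(np.nanpercentile(rep_r, 2.5)),
              float(np.nanpercentile(rep_r, 97.5))))
    if compare_baseline:
        result.baseline_r = float(np.nanmean(base_r))
        result.baseline_mae = float(np.mean(base_mae))
        # clip away exact +-1 so the Fisher transform stays finite
        r1 = float(np.clip(result.mean_r, -0.9999, 0.9999))
        r2 = float(np.clip(result.baseline_r, -0.9999, 0.9999))
        r12m = float(np.clip(np.nanmean(r12), -0.999, 0.999)) if r12 else 0.0
        if np.isfinite(r1) and np.isfinite(r2) and n > 3:
            result.meng_z, result.meng_p = mengs_z(r1, r2, r12m, n)
    return result


def baseline_mean_predict(target: np.ndarray, n_outer: int = 10,
                          n_reps: int = 100, seed: int = 0):
    """Training-mean predictor; returns (baseline_r, baseline_mae).

    r is NaN for a constant target (correlation undefined).
    """
    y = np.asarray(target, float)
    rs = np.random.RandomState(seed)
    rvals, maes = [], []
    for _ in range(n_reps):
        outer = KFold(n_splits=n_outer, shuffle=True,
                      random_state=rs.randint(2**31 - 1))
        preds = np.empty(len(y))
        for tr, te in outer.split(y):
            preds[te] = y[tr].mean()
        maes.append(np.abs(preds - y).mean())
        rvals.append(np.corrcoef(preds, y)[0, 1]
                     if preds.std() > 0 and y.std() > 0 else np.nan)
    return float(np.nanmean(rvals)) if not np.all(np.isnan(rvals)) else np.nan, \
        float(np.mean(maes))


def mengs_z(r1: float, r2: float, r12: float, n: int):
    """Meng's z-test for two correlated correlations sharing a variable.

    z = (z1 - z2) * sqrt((n - 3) / (2 (1 - r12) h)), with
    h = (1 - f rbar^2) / (1 - rbar^2), f = min(1, (1 - r12) / (2 (1 - rbar^2))),
    rbar^2 = (r1^2 + r2^2) / 2.  Two-sided p.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly in (-1, 1)")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    return float(z), float(2 * stats.norm.sf(abs(z)))


def permutation_pvalue(features: np.ndarray, target: np.ndarray,
                       covariates: np.ndarray | None = None,
                       observed_r: float | None = None, n_perm: int = 1000,
                       n_reps: int = 1, seed: int = 0, **kwargs) -> float:
    """Permutation p-value for the prediction correlation.

    The target is shuffled across subjects and the full nested prediction is
    rerun per permutation (with a reduced repetition count for tractability);
    p = (1 + #{null r >= observed r}) / (n_perm + 1), one-sided.
    """
    if observed_r is None:
        observed_r = nested_elasticnet_predict(
            features, target, covariates, n_reps=n_reps, seed=seed,
            compare_baseline=False, **kwargs).mean_r
    rng = np.random.default_rng(seed)
    count = 0
    for i in range(n_perm):
        y_perm = rng.permutation(np.asarray(target, float))
        null = nested_elasticnet_predict(
            features, y_perm, covariates, n_reps=n_reps, seed=seed + 1 + i,
            compare_baseline=False, **kwargs).mean_r
        if not np.isnan(null) and null >= observed_r - 1e-15:
            count += 1
    return (1 + count) / (n_perm + 1)
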