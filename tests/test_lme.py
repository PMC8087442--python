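"""Mixed-effects age models: exactness, calibration, cross-engine agreement."""

import numpy as np
import pandas as pd
import pytest

from manecc import (CohortConfig, age_bin_stratify, fdr_correct,
                    fit_lme_per_feature, fit_quadratic_age, interaction_test,
                    residualize_features, simulate_cohort, stratify_map,
                    visits_to_frame)


@pytest.fixture(scope="module")
def vdf():
    cfg = CohortConfig(n_subjects=40, seed=2)
    return visits_to_frame(simulate_cohort(cfg))


def test_exact_linear_feature_recovered(vdf):
    y = 2.0 * vdf.age.to_numpy()
    res = fit_lme_per_feature(y[:, None], vdf)
    row = res.table.iloc[0]
    assert row.beta_age == pytest.approx(2.0, abs=1e-8)
    assert row.p < 1e-12


def test_subject_intercepts_leave_slope_unbiased(vdf, rng):
    """Recovered slope stays within 2 SE of truth despite large random
    intercepts (simulation oracle, 200 replicate fits)."""
    n = len(vdf)
    n_subj = vdf.subject_id.nunique()
    subj_idx = pd.factorize(vdf.subject_id)[0]
    slopes = []
    feats = np.empty((n, 200))
    for j in range(200):
        intercepts = rng.normal(0, 5, n_subj)[subj_idx]
        feats[:, j] = 0.3 * vdf.age + intercepts + rng.normal(0, 1, n)
    res = fit_lme_per_feature(feats, vdf)
    mean_slope = res.table.beta_age.mean()
    se = res.table.beta_age.std() / np.sqrt(200)
    assert abs(mean_slope - 0.3) < 2 * se + 0.01


def test_null_rejection_rate_calibrated(vdf, rng):
    """beta_age = 0: rejection at p < 0.05 within [0.03, 0.07] (500+ fits)."""
    n = len(vdf)
    n_subj = vdf.subject_id.nunique()
    subj_idx = pd.factorize(vdf.subject_id)[0]
    feats = np.empty((n, 600))
    for j in range(600):
        feats[:, j] = rng.normal(0, 0.7, n_subj)[subj_idx] + rng.normal(0, 0.5, n)
    res = fit_lme_per_feature(feats, vdf)
    rate = (res.table.p < 0.05).mean()
    assert 0.03 <= rate <= 0.07


def test_fast_engine_agrees_with_statsmodels(vdf, rng):
    """Independent cross-check of the profiled-REML solver against MixedLM."""
    n = len(vdf)
    subj_idx = pd.factorize(vdf.subject_id)[0]
    feats = np.empty((n, 10))
    for j in range(10):
        feats[:, j] = (0.05 * rng.normal() * vdf.age
                       + rng.normal(0, 0.5, vdf.subject_id.nunique())[subj_idx]
                       + rng.normal(0, 0.4, n))
    fast = fit_lme_per_feature(feats, vdf, engine="fast")
    sm = fit_lme_per_feature(feats, vdf, engine="statsmodels")
    assert np.allclose(fast.table.beta_age, sm.table.beta_age, atol=1e-5)
    assert np.allclose(fast.table.t, sm.table.t, rtol=0.05, atol=0.05)


def test_constant_feature_gets_absent_statistics(vdf):
    feats = np.column_stack([np.ones(len(vdf)), 2.0 * vdf.age.to_numpy()])
    res = fit_lme_per_feature(feats, vdf)
    assert np.isnan(res.table.p.iloc[0])
    assert not res.table.significant.iloc[0]
    assert res.table.p.iloc[1] < 1e-10


def test_subject_order_invariance(vdf, rng):
    y = (0.1 * vdf.age + rng.normal(0, 0.5, len(vdf))).to_numpy()
    res1 = fit_lme_per_feature(y[:, None], vdf)
    perm = rng.permutation(len(vdf))
    res2 = fit_lme_per_feature(y[perm][:, None], vdf.iloc[perm].reset_index(drop=True))
    assert res1.table.t.iloc[0] == pytest.approx(res2.table.t.iloc[0], abs=1e-6)


def test_quadratic_age_exact(vdf):
    y = (vdf.age.to_numpy() - 20.0)**2
    res = fit_quadratic_age(y[:, None], vdf)
    assert res.table.beta_age.iloc[0] == pytest.approx(1.0, abs=1e-6)
    assert res.model_terms["coefficient"] == "age2"


def test_quadratic_null_on_linear_feature(vdf, rng):
    feats = np.empty((len(vdf), 300))
    subj_idx = pd.factorize(vdf.subject_id)[0]
    for j in range(300):
        feats[:, j] = (0.2 * vdf.age
                       + rng.normal(0, 0.5, vdf.subject_id.nunique())[subj_idx]
                       + rng.normal(0, 0.5, len(vdf)))
    res = fit_quadratic_age(feats, vdf)
    rate = (res.table.p < 0.05).mean()
    assert 0.01 <= rate <= 0.1


def test_fdr_closed_forms():
    q, mask = fdr_correct(np.array([0.01, 0.04]))
    assert np.allclose(q, [0.02, 0.04])
    q, _ = fdr_correct(np.full(5, 0.03))
    assert np.allclose(q, 0.03)
    p = np.random.default_rng(0).uniform(size=50)
    q, _ = fdr_correct(p)
    assert (q >= p - 1e-12).all()
    q, mask = fdr_correct(np.array([]))
    assert len(q) == 0 and len(mask) == 0


def test_residualize_features(rng):
    n = 40
    f = rng.normal(0, 1, (n, 3))
    r = residualize_features(f, [f])  # covariate equals the feature
    assert np.allclose(r, 0.0, atol=1e-10)
    cov = rng.normal(0, 1, (n, 3))
    r2 = residualize_features(f, [cov])
    for j in range(3):
        assert abs(np.dot(r2[:, j], cov[:, j])) < 1e-8
        assert abs(r2[:, j].sum()) < 1e-8


def test_stratify_map_group_means(rng):
    values = rng.normal(0, 1, 30)
    classes = np.array((["a"] * 10) + (["b"] * 10) + (["c"] * 10))
    out = stratify_map(values, classes)
    assert out.set_index("class").loc["b", "mean"] == pytest.approx(values[10:20].mean())
    const = stratify_map(np.full(30, 2.5), classes)
    assert np.allclose(const["mean"], 2.5)
    ind = stratify_map((classes == "a").astype(float), classes)
    assert ind.set_index("class").loc["a", "mean"] == 1.0
    assert ind.set_index("class").loc["c", "mean"] == 0.0


def test_interaction_recovers_slope_difference(vdf, rng):
    # reference-coded against the first level (F): beta = slope_M - slope_F
    slopes = vdf.sex.map({"M": 2.0, "F": 1.0}).to_numpy()
    y = slopes * vdf.age.to_numpy() + rng.normal(0, 1e-6, len(vdf))
    beta, t, p = interaction_test(y, vdf, moderator="sex")
    assert beta == pytest.approx(1.0, abs=1e-3)
    assert p < 1e-6
    y0 = 1.5 * vdf.age.to_numpy() + rng.normal(0, 0.3, len(vdf))
    beta0, _, p0 = interaction_test(y0, vdf, moderator="sex")
    assert abs(beta0) < 0.1


def test_interaction_null_calibration(vdf, rng):
    hits = 0
    n_rep = 100
    subj_idx = pd.factorize(vdf.subject_id)[0]
    for j in range(n_rep):
        y = (0.2 * vdf.age
             + rng.normal(0, 0.5, vdf.subject_id.nunique())[subj_idx]
             + rng.normal(0, 0.5, len(vdf)))
        _, _, p = interaction_test(y.to_numpy(), vdf, moderator="sex")
        hits += p < 0.05
    assert hits / n_rep <= 0.12


def test_interaction_constant_moderator_rejected(vdf):
    vdf2 = vdf.copy()
    vdf2["sex"] = "F"
    with pytest.raises(ValueError, match="constant"):
        interaction_test(np.zeros(len(vdf2)), vdf2, moderator="sex")


def test_age_bin_stratification(vdf, rng):
    y = rng.normal(0, 1, len(vdf))
    out = age_bin_stratify(y, vdf)
    assert len(out) == 5
    ages = vdf.age.to_numpy()
    in_second = (ages >= 17) & (ages < 19)
    if in_second.any():
        assert out["mean"].iloc[1] == pytest.approx(y[in_second].mean())
    single = vdf.copy()
    single["age"] = 18.0
    out2 = age_bin_stratify(y, single)
    assert out2.n.tolist() == [0, len(vdf), 0, 0, 0]
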