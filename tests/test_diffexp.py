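import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from npxcc.diffexp import (
    ModerationParams,
    PairedContrast,
    ProteinFits,
    bh_fdr,
    build_design,
    estimate_moderation,
    fit_linear_models,
    moderate,
    paired_de,
    run_de,
)
from npxcc.exceptions import IntegrityError
from npxcc.simulate import SimConfig, null_config, simulate_cohorts

from conftest import make_npx


def _fits_from_sim(n_prot=20, n=50, seed=0, d0=4.0, s0=0.25):
    """OLS fits on simulated two-group data (shared design, no covariates)."""
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, n).astype(float)
    design = pd.DataFrame(
        {"intercept": 1.0, "group": group}, index=[f"s{i}" for i in range(n)]
    )
    sig2 = d0 * s0 / rng.chisquare(d0, n_prot)
    y = pd.DataFrame(
        rng.normal(size=(n, n_prot)) * np.sqrt(sig2),
        index=design.index,
        columns=[f"p{i}" for i in range(n_prot)],
    )
    return fit_linear_models(y, design), y, design


def test_two_group_beta_equals_mean_difference():
    rng = np.random.default_rng(1)
    n = 40
    group = np.repeat([0.0, 1.0], n // 2)
    y = pd.DataFrame({"p1": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)])
    design = pd.DataFrame({"intercept": 1.0, "group": group}, index=y.index)
    fits = fit_linear_models(y, design)
    expected = y["p1"][group == 1].mean() - y["p1"][group == 0].mean()
    assert fits.beta[0, fits.coef_index("group")] == pytest.approx(expected, abs=1e-12)


def test_constant_response_zero_slope_zero_variance():
    y = pd.DataFrame({"p1": [3.0] * 10}, index=[f"s{i}" for i in range(10)])
    design = pd.DataFrame(
        {"intercept": 1.0, "x": np.arange(10, dtype=float)}, index=y.index
    )
    fits = fit_linear_models(y, design)
    assert fits.beta[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-20)


def test_continuous_covariate_slope_recovered():
    rng = np.random.default_rng(2)
    n = 200
    age = rng.uniform(18, 65, n)
    y = pd.DataFrame({"p1": 0.5 * age + rng.normal(0, 0.01, n)},
                     index=[f"s{i}" for i in range(n)])
    design = pd.DataFrame({"intercept": 1.0, "age": age}, index=y.index)
    fits = fit_linear_models(y, design)
    j = fits.coef_index("age")
    assert abs(fits.beta[0, j] - 0.5) < 3 * fits.se[0, j]


def test_missing_response_handled_pairwise():
    rng = np.random.default_rng(3)
    n = 30
    y = pd.DataFrame(rng.normal(size=(n, 2)), index=[f"s{i}" for i in range(n)],
                     columns=["p1", "p2"])
    y.iloc[:5, 1] = np.nan
    design = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)}, index=y.index)
    fits = fit_linear_models(y, design)
    assert fits.n_used[0] == n and fits.n_used[1] == n - 5
    assert fits.df_resid[1] == n - 5 - 2


def test_moderation_d0_zero_reproduces_classical_ols():
    """No-shrinkage limit: moderated t equals the OLS t computed protein by
    protein with an independent implementation, to 1e-10 relative error."""
    fits, y, design = _fits_from_sim()
    mod = moderate(fits, ModerationParams(d0=0.0, s0_sq=1.0), "group")
    x = design.to_numpy()
    for i, prot in enumerate(fits.proteins):
        # independent one-protein OLS oracle
        yv = y[prot].to_numpy()
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ yv
        resid = yv - x @ beta
        df = len(yv) - 2
        s2 = resid @ resid / df
        t_ols = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
        p_ols = 2 * stats.t.sf(abs(t_ols), df)
        assert mod["t_mod"].iloc[i] == pytest.approx(t_ols, rel=1e-10)
        assert mod["p"].iloc[i] == pytest.approx(p_ols, rel=1e-10)


def test_moderation_matches_direct_shrinkage_formula():
    """Moderated t on a 20-protein fixture equals an independently coded
    one-protein-at-a-time shrinkage computation."""
    fits, _, _ = _fits_from_sim()
    params = estimate_moderation(fits)
    mod = moderate(fits, params, "group")
    for i in range(len(fits.proteins)):
        df = fits.df_resid[i]
        s2_post = (params.d0 * params.s0_sq + df * fits.sigma2[i]) / (params.d0 + df)
        t_direct = fits.beta[i, 1] / (fits.stdev_unscaled[i, 1] * np.sqrt(s2_post))
        p_direct = 2 * stats.t.sf(abs(t_direct), params.d0 + df)
        assert mod["t_mod"].iloc[i] == pytest.approx(t_direct, rel=1e-12)
        assert mod["p"].iloc[i] == pytest.approx(p_direct, rel=1e-12)


def test_moderation_d0_infinite_pools_variance():
    fits, _, _ = _fits_from_sim()
    mod = moderate(fits, ModerationParams(d0=np.inf, s0_sq=0.3), "group")
    assert np.allclose(mod["s2_post"], 0.3)


def test_equal_variances_give_infinite_prior_df():
    fits = ProteinFits(
        proteins=pd.Index([f"p{i}" for i in range(20)]),
        coef_names=["intercept"],
        beta=np.zeros((20, 1)),
        stdev_unscaled=np.ones((20, 1)),
        sigma2=np.full(20, 0.4),
        df_resid=np.full(20, 30.0),
        n_used=np.full(20, 31),
    )
    params = estimate_moderation(fits)
    assert np.isinf(params.d0)
    assert params.s0_sq == pytest.approx(0.4, rel=1e-6)


def test_few_proteins_flagged_low_confidence():
    fits = ProteinFits(
        proteins=pd.Index(["p1", "p2"]),
        coef_names=["intercept"],
        beta=np.zeros((2, 1)),
        stdev_unscaled=np.ones((2, 1)),
        sigma2=np.array([0.2, 0.9]),
        df_resid=np.full(2, 10.0),
        n_used=np.full(2, 11),
    )
    with pytest.warns(UserWarning, match="low confidence"):
        params = estimate_moderation(fits)
    assert params.low_confidence


def test_moderation_prior_recovery():
    """(d0, s0^2) recovered from 500 scaled-inverse-chi-squared variances."""
    rng = np.random.default_rng(12)
    d0, s0 = 4.0, 0.25
    sig2 = d0 * s0 / rng.chisquare(d0, 500)
    s2 = sig2 * rng.chisquare(100, 500) / 100
    fits = ProteinFits(
        proteins=pd.Index([f"p{i}" for i in range(500)]),
        coef_names=["intercept"],
        beta=np.zeros((500, 1)),
        stdev_unscaled=np.ones((500, 1)),
        sigma2=s2,
        df_resid=np.full(500, 100.0),
        n_used=np.full(500, 101),
    )
    params = estimate_moderation(fits)
    assert 2.5 <= params.d0 <= 6.5
    assert abs(params.s0_sq - s0) / s0 <= 0.15


def test_bh_fdr_step_up_definition():
    """Matches the brute-force q_(i) = min_{j>=i} m p_(j)/j definition."""
    def brute(p):
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            q[idx] = min(
                min(m * p[j] / (list(order).index(j) + 1) for j in order[rank - 1:]), 1.0
            )
        return q

    for p in ([0.01, 0.02, 0.03, 0.04], [0.5], [1.0, 1.0, 1.0], [0.04, 0.001, 0.9, 0.2]):
        assert np.allclose(bh_fdr(p), brute(p), atol=1e-12)
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_fdr([]).size == 0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20))
def test_bh_fdr_permutation_equivariant_and_monotone(p):
    p = np.array(p)
    q = bh_fdr(p)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(p))
    assert np.allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_run_de_antisymmetric_under_cohort_swap(small_pair):
    a, b, meta, _ = small_pair
    de_ab = run_de(a, b, meta, covariates=("age", "sex"))
    de_ba = run_de(b, a, meta, covariates=("age", "sex"))
    assert np.allclose(de_ab.table["log2_fc"], -de_ba.table["log2_fc"], atol=1e-10)


def test_run_de_missing_covariate_in_one_cohort_named(small_pair):
    a, b, meta, _ = small_pair
    meta = meta.copy()
    meta.loc[meta["cohort"] == b.cohort, "bmi"] = np.nan
    with pytest.raises(IntegrityError, match="bmi"):
        run_de(a, b, meta, covariates=("age", "sex", "bmi"))


def test_run_de_effect_estimates_unbiased():
    """Mean signed error of log2 FC over replicates within 2 MC SEs of 0."""
    errs = []
    effects = {"prot005": 0.8, "prot011": -0.5}
    for r in range(30):
        cfg = null_config(seed=300 + r, n_a=80, n_b=100, n_proteins=16,
                          cohort_effects=effects)
        a, b, meta, _ = simulate_cohorts(cfg)
        de = run_de(a, b, meta)
        for p, e in effects.items():
            errs.append(de.table.loc[p, "log2_fc"] - e)
    errs = np.array(errs)
    mc_se = errs.std(ddof=1) / np.sqrt(len(errs))
    assert abs(errs.mean()) < 2 * mc_se + 1e-9


def test_de_summary_and_volcano_shapes(small_pair):
    a, b, meta, _ = small_pair
    de = run_de(a, b, meta)
    assert set(de.counts) == {"up", "down", "ns"}
    assert sum(de.counts.values()) == len(de.table)
    vol = de.volcano_table()
    assert {"log2_fc", "neg_log10_fdr"} <= set(vol.columns)
    assert de.summary()["fdr"].is_monotonic_increasing


def test_paired_contrast_degenerate_and_reversal():
    rng = np.random.default_rng(4)
    n = 10
    pre_vals = pd.DataFrame(rng.normal(5, 1, (n, 3)), columns=["p1", "p2", "p3"],
                            index=[f"pre{i}" for i in range(n)])
    post_vals = pre_vals.copy()
    post_vals.index = [f"post{i}" for i in range(n)]
    pre = make_npx(pre_vals)
    post = make_npx(post_vals)
    pairing = {f"post{i}": f"pre{i}" for i in range(n)}
    res = paired_de(pre, post, pairing)
    assert np.allclose(res["beta"], 0.0)
    assert (res["p"] == 1.0).all() and res["degenerate"].all()

    post2_vals = pre_vals + rng.normal(0.5, 0.2, (n, 3))
    post2_vals.index = [f"post{i}" for i in range(n)]
    post2 = make_npx(post2_vals)
    fwd = paired_de(pre, post2, pairing)
    rev = paired_de(post2, pre, {v: k for k, v in pairing.items()})
    assert np.allclose(fwd["beta"], -rev["beta"], atol=1e-12)


def test_paired_contrast_recovers_intervention_effect():
    """A -1.87 log2 within-subject shift at n=23 (noise sd 0.3) is recovered
    within +/-0.2, as in a two-week dietary-switch design."""
    rng = np.random.default_rng(9)
    n = 23
    pre_vals = pd.DataFrame({"p1": rng.normal(6, 1, n)}, index=[f"pre{i}" for i in range(n)])
    post_vals = pd.DataFrame(
        {"p1": pre_vals["p1"].to_numpy() - 1.87 + rng.normal(0, 0.3, n)},
        index=[f"post{i}" for i in range(n)],
    )
    res = paired_de(make_npx(pre_vals), make_npx(post_vals),
                    {f"post{i}": f"pre{i}" for i in range(n)})
    assert res.loc["p1", "beta"] == pytest.approx(-1.87, abs=0.2)
    assert res.loc["p1", "p"] < 0.01


def test_paired_contrast_unpaired_sample_listed():
    pre = make_npx(pd.DataFrame({"p1": [1.0, 2.0]}, index=["a", "b"]))
    post = make_npx(pd.DataFrame({"p1": [1.0, 2.0]}, index=["c", "d"]))
    with pytest.raises(IntegrityError, match="d"):
        PairedContrast(pre, post, {"c": "a"})
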