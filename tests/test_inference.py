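import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from songsel.inference import (
    RSLongTable,
    _design_matrices,
    _neg2_reml,
    build_long_table,
    fit_random_intercept_model,
    fixed_effects_at,
    levene_test,
    mann_whitney_u,
    n_exact_assignments,
    neg2_reml_dense,
    permutation_interaction_test,
)

SONGS = [
    (f"{t}-{i}", t, d) for t in ("CON", "HET") for i in (1, 2, 3) for d in ("FOR", "REV")
]


def lmm_table(rng, n_birds=12, n_units=8, sd_bird=0.5, sd_unit=0.3, sd_resid=1.0,
              interaction=0.0):
    """Long table drawn straight from the linear mixed model."""
    rows = []
    for b in range(n_birds):
        grp = "ZF-ZF" if b < n_birds // 2 else "ZF-CF"
        eb = rng.normal(0.0, sd_bird)
        for u in range(n_units):
            eu = rng.normal(0.0, sd_unit)
            for sid, stype, d in SONGS:
                y = 1.0 + eb + eu + rng.normal(0.0, sd_resid)
                if grp == "ZF-ZF" and stype == "CON":
                    y += interaction
                rows.append((f"b{b:02d}", grp, f"b{b:02d}u{u}", sid, stype, d, y))
    return pd.DataFrame(
        rows,
        columns=["bird_id", "group", "unit_id", "song_id", "song_type", "direction", "mean_rs"],
    )


# --- long table / transform ------------------------------------------------


def test_log_offset_rules():
    base = lmm_table(np.random.default_rng(0), n_birds=2, n_units=1)
    df = base.copy()
    df["mean_rs"] = np.linspace(1.0, 5.0, len(df))  # min exactly 1 -> pure log
    t = build_long_table(df)
    assert t.offset == 0.0
    np.testing.assert_allclose(t.data["transformed_rs"], np.log(df["mean_rs"]))

    df.loc[df.index[0], "mean_rs"] = -3.0
    t = build_long_table(df)
    assert t.offset == pytest.approx(4.0)
    assert t.data["transformed_rs"].min() == pytest.approx(0.0)  # ln(1)

    t = build_long_table(df, transform="identity")
    np.testing.assert_array_equal(t.data["transformed_rs"], df["mean_rs"])
    with pytest.raises(ValueError):
        build_long_table(df.iloc[0:0])


# --- REML ------------------------------------------------------------------


def test_reml_objective_matches_dense_oracle():
    """The Woodbury-factored objective equals a direct dense evaluation."""
    table = build_long_table(lmm_table(np.random.default_rng(1), 4, 3), "identity")
    y, X, Zb, Zu, _ = _design_matrices(table)
    Z = np.hstack([Zb, Zu])
    args = (y, X, Z, Z.T @ Z, Z.T @ y, Z.T @ X, Zb.shape[1])
    for vb, vu, ve in [(0.5, 0.3, 1.0), (0.01, 2.0, 0.4), (1e-5, 1e-5, 1.0)]:
        a = _neg2_reml(np.log([vb, vu, ve]), *args)
        b = neg2_reml_dense(table, vb, vu, ve)
        assert a == pytest.approx(b, rel=1e-9)


def test_reml_optimum_beats_grid_oracle():
    """On a 2-bird-per-group toy problem the fit's objective value is no
    worse than an exhaustive grid search of the dense objective."""
    table = build_long_table(lmm_table(np.random.default_rng(2), 4, 2), "identity")
    fit = fit_random_intercept_model(table)
    ours = -2.0 * fit.loglik_reml
    grid = np.geomspace(1e-3, 4.0, 12)
    best = min(
        neg2_reml_dense(table, vb, vu, ve)
        for vb in grid for vu in grid for ve in grid
    )
    assert ours <= best + 1e-6


def test_reml_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.formula.api")
    table = build_long_table(lmm_table(np.random.default_rng(3)), "identity")
    fit = fit_random_intercept_model(table)
    y, X, _, _, names = _design_matrices(table)
    d = table.data.copy()
    d["y"] = y
    for j in range(1, X.shape[1]):
        d[f"x{j}"] = X[:, j]
    rhs = " + ".join(f"x{j}" for j in range(1, X.shape[1]))
    mf = sm.mixedlm(
        f"y ~ {rhs}", d, groups="bird_id", re_formula="1",
        vc_formula={"unit": "0 + C(unit_id)"},
    ).fit(reml=True, method="lbfgs")
    assert fit.var_bird == pytest.approx(float(mf.cov_re.iloc[0, 0]), rel=0.05, abs=0.01)
    assert fit.var_unit == pytest.approx(float(mf.vcomp[0]), rel=0.05, abs=0.01)
    assert fit.var_resid == pytest.approx(float(mf.scale), rel=0.02)
    np.testing.assert_allclose(fit.beta.to_numpy(), mf.fe_params, atol=0.02)


def test_reml_zero_variance_data_hits_boundary():
    """With no true random effects the component estimates sit near zero."""
    table = build_long_table(
        lmm_table(np.random.default_rng(4), sd_bird=0.0, sd_unit=0.0), "identity"
    )
    fit = fit_random_intercept_model(table)
    assert fit.var_bird < 0.02
    assert fit.var_unit < 0.02
    assert fit.var_resid == pytest.approx(1.0, rel=0.15)


def test_gls_at_zero_variances_equals_ols():
    table = build_long_table(lmm_table(np.random.default_rng(5), 4, 3), "identity")
    y, X, _, _, _ = _design_matrices(table)
    beta = fixed_effects_at(table, 0.0, 0.0, 1.0)
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(beta.to_numpy(), ols, atol=1e-6)


def test_reml_requires_two_birds_per_group():
    df = lmm_table(np.random.default_rng(6), n_birds=2, n_units=2)
    df = df[df["bird_id"] != "b01"]  # leaves 1 ZF-ZF bird
    with pytest.raises(ValueError):
        fit_random_intercept_model(build_long_table(df, "identity"))


# --- permutation test ------------------------------------------------------


def test_exact_assignment_count_six_vs_six():
    assert n_exact_assignments(12, 6) == 924
    r = permutation_interaction_test(
        build_long_table(lmm_table(np.random.default_rng(7)), "identity"),
        value_col="transformed_rs",
    )
    assert r.exact and r.n_permutations == 924


def test_exact_and_monte_carlo_modes_agree():
    df = lmm_table(np.random.default_rng(8), n_birds=12, n_units=4, interaction=0.4)
    exact = permutation_interaction_test(df, method="exact")
    mc = permutation_interaction_test(df, n_perm=8000, seed=0, method="monte_carlo")
    assert exact.exact and not mc.exact
    assert mc.statistic == pytest.approx(exact.statistic)
    se = math.sqrt(exact.p_value * (1 - exact.p_value) / 8000)
    assert abs(mc.p_value - exact.p_value) < max(4 * se, 0.005)


def test_permutation_statistic_definition():
    """T equals the group difference of bird-mean (CON - HET) by hand."""
    df = lmm_table(np.random.default_rng(9), n_birds=4, n_units=2, interaction=1.0)
    r = permutation_interaction_test(df)
    means = df.groupby(["bird_id", "song_type"])["mean_rs"].mean().unstack()
    diff = means["CON"] - means["HET"]
    grp = df.groupby("bird_id")["group"].first()
    expected = diff[grp == "ZF-CF"].mean() - diff[grp == "ZF-ZF"].mean()
    assert r.statistic == pytest.approx(expected)


def test_permutation_requires_two_birds_per_group():
    df = lmm_table(np.random.default_rng(10), n_birds=2, n_units=2)
    df = df[df["bird_id"] != "b00"]
    with pytest.raises(ValueError):
        permutation_interaction_test(df)
    with pytest.raises(ValueError):  # Monte-Carlo mode needs a seed
        big = pd.concat(
            [lmm_table(np.random.default_rng(11), 26, 1)], ignore_index=True
        )
        permutation_interaction_test(big, seed=None)


def test_permutation_detects_strong_interaction():
    df = lmm_table(np.random.default_rng(12), interaction=2.0)
    r = permutation_interaction_test(df)
    assert r.p_value <= 0.01


# --- Mann-Whitney ----------------------------------------------------------


def test_mann_whitney_exact_textbook_case():
    """x = (1,2,3) vs y = (4,5,6): U = 0 and one-sided p = 1/20."""
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
    assert u == 0.0
    assert p == pytest.approx(1.0 / 20.0)


def test_mann_whitney_identical_samples_with_ties():
    x = [1.0, 2.0, 2.0, 3.0, 5.0] * 3
    u, p = mann_whitney_u(x, list(x))
    assert u == pytest.approx(len(x) ** 2 / 2.0)
    assert p > 0.9


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mann_whitney_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    # exact branch: small samples, no ties
    x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 7)
    for alt in ("two-sided", "greater", "less"):
        u, p = mann_whitney_u(x, y, alternative=alt)
        ref = stats.mannwhitneyu(x, y, alternative=alt, method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
    # normal-approximation branch with ties
    x = np.round(rng.normal(0, 1, 40), 1)
    y = np.round(rng.normal(0.3, 1, 35), 1)
    u, p = mann_whitney_u(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert u == ref.statistic
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_mann_whitney_separated_samples():
    rng = np.random.default_rng(13)
    _, p = mann_whitney_u(rng.normal(0, 1, 80), rng.normal(2, 1, 80))
    assert p < 1e-3
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# --- Levene (Brown-Forsythe) ----------------------------------------------


def test_levene_identical_groups():
    g = [1.0, 2.0, 3.0, 4.0]
    w, p = levene_test(g, list(g))
    assert w == 0.0
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_levene_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    groups = [rng.normal(0, s, n) for s, n in ((1, 20), (2, 25), (0.5, 15))]
    w, p = levene_test(*groups)
    ref = stats.levene(*groups, center="median")
    assert w == pytest.approx(ref.statistic, rel=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-12)


def test_levene_detects_ninefold_variance_ratio():
    rng = np.random.default_rng(14)
    hits = 0
    for _ in range(20):
        _, p = levene_test(rng.normal(0, 1, 50), rng.normal(0, 3, 50))
        hits += p < 0.01
    assert hits >= 19


def test_levene_degenerate_groups_rejected():
    with pytest.raises(ValueError):
        levene_test([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        levene_test([1.0, 2.0])
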