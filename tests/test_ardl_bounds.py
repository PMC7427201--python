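import numpy as np
import pytest

from bardl import (
    ARDLSpec,
    AnnualSeries,
    Dataset,
    DummySpec,
    bootstrap_critical_values,
    bounds_test,
    build_ecm_design,
    classify_outcome,
    compute_bounds_statistics,
    estimate_ecm,
    select_lags,
    simulate_trivariate,
    wald_f,
    DGPConfig,
)
from bardl.ardl_bounds import BootstrapCriticalValues, BoundsStatistics
from bardl.exceptions import (
    CollinearityError,
    ComparisonError,
    ReplicationError,
    SizeError,
    SpecificationError,
)
from conftest import TABLE3


def _stats(f, t, find):
    return BoundsStatistics(F_overall=f, t_dep=t, F_indep=find,
                            df_num_overall=3, df_num_indep=2, df_den=10)


def _cvs(f, t, find, alpha=0.05):
    return BootstrapCriticalValues(alpha=alpha, B=199, f_star=f, t_star=t,
                                   f_indep_star=find, seed=0, scheme="fixture")


# ---------------------------------------------------------------- design

def test_design_layout_counts(rng):
    n = 24
    years = np.arange(1992, 1992 + n)
    data = Dataset(tuple(
        AnnualSeries(nm, years, np.cumsum(rng.standard_normal(n)))
        for nm in ("y", "x", "z")
    ))
    spec = ARDLSpec("y", ("x", "z"), p=1, q=(1, 1), dummies=DummySpec((2003, 2007, 2011)))
    X, dy, names, groups = build_ecm_design(data, spec)
    assert X.shape == (22, 7)          # const + 3 levels + 3 dummies, n - 1 - 1 rows
    assert dy.shape == (22,)
    assert names[:4] == ("const", "y.L1", "x.L1", "z.L1")
    assert names[4:] == ("D2003", "D2007", "D2011")

    spec2 = ARDLSpec("y", ("x", "z"), p=2, q=(1, 1))
    X2, _, names2, _ = build_ecm_design(data, spec2)
    assert X2.shape == (21, 5) and "dy.L1" in names2


def test_duplicate_independent_rejected():
    with pytest.raises(SpecificationError):
        ARDLSpec("y", ("x", "x"), p=1, q=(1, 1))


def test_exact_collinearity_names_columns(rng):
    n = 40
    years = np.arange(1980, 1980 + n)
    x = np.cumsum(rng.standard_normal(n))
    data = Dataset((
        AnnualSeries("y", years, np.cumsum(rng.standard_normal(n))),
        AnnualSeries("x", years, x),
        AnnualSeries("z", years, 2.0 * x),     # exact multiple of x
    ))
    with pytest.raises(CollinearityError) as exc:
        build_ecm_design(data, ARDLSpec("y", ("x", "z"), 1, (1, 1)))
    assert exc.value.columns


def test_sample_size_gate():
    years = np.arange(2000, 2012)
    data = Dataset(tuple(
        AnnualSeries(nm, years, np.arange(12.0) + i + np.sin(np.arange(12) + i))
        for i, nm in enumerate(("y", "x", "z"))
    ))
    with pytest.raises(SizeError):
        build_ecm_design(data, ARDLSpec("y", ("x", "z"), p=3, q=(3, 3)))


# ---------------------------------------------------------------- estimation

def test_zero_noise_coefficients_recovered_exactly(rng):
    """Data generated exactly from the ECM is interpolated to machine precision."""
    n = 40
    years = np.arange(1970, 1970 + n)
    x = 5 + np.cumsum(rng.standard_normal(n))
    z = 3 + np.cumsum(rng.standard_normal(n))
    true = {"const": 0.3, "y.L1": -0.4, "x.L1": 0.2, "z.L1": 0.1, "dx.L1": 0.5}
    y = np.empty(n)
    y[:2] = (1.0, 1.5)
    for t in range(2, n):
        dy = (true["const"] + true["y.L1"] * y[t - 1] + true["x.L1"] * x[t - 1]
              + true["z.L1"] * z[t - 1] + true["dx.L1"] * (x[t - 1] - x[t - 2]))
        y[t] = y[t - 1] + dy
    data = Dataset((AnnualSeries("y", years, y), AnnualSeries("x", years, x),
                    AnnualSeries("z", years, z)))
    fit = estimate_ecm(data, ARDLSpec("y", ("x", "z"), p=1, q=(2, 1)))
    for name, v in true.items():
        assert fit.coef(name) == pytest.approx(v, abs=1e-8)
    lrm = fit.long_run_multipliers
    assert lrm["x"] == pytest.approx(-0.2 / -0.4, abs=1e-8)
    assert lrm["z"] == pytest.approx(-0.1 / -0.4, abs=1e-8)


def test_ols_matches_normal_equations_oracle(random_walk_dataset):
    """lstsq solution equals the brute-force (X'X)^{-1}X'y oracle."""
    fit = estimate_ecm(random_walk_dataset, ARDLSpec("gdp", ("le", "alc"), 2, (2, 2)))
    X, y = fit.X, fit.y
    beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(fit.params, beta_oracle, atol=1e-8)
    # residual orthogonality
    assert np.abs(X.T @ fit.resid).max() <= 1e-8 * (1 + np.abs(X.T @ y).max())


def test_wald_f_equals_rss_oracle(rng):
    """Covariance-form Wald F == ((RSS_r-RSS_u)/m)/(RSS_u/(T-k)), 100 instances."""
    for i in range(100):
        r = np.random.default_rng(5000 + i)
        n = 45
        years = np.arange(1960, 1960 + n)
        data = Dataset(tuple(
            AnnualSeries(nm, years, np.cumsum(r.standard_normal(n)))
            for nm in ("y", "x", "z")
        ))
        fit = estimate_ecm(data, ARDLSpec("y", ("x", "z"), 2, (2, 2)))
        st = compute_bounds_statistics(fit)
        X, y = fit.X, fit.y
        T, k = X.shape

        def rss(cols_dropped):
            keep = [j for j in range(k) if j not in cols_dropped]
            b, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
            e = y - X[:, keep] @ b
            return e @ e

        rss_u = fit.rss
        for F, drop in ((st.F_overall, fit.groups["levels"]),
                        (st.F_indep, fit.groups["level_indep"])):
            F_oracle = ((rss(drop) - rss_u) / len(drop)) / (rss_u / (T - k))
            assert F == pytest.approx(F_oracle, abs=1e-8, rel=1e-8)


def test_statistics_invariant_to_rescaling_regressor(random_walk_dataset):
    d = random_walk_dataset
    scaled = Dataset((d["gdp"], AnnualSeries("le", d.years, 10.0 * d["le"].values),
                      d["alc"]), country=d.country)
    spec = ARDLSpec("gdp", ("le", "alc"), 2, (2, 2))
    a = compute_bounds_statistics(estimate_ecm(d, spec))
    b = compute_bounds_statistics(estimate_ecm(scaled, spec))
    assert a.F_overall == pytest.approx(b.F_overall, abs=1e-8)
    assert a.t_dep == pytest.approx(b.t_dep, abs=1e-8)
    assert a.F_indep == pytest.approx(b.F_indep, abs=1e-8)


def test_single_independent_f_indep_is_squared_t(random_walk_dataset):
    d = random_walk_dataset
    two = Dataset((d["gdp"], d["le"]))
    fit = estimate_ecm(two, ARDLSpec("gdp", ("le",), 2, (2,)))
    st = compute_bounds_statistics(fit)
    i = fit.groups["level_indep"][0]
    t = fit.params[i] / np.sqrt(fit.cov_params[i, i])
    assert st.F_indep == pytest.approx(t**2, abs=1e-8)


def test_empty_restriction_errors(random_walk_dataset):
    fit = estimate_ecm(random_walk_dataset, ARDLSpec("gdp", ("le", "alc"), 1, (1, 1)))
    with pytest.raises(SpecificationError):
        wald_f(fit, [])


# ---------------------------------------------------------------- lag selection

def test_select_lags_singleton_grid(random_walk_dataset):
    spec = select_lags(random_walk_dataset, "gdp", ("le", "alc"), [1], [1])
    assert (spec.p, spec.q) == (1, (1, 1))


def test_select_lags_detects_genuine_short_run_effect():
    data = simulate_trivariate(DGPConfig.for_scenario("one_way_short_run", n=2000, seed=3))
    spec = select_lags(data, "gdp", ("le", "alc"), range(1, 4), range(1, 4))
    assert spec.q[0] >= 2          # the lagged d(le) term is real


def test_select_lags_prefers_parsimony_on_pure_noise():
    """On a pure random-walk system the SIC penalty favours small orders."""
    data = simulate_trivariate(DGPConfig.for_scenario("no_cointegration", n=1000, seed=9))
    spec = select_lags(data, "gdp", ("le", "alc"), range(1, 3), range(1, 3))
    assert spec.n_params <= ARDLSpec("gdp", ("le", "alc"), 2, (2, 2)).n_params


# ---------------------------------------------------------------- bootstrap

def test_bootstrap_deterministic_given_seed(random_walk_dataset):
    spec = ARDLSpec("gdp", ("le", "alc"), 2, (2, 2))
    a = bootstrap_critical_values(random_walk_dataset, spec, B=199, seed=77)
    b = bootstrap_critical_values(random_walk_dataset, spec, B=199, seed=77)
    assert (a.f_star, a.t_star, a.f_indep_star) == (b.f_star, b.t_star, b.f_indep_star)
    np.testing.assert_array_equal(a.replicates["F_overall"], b.replicates["F_overall"])
    c = bootstrap_critical_values(random_walk_dataset, spec, B=199, seed=78)
    assert a.f_star != c.f_star


def test_bootstrap_quantiles_monotone_in_alpha(random_walk_dataset):
    spec = ARDLSpec("gdp", ("le", "alc"), 2, (2, 2))
    cvs = {a: bootstrap_critical_values(random_walk_dataset, spec, B=499, alpha=a, seed=3)
           for a in (0.01, 0.05, 0.10)}
    assert cvs[0.01].f_star >= cvs[0.05].f_star >= cvs[0.10].f_star
    assert cvs[0.01].t_star <= cvs[0.05].t_star <= cvs[0.10].t_star
    assert cvs[0.01].f_indep_star >= cvs[0.05].f_indep_star >= cvs[0.10].f_indep_star


def test_bootstrap_requires_enough_replicates(random_walk_dataset):
    with pytest.raises(ReplicationError):
        bootstrap_critical_values(random_walk_dataset,
                                  ARDLSpec("gdp", ("le", "alc"), 1, (1, 1)), B=99)


def test_irrelevant_dummy_barely_moves_statistics():
    data = simulate_trivariate(DGPConfig.for_scenario("cointegration", n=50, seed=5))
    base = ARDLSpec("gdp", ("le", "alc"), 2, (2, 2))
    plus = ARDLSpec("gdp", ("le", "alc"), 2, (2, 2), dummies=DummySpec((2005,)))
    a = compute_bounds_statistics(estimate_ecm(data, base))
    b = compute_bounds_statistics(estimate_ecm(data, plus))
    assert abs(a.F_overall - b.F_overall) < 0.2 * abs(a.F_overall) + 1.0
    assert abs(a.t_dep - b.t_dep) < 0.2 * abs(a.t_dep) + 1.0
    # determinism contract unaffected by the extra dummy
    c1 = bootstrap_critical_values(data, plus, B=199, seed=4)
    c2 = bootstrap_critical_values(data, plus, B=199, seed=4)
    assert c1.f_star == c2.f_star


# ---------------------------------------------------------------- classification

@pytest.mark.parametrize("row,stats,cvs,expected", TABLE3)
def test_classifier_reproduces_published_truth_table(row, stats, cvs, expected):
    outcome = classify_outcome(_stats(*stats), _cvs(*cvs))
    assert outcome.label == expected, row


def test_classifier_tie_is_not_significant():
    o = classify_outcome(_stats(3.0, -2.0, 4.0), _cvs(3.0, -2.0, 4.0))
    assert o.label == "NO_COINTEGRATION"
    assert not (o.sig_F or o.sig_t or o.sig_F_indep)


def test_classifier_unenumerated_cell_warns():
    o = classify_outcome(_stats(5.0, -0.1, 1.0), _cvs(3.0, -2.0, 4.0))
    assert o.label == "NO_COINTEGRATION" and o.warning is not None


def test_classifier_alpha_mismatch():
    with pytest.raises(ComparisonError):
        classify_outcome(_stats(1, -1, 1), _cvs(1, -1, 1, alpha=0.10), alpha=0.05)


def test_degenerate_1_label():
    o = classify_outcome(_stats(5.0, -0.5, 6.0), _cvs(3.0, -2.0, 4.0))
    assert o.label == "DEGENERATE_1"


def test_bounds_test_end_to_end_cointegration():
    data = simulate_trivariate(DGPConfig.for_scenario("cointegration", n=60, seed=1))
    res = bounds_test(data, ARDLSpec("gdp", ("le", "alc"), 2, (2, 2)), B=199, seed=2)
    assert res.outcome.label == "COINTEGRATION"
    assert res.statistics.F_overall > res.critical_values.f_star
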