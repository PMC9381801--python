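import numpy as np
import pytest
from scipy import optimize

from spmixcopula import (
    CopulaModel,
    MixtureCopula,
    PredictionConfig,
    SpatialDataset,
    SpatialMixtureCopula,
    SupportError,
    conditional_level,
    fit_marginal,
    invert_conditional,
    predict_variable,
)

from conftest import binning_from_distances


def _single_bin_model(copulas, marginals):
    binning = binning_from_distances([50.0], 100.0, 1)
    w = np.full(len(copulas), 1.0 / len(copulas))
    return SpatialMixtureCopula(binning=binning,
                                bin_mixtures=[MixtureCopula(copulas, w)],
                                lambdas=[], marginals=marginals, weights=w,
                                names=["z1", "z2"][: len(marginals)])


def test_conditional_level_closed_forms(independence_model):
    model, _, _ = independence_model
    # independence region algebra: t = u * r
    assert conditional_level(model, 0.3, 0.7, 500.0) == pytest.approx(0.21)
    assert conditional_level(model, 0.3, 0.7, 10.0) == pytest.approx(0.21)
    # r = 1 margin: t = u
    assert conditional_level(model, 0.44, 1.0, 10.0) == pytest.approx(0.44, abs=1e-12)


def test_invert_conditional_product_region(independence_model):
    model, _, _ = independence_model
    # beyond the cut-off the conditional of s*r in r is s, so s = t
    assert invert_conditional(model, 0.21, 0.7, 500.0) == pytest.approx(0.21)
    # under an independence copula the same holds inside the bin
    assert invert_conditional(model, 0.21, 0.7, 10.0) == pytest.approx(0.21, abs=1e-8)


def test_invert_conditional_matches_bisection_oracle():
    rng = np.random.default_rng(6)
    marg = [fit_marginal(rng.gamma(3, 1, 150), "gamma"),
            fit_marginal(rng.gamma(2, 2, 150), "gamma")]
    cop = CopulaModel("clayton", (2.0,))
    model = _single_bin_model([cop, cop], marg)
    for t, r in [(0.3, 0.6), (0.8, 0.2), (0.05, 0.9)]:
        s = invert_conditional(model, t, r, 10.0)
        oracle = optimize.bisect(lambda x: float(model.hfunc(x, r, 10.0)) - t,
                                 1e-12, 1 - 1e-12, xtol=1e-10)
        assert s == pytest.approx(oracle, abs=1e-8)


def test_s_nondecreasing_in_t():
    cop = CopulaModel("gumbel", (1.6,))
    rng = np.random.default_rng(1)
    marg = [fit_marginal(rng.normal(0, 1, 100), "normal")] * 2
    model = _single_bin_model([cop, cop], marg)
    ts = np.linspace(0.01, 0.99, 25)
    s = np.asarray(invert_conditional(model, ts, 0.4, 10.0))
    assert np.all(np.diff(s) >= -1e-10)


def test_faithful_prediction_under_independence(independence_model):
    model, z1, z2 = independence_model
    ds = SpatialDataset(np.random.default_rng(0).uniform(0, 100, (200, 2)),
                        np.column_stack([z1, z2]), ["z1", "z2"])
    res = predict_variable(model, ds, PredictionConfig(target=0, mode="faithful"))
    f1, f2 = model.marginals
    expect = f1.quantile(np.clip(f1.cdf(z1) * f2.cdf(z2), 1e-10, 1 - 1e-10))
    assert np.allclose(res.predicted, expect, atol=1e-8)
    # intermediate quantities are consistent
    assert np.allclose(res.t, f1.cdf(z1) * f2.cdf(z2), atol=1e-10)
    assert np.allclose(res.s, res.t, atol=1e-8)


def test_median_prediction_under_independence(independence_model):
    model, z1, z2 = independence_model
    ds = SpatialDataset(np.random.default_rng(0).uniform(0, 100, (200, 2)),
                        np.column_stack([z1, z2]), ["z1", "z2"])
    res = predict_variable(model, ds, PredictionConfig(target=0, mode="median"))
    assert np.allclose(res.predicted, model.marginals[0].median(), atol=1e-8)


def test_subscript_swap_predicts_other_variable(independence_model):
    model, z1, z2 = independence_model
    ds = SpatialDataset(np.random.default_rng(0).uniform(0, 100, (200, 2)),
                        np.column_stack([z1, z2]), ["z1", "z2"])
    res = predict_variable(model, ds, PredictionConfig(target=1, mode="faithful"))
    f1, f2 = model.marginals
    expect = f2.quantile(np.clip(f2.cdf(z2) * f1.cdf(z1), 1e-10, 1 - 1e-10))
    assert np.allclose(res.predicted, expect, atol=1e-8)


def test_predictions_lie_in_marginal_support():
    rng = np.random.default_rng(10)
    marg = [fit_marginal(rng.gamma(3, 1, 200), "gamma"),
            fit_marginal(rng.normal(0, 1, 200), "normal")]
    model = _single_bin_model([CopulaModel("gumbel", (1.7,)),
                               CopulaModel("gaussian", (0.5,))], marg)
    ds = SpatialDataset(rng.uniform(0, 100, (200, 2)),
                        np.column_stack([rng.gamma(3, 1, 200), rng.normal(0, 1, 200)]),
                        ["z1", "z2"])
    res = predict_variable(model, ds, PredictionConfig(target=0, mode="faithful"))
    lo, hi = marg[0].support()
    assert np.all(res.predicted > lo) and np.all(res.predicted < hi)
    assert np.all((res.s > 0) & (res.s < 1))


def test_strong_dependence_recovers_observations():
    """With a near-comonotone copula and identical variables the
    inverse-conditional prediction reproduces the observed values almost
    exactly."""
    rng = np.random.default_rng(13)
    z = rng.normal(5, 2, 300)
    marg = [fit_marginal(z, "normal"), fit_marginal(z, "normal")]
    strong = CopulaModel("gaussian", (0.9999,))
    model = _single_bin_model([strong, strong], marg)
    ds = SpatialDataset(rng.uniform(0, 100, (300, 2)),
                        np.column_stack([z, z]), ["z1", "z2"])
    res = predict_variable(model, ds, PredictionConfig(target=0, mode="faithful"))
    assert np.sqrt(np.mean((res.predicted - z) ** 2)) < 0.05 * z.std()


def test_monotone_rescaling_of_secondary_is_equivariant():
    """Scaling the secondary variable (its marginal refitted within the
    same family) leaves predictions unchanged — the copula only sees
    quantiles."""
    rng = np.random.default_rng(21)
    z1 = rng.gamma(3, 1, 250)
    z2 = rng.lognormal(0.2, 0.5, 250)
    marg = [fit_marginal(z1, "gamma"), fit_marginal(z2, "lognormal")]
    marg_scaled = [marg[0], fit_marginal(3.0 * z2, "lognormal")]
    cop = [CopulaModel("frank", (4.0,)), CopulaModel("frank", (3.0,))]
    coords = rng.uniform(0, 100, (250, 2))
    ds = SpatialDataset(coords, np.column_stack([z1, z2]), ["z1", "z2"])
    ds_scaled = SpatialDataset(coords, np.column_stack([z1, 3.0 * z2]), ["z1", "z2"])
    a = predict_variable(_single_bin_model(cop, marg), ds,
                         PredictionConfig(target=0, mode="faithful"))
    b = predict_variable(_single_bin_model(cop, marg_scaled), ds_scaled,
                         PredictionConfig(target=0, mode="faithful"))
    assert np.allclose(a.predicted, b.predicted, atol=1e-6)


def test_h_policy_variants(independence_model):
    model, z1, z2 = independence_model
    coords = np.column_stack([np.arange(200.0), np.zeros(200)])
    ds = SpatialDataset(coords, np.column_stack([z1, z2]), ["z1", "z2"])
    fixed = predict_variable(model, ds, PredictionConfig(mode="median", h_policy="fixed",
                                                         h_value=500.0))
    assert np.all(fixed.h == 500.0)
    near = predict_variable(model, ds, PredictionConfig(mode="median", h_policy="nearest"))
    assert np.all(near.h == 1.0)  # unit-spaced transect
    with pytest.raises(SupportError):
        PredictionConfig(h_policy="fixed")
    with pytest.raises(SupportError):
        PredictionConfig(mode="other")
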