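"""Prior sampling, rejection, GLM adjustment and posterior summaries."""

import numpy as np
import pytest
from scipy import stats

from coalabc.abc import (
    PriorParam,
    PriorSpec,
    ReferenceTable,
    build_reference_table,
    default_bottleneck_priors,
    default_im_priors,
    glm_adjust,
    mode_and_hpdi,
    reject_nearest,
    sample_prior,
)
from coalabc.coalsim import SampleConfig
from coalabc.sumstats import AbcSummaryVector


def _toy_table(n, rng, sigma=1.0):
    priors = PriorSpec([PriorParam("theta", 0.0, 10.0, "linear")])
    X = sample_prior(priors, n, rng)
    S = X + rng.normal(0.0, sigma, size=(n, 1))
    tab = ReferenceTable("IM", priors.names, ("s",), X, S, np.ones(n, bool), 0)
    return priors, tab


def test_prior_uniform_mean(rng):
    spec = PriorSpec([PriorParam("x", 0.0, 1.0)])
    draws = sample_prior(spec, 100_000, rng)[:, 0]
    assert abs(draws.mean() - 0.5) < 3 * draws.std() / np.sqrt(draws.size)


def test_prior_log10_median(rng):
    spec = PriorSpec([PriorParam("n", 1e3, 1e6, "log10")])
    draws = sample_prior(spec, 100_000, rng)[:, 0]
    # uniform in the exponent: median at 10^4.5, tolerance from the
    # order-statistic SE of the median of U(3, 6)
    med = np.median(np.log10(draws))
    se = 1.2533 * (3.0 / np.sqrt(12)) / np.sqrt(draws.size)
    assert abs(med - 4.5) < 4 * se


def test_prior_reproducible_and_constrained():
    spec = default_bottleneck_priors()
    a = sample_prior(spec, 500, np.random.default_rng(9), constraint=lambda r: r["Tb"] > r["Te"])
    b = sample_prior(spec, 500, np.random.default_rng(9), constraint=lambda r: r["Tb"] > r["Te"])
    assert np.array_equal(a, b)
    assert np.all(a[:, spec.names.index("Tb")] > a[:, spec.names.index("Te")])


def test_reject_nearest_exact_match_first(rng):
    priors, tab = _toy_table(500, rng)
    obs = AbcSummaryVector("IM", ("s",), tab.summaries[123])
    ret = reject_nearest(tab, obs, 10)
    assert ret.indices[0] == 123 and ret.distances[0] == 0.0


def test_reject_all_keeps_prior(rng):
    priors, tab = _toy_table(20_000, rng)
    obs = AbcSummaryVector("IM", ("s",), np.array([5.0]))
    ret = reject_nearest(tab, obs, tab.n_rows)
    ks = stats.kstest(ret.params[:, 0], stats.uniform(0, 10).cdf)
    assert ks.statistic < 0.02


def test_reject_invalid_observed_rejected(rng):
    priors, tab = _toy_table(100, rng)
    obs = AbcSummaryVector("IM", ("s",), np.array([np.nan]))
    with pytest.raises(ValueError):
        reject_nearest(tab, obs, 10)


def test_retention_concentrates_around_truth(rng):
    """Shrinking the retained set concentrates parameters near truth."""
    priors, tab = _toy_table(20_000, rng, sigma=0.3)
    obs = AbcSummaryVector("IM", ("s",), np.array([4.0]))
    wide = reject_nearest(tab, obs, 10_000).params[:, 0]
    narrow = reject_nearest(tab, obs, 200).params[:, 0]
    assert np.abs(narrow - 4.0).mean() < np.abs(wide - 4.0).mean()


def test_glm_conjugate_posterior(rng):
    """Linear-Gaussian toy: GLM posterior matches the analytic truncated
    normal N(s_obs, sigma^2) on the prior support."""
    priors, tab = _toy_table(5000, rng, sigma=1.0)
    obs = AbcSummaryVector("IM", ("s",), np.array([4.3]))
    ret = reject_nearest(tab, obs, tab.n_rows)
    post = glm_adjust(ret, obs, priors, seed=5)
    s = post.joint_samples[:, 0]
    assert s.mean() == pytest.approx(4.3, abs=0.1)
    assert s.var() == pytest.approx(1.0, rel=0.15)
    m = post.marginals["theta"]
    assert m.hpdi_low == pytest.approx(4.3 - 1.96, abs=0.15)
    assert m.hpdi_high == pytest.approx(4.3 + 1.96, abs=0.15)


def test_glm_mode_at_symmetric_center(rng):
    priors, tab = _toy_table(4000, rng, sigma=0.5)
    obs = AbcSummaryVector("IM", ("s",), np.array([5.0]))
    ret = reject_nearest(tab, obs, 2000)
    post = glm_adjust(ret, obs, priors, seed=2)
    assert post.marginals["theta"].mode == pytest.approx(5.0, abs=0.3)


def test_loclinear_adjustment_available(rng):
    priors, tab = _toy_table(2000, rng)
    obs = AbcSummaryVector("IM", ("s",), np.array([5.0]))
    ret = reject_nearest(tab, obs, 500)
    post = glm_adjust(ret, obs, priors, seed=2, method="loclinear")
    assert post.method == "loclinear"
    assert 3.0 < post.marginals["theta"].mode < 7.0


def test_glm_needs_enough_rows(rng):
    priors, tab = _toy_table(100, rng)
    obs = AbcSummaryVector("IM", ("s",), np.array([5.0]))
    ret = reject_nearest(tab, obs, 20)
    with pytest.raises(ValueError):
        glm_adjust(ret, obs, priors, seed=0)


def test_mode_and_hpdi_uniform_width():
    grid = np.linspace(0, 1, 2001)
    dens = np.ones_like(grid)
    _, lo, hi, _ = mode_and_hpdi(grid, dens, level=0.95)
    assert (hi - lo) == pytest.approx(0.95, abs=0.01)


def test_mode_and_hpdi_point_mass():
    grid = np.linspace(0, 1, 101)
    dens = np.zeros_like(grid)
    dens[40] = 1.0
    mode, lo, hi, _ = mode_and_hpdi(grid, dens)
    assert mode == lo == hi == pytest.approx(0.4)


def test_mode_and_hpdi_flags_multimodal():
    grid = np.linspace(0, 1, 101)
    dens = np.exp(-0.5 * ((grid - 0.2) / 0.03) ** 2) + np.exp(
        -0.5 * ((grid - 0.8) / 0.03) ** 2
    )
    *_, multi = mode_and_hpdi(grid, dens)
    assert multi


def test_reference_table_smoke_and_determinism():
    priors = default_im_priors()
    cfg = SampleConfig((500,) * 2, (6, 6))
    a = build_reference_table("IM", priors, 30, cfg, seed=4)
    b = build_reference_table("IM", priors, 30, cfg, seed=4)
    assert a.n_valid >= 1
    assert np.array_equal(a.params, b.params)
    assert np.array_equal(a.summaries[a.valid], b.summaries[b.valid])


def test_reference_table_bottleneck_constraint():
    priors = default_bottleneck_priors()
    cfg = SampleConfig((500,), (8,))
    tab = build_reference_table("BOTTLENECK", priors, 20, cfg, seed=5)
    iTb, iTe = priors.names.index("Tb"), priors.names.index("Te")
    assert np.all(tab.params[:, iTb] > tab.params[:, iTe])
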