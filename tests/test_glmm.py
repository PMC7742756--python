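import math

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit

from methylsel.glmm import (
    DispersionRecord,
    GlmmConfig,
    GlmmFit,
    _MarginalLik,
    dispersion_lambda,
    filter_dispersion,
    glmm_site_fit,
    hpd_interval,
    family_site_tests,
)
from methylsel.pooled import pooled_site_test

F = 8
FAM_IDX = np.repeat(np.arange(F), 2)
FAMS = np.repeat([f"f{i}" for i in range(F)], 2)
IS_FE = np.tile([True, False], F)
X = IS_FE.astype(float)


def _draw_site(rng, beta0=0.0, beta1=0.0, sigma_fam=0.5, coverage=20):
    u = rng.normal(0, sigma_fam, F)
    p = expit(beta0 + u[FAM_IDX] + beta1 * X)
    if np.isscalar(coverage):
        n = np.full(2 * F, coverage)
    else:
        n = coverage
    c = rng.binomial(n, p)
    return c, n


def test_no_variation_gives_singular_null_fit():
    fit = glmm_site_fit([5] * 16, [10] * 16, IS_FE, FAMS)
    assert fit.flag == "singular"
    assert fit.beta1 == pytest.approx(0.0, abs=1e-6)
    assert fit.sigma2_u == 0.0
    assert fit.beta0 == pytest.approx(0.0, abs=1e-6)


def test_laplace_matches_high_order_quadrature_on_seeded_site():
    rng = np.random.default_rng(1)
    c, n = _draw_site(rng, beta1=1.0, sigma_fam=0.5, coverage=20)
    laplace = glmm_site_fit(c, n, IS_FE, FAMS)
    agq = glmm_site_fit(c, n, IS_FE, FAMS, GlmmConfig(method="agq", agq_nodes=51))
    assert abs(laplace.beta1 - agq.beta1) <= 1e-3
    assert laplace.sigma2_u == pytest.approx(agq.sigma2_u, abs=5e-3)


def test_matches_lme4_glmer_frozen_oracle():
    """Frozen reference fits from R lme4::glmer (binomial, Laplace):

        glmer(cbind(c, n - c) ~ x + (1 | fam), family = binomial)

    on the first two sites drawn below (seed 42); estimates from
    summary()$coefficients and VarCorr().
    """
    rng = np.random.default_rng(42)
    expected = [
        # (beta0, beta1, sigma2_u, se_beta1)
        (-0.002149, -0.380080, 0.388079, 0.291844),
        (-0.105808, 1.143476, 0.107996, 0.291872),
    ]
    for i, (b0, b1, s2, se) in enumerate(expected):
        u = rng.normal(0, 0.5, F)
        p = expit(0.0 + u[FAM_IDX] + (0.8 if i % 2 else 0.0) * X)
        n = np.maximum(rng.negative_binomial(8, 8 / 23, 2 * F), 1)
        c = rng.binomial(n, p)
        fit = glmm_site_fit(c, n, IS_FE, FAMS)
        assert fit.beta0 == pytest.approx(b0, abs=1e-3)
        assert fit.beta1 == pytest.approx(b1, abs=1e-3)
        assert fit.sigma2_u == pytest.approx(s2, abs=1e-3)
        assert fit.se_beta1 == pytest.approx(se, rel=0.05)


def test_analytic_gradient_matches_numerical():
    rng = np.random.default_rng(3)
    c, n = _draw_site(rng, beta0=-0.5, beta1=0.8, coverage=15)
    lik = _MarginalLik(c, n, X, FAM_IDX, F)
    for theta in ([-0.4, 0.5, math.log(0.4)], [0.2, -0.3, math.log(0.05)],
                  [0.0, 0.0, math.log(1.5)]):
        theta = np.array(theta)
        f, g = lik.negll_grad(theta)
        assert f == pytest.approx(lik.negll(theta), abs=1e-10)
        gn = approx_fprime(theta, lik.negll, 1e-6)
        assert np.max(np.abs(g - gn)) < 1e-3


def test_label_swap_negates_beta1_preserves_p_and_lambda():
    rng = np.random.default_rng(4)
    c, n = _draw_site(rng, beta1=0.7)
    a = glmm_site_fit(c, n, IS_FE, FAMS)
    b = glmm_site_fit(c, n, ~IS_FE, FAMS)
    assert a.beta1 == pytest.approx(-b.beta1, abs=1e-5)
    assert a.p == pytest.approx(b.p, rel=1e-3)
    la = dispersion_lambda(a, c, n, IS_FE, FAMS)
    lb = dispersion_lambda(b, c, n, ~IS_FE, FAMS)
    assert la.lam == pytest.approx(lb.lam, rel=1e-4)


def test_sigma_zero_agrees_with_pooled_two_group_estimate():
    # with no family effect the GLMM collapses to the two-cell logistic model
    rng = np.random.default_rng(5)
    diffs = []
    for _ in range(20):
        c, n = _draw_site(rng, beta1=0.8, sigma_fam=0.0, coverage=30)
        fit = glmm_site_fit(c, n, IS_FE, FAMS)
        pool = pooled_site_test(
            int(c[IS_FE].sum()), int((n - c)[IS_FE].sum()),
            int(c[~IS_FE].sum()), int((n - c)[~IS_FE].sum()),
        )
        diffs.append(abs(fit.beta1 - pool.beta1))
    assert np.median(diffs) < 0.05


def test_degenerate_and_underdetermined_inputs():
    with pytest.raises(ValueError, match="families"):
        glmm_site_fit([1, 2], [5, 5], [True, False], ["f1", "f1"])
    fit = glmm_site_fit([0] * 16, [10] * 16, IS_FE, FAMS)
    assert fit.flag == "nonconverged"
    assert math.isnan(fit.beta1)
    rec = dispersion_lambda(fit, [0] * 16, [10] * 16, IS_FE, FAMS)
    assert math.isnan(rec.lam) and not rec.retained


def test_dispersion_lambda_formula():
    # a perfectly fitted site has zero residuals
    fit = glmm_site_fit([5] * 16, [10] * 16, IS_FE, FAMS)
    rec = dispersion_lambda(fit, [5] * 16, [10] * 16, IS_FE, FAMS)
    assert rec.lam == pytest.approx(0.0, abs=1e-8)
    # hand-built fit: residual sum 12 over denominator 6 -> lambda 2
    fit = GlmmFit((), 0.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, "converged",
                  tuple([0.0] * F))
    c = np.full(16, 5.0)
    n = np.full(16, 10.0)
    # Pearson residual per sample: (c - n/2)^2 / (n/4); choose c so sum = 12
    c[0] = 5 + math.sqrt(2.5 * 12)  # single sample carries all misfit
    rec = dispersion_lambda(fit, c, n, IS_FE, FAMS, denominator_k=6)
    assert rec.lam == pytest.approx(2.0, abs=1e-9)


def test_lambda_distribution_tracks_overdispersion():
    """For well-specified binomial data lambda sits near residual-dof/6;
    extra-binomial noise (a per-sample logit effect the model lacks)
    shifts the lambda distribution upward."""
    rng = np.random.default_rng(6)

    def lam_sample(extra_sd, n_sites=120):
        lams = []
        for _ in range(n_sites):
            u = rng.normal(0, 0.4, F)
            e = rng.normal(0, extra_sd, 2 * F)
            p = expit(-0.3 + u[FAM_IDX] + e)
            n = np.full(2 * F, 20)
            c = rng.binomial(n, p)
            fit = glmm_site_fit(c, n, IS_FE, FAMS)
            if fit.flag == "converged":
                lams.append(dispersion_lambda(fit, c, n, IS_FE, FAMS).lam)
        return np.array(lams)

    well = lam_sample(0.0)
    over = lam_sample(0.8)
    # residual dof: 16 samples minus fixed effects and (shrunk) family modes
    assert 0.8 < np.median(well) < 2.6
    assert np.median(over) > np.median(well) * 1.5


def test_hpd_interval_shortest_window():
    values = [1.0] * 19 + [100.0]
    lo, hi = hpd_interval(values, 0.95)
    assert (lo, hi) == (1.0, 1.0)
    # brute force over all ceil(0.95*20)=19-windows of the sorted values
    v = np.sort(values)
    m = math.ceil(0.95 * 20)
    widths = [(v[i + m - 1] - v[i], v[i], v[i + m - 1]) for i in range(20 - m + 1)]
    assert min(widths)[1:] == (lo, hi)

    assert hpd_interval([3.3] * 25, 0.95) == (3.3, 3.3)
    with pytest.raises(ValueError):
        hpd_interval([1.0] * 25, 1.0)
    with pytest.raises(ValueError):
        hpd_interval([1.0] * 10, 0.95)


def test_filter_dispersion_marks_outliers_and_bad_fits():
    fits = [
        GlmmFit((i,), 0, 0, 0.1, 1, 0, 0.5, 0, "converged") for i in range(19)
    ]
    recs = [DispersionRecord((i,), 1.0) for i in range(19)]
    fits.append(GlmmFit((19,), 0, 0, 0.1, 1, 0, 0.5, 0, "converged"))
    recs.append(DispersionRecord((19,), 100.0))
    fits.append(GlmmFit((20,), 0, 0, 0.0, 1, 0, 0.5, 0, "singular"))
    recs.append(DispersionRecord((20,), 1.0))
    out, (lo, hi) = filter_dispersion(fits, recs, 0.95)
    assert (lo, hi) == (1.0, 1.0)
    retained = [r.site[0] for r in out if r.retained]
    assert retained == list(range(19))  # outlier and singular site excluded


def test_matrix_level_family_test(paired_cohort):
    res, (lo, hi) = family_site_tests(paired_cohort.matrix,
                                       paired_cohort.matrix.meta)
    assert len(res) > 200
    assert lo <= hi
    assert set(res.glmm_flag) <= {"converged", "singular", "nonconverged"}
    assert (res.loc[res.retained, "glmm_flag"] == "converged").all()
    assert ((res.p > 0) & (res.p <= 1)).all() or res.p.isna().any()
    # meth_diff sign convention: positive when FE more methylated
    sub = res.dropna(subset=["beta1"])
    strong = sub[sub.beta1.abs() > 0.5]
    if len(strong):
        agree = np.sign(strong.beta1) == np.sign(strong.meth_diff)
        assert agree.mean() > 0.9
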