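"""Per-site binomial GLMM for the paired-sibling design, with overdispersion
filtering.

Model, per CpG site: for sibling j of family f with methylated count c_j
out of n_j reads,

    c_j ~ Binomial(n_j, expit(beta0 + beta1 * I[FE] + u_f)),
    u_f ~ Normal(0, sigma_u^2)

where beta1 is the fast- vs slow-exploring personality effect on the
logit scale and u_f a family random intercept absorbing the shared
(genetic) background of the two matched siblings.  The marginal
likelihood integrates u_f out per family; this module maximizes it with
a Laplace approximation by default, and exposes adaptive Gauss-Hermite
quadrature with a configurable node count as a high-accuracy oracle
mode.  Significance of beta1 is a Wald test against the normal.

After fitting, a per-site dispersion statistic

    lambda = sum_j pearson_residual_j^2 / k,   k = 2 * (n_fixed + n_random) = 6

summarizes how much the data over- or under-disperse relative to the
fitted binomial; sites whose lambda falls outside the empirical 95%
highest-density interval of the genome-wide lambda distribution are
removed before DMC calling, as are sites with singular (sigma_u^2 ~ 0
boundary) or non-converged fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit
from numpy.polynomial.hermite import hermgauss

from .cgmap import SampleMeta, SiteMatrix, check_paired_families

__all__ = [
    "GlmmConfig",
    "GlmmFit",
    "DispersionRecord",
    "glmm_site_fit",
    "dispersion_lambda",
    "hpd_interval",
    "filter_dispersion",
    "family_site_tests",
]

FLAG_OK = "converged"
FLAG_SINGULAR = "singular"
FLAG_NONCONVERGED = "nonconverged"


@dataclass(frozen=True)
class GlmmConfig:
    method: str = "laplace"  # or "agq"
    agq_nodes: int = 50
    singular_tol: float = 1e-6  # on sigma_u^2
    gtol: float = 1e-5
    maxiter: int = 200
    denominator_k: int = 6  # 2 * (2 fixed + 1 random) effects
    log_sigma_bounds: tuple[float, float] = (-8.0, 2.5)

    def validate(self) -> None:
        if self.method not in ("laplace", "agq"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.agq_nodes < 1:
            raise ValueError("agq_nodes must be >= 1")


@dataclass(frozen=True)
class GlmmFit:
    site: tuple
    beta0: float
    beta1: float
    sigma2_u: float
    se_beta1: float
    z: float
    p: float
    loglik: float
    flag: str
    u_modes: tuple = ()  # posterior modes per family at the optimum

    @property
    def neglog10p(self) -> float:
        return -math.log10(self.p) if self.p > 0 else math.inf


@dataclass(frozen=True)
class DispersionRecord:
    site: tuple
    lam: float  # NaN when the fit did not converge
    retained: bool = True


class _MarginalLik:
    """Per-site marginal log-likelihood with family-wise Laplace/AGQ integral.

    Caches the posterior modes between evaluations (warm start for the
    inner Newton solve); the integrand is strictly log-concave in u, so
    damped Newton converges from any start.
    """

    def __init__(self, c, n, x, fam, n_fam, method="laplace", nodes=50):
        self.c = np.asarray(c, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.fam = np.asarray(fam, dtype=np.intp)
        self.n_fam = int(n_fam)
        self.method = method
        if method == "agq":
            zk, wk = hermgauss(nodes)  # physicists': int e^{-z^2} f(z) dz
            self.zk = zk
            self.logwk = np.log(wk)
        self.u = np.zeros(self.n_fam)

    def _modes(self, beta0, beta1, s2):
        """Newton solve for the per-family posterior modes and curvatures."""
        u = self.u.copy()
        fixed = beta0 + beta1 * self.x
        for _ in range(50):
            eta = fixed + u[self.fam]
            mu = expit(eta)
            g = np.bincount(self.fam, self.c - self.n * mu, self.n_fam) - u / s2
            w = np.bincount(self.fam, self.n * mu * (1 - mu), self.n_fam) + 1.0 / s2
            step = g / w
            np.clip(step, -4.0, 4.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = fixed + u[self.fam]
        mu = expit(eta)
        w = np.bincount(self.fam, self.n * mu * (1 - mu), self.n_fam) + 1.0 / s2
        self.u = u
        return u, w, eta

    def _h(self, u, beta0, beta1, s2):
        """Joint log-density h_f(u_f) per family (binomial + normal prior)."""
        eta = beta0 + beta1 * self.x + u[self.fam]
        b = self.c * eta - self.n * np.logaddexp(0.0, eta)
        return (
            np.bincount(self.fam, b, self.n_fam)
            - 0.5 * u * u / s2
            - 0.5 * math.log(2.0 * math.pi * s2)
        )

    def loglik(self, theta) -> float:
        beta0, beta1, s = theta
        s2 = math.exp(2.0 * s)
        u, w, _ = self._modes(beta0, beta1, s2)
        if self.method == "laplace":
            h = self._h(u, beta0, beta1, s2)
            ll = h + 0.5 * math.log(2.0 * math.pi) - 0.5 * np.log(w)
            return float(np.sum(ll))
        tau = 1.0 / np.sqrt(w)  # (n_fam,)
        # u_{f,k} = mode_f + sqrt(2) tau_f z_k
        uk = u[None, :] + math.sqrt(2.0) * tau[None, :] * self.zk[:, None]
        a = np.empty_like(uk)
        for k in range(uk.shape[0]):
            a[k] = self._h(uk[k], beta0, beta1, s2) + self.zk[k] ** 2
        m = np.max(a, axis=0)
        ll = (
            m
            + np.log(np.sum(np.exp(a - m[None, :]) * np.exp(self.logwk)[:, None], axis=0))
            + 0.5 * math.log(2.0) + np.log(tau)
        )
        return float(np.sum(ll))

    def negll(self, theta) -> float:
        return -self.loglik(theta)

    def negll_grad(self, theta):
        """Laplace objective and its analytic gradient.

        Differentiates through the posterior mode with the implicit
        function theorem (h'(u-hat) = 0), including the curvature term
        -1/2 log(-h''): for each family, with v_j = n_j mu_j (1 - mu_j),
        w = sum v + 1/sigma^2 and B = sum v (1 - 2 mu),

            du-hat/dbeta = -(sum of that predictor's v) / w
            dl/dbeta     = score(beta) - (dw/dbeta + B * du-hat/dbeta) / (2 w).
        """
        if self.method != "laplace":
            raise ValueError("analytic gradient is for the laplace method")
        beta0, beta1, s = theta
        s2 = math.exp(2.0 * s)
        u, w, eta = self._modes(beta0, beta1, s2)
        mu = expit(eta)
        b = self.c * eta - self.n * np.logaddexp(0.0, eta)
        h = (
            np.bincount(self.fam, b, self.n_fam)
            - 0.5 * u * u / s2
            - 0.5 * math.log(2.0 * math.pi * s2)
        )
        ll = float(np.sum(h + 0.5 * math.log(2.0 * math.pi) - 0.5 * np.log(w)))

        resid = self.c - self.n * mu
        v = self.n * mu * (1 - mu)
        vp = v * (1 - 2 * mu)
        S0 = np.bincount(self.fam, resid, self.n_fam)
        S0x = np.bincount(self.fam, resid * self.x, self.n_fam)
        A = w - 1.0 / s2
        Ax = np.bincount(self.fam, v * self.x, self.n_fam)
        B = np.bincount(self.fam, vp, self.n_fam)
        Bx = np.bincount(self.fam, vp * self.x, self.n_fam)

        du_db0 = -A / w
        du_db1 = -Ax / w
        du_ds = 2.0 * u / (s2 * w)
        g0 = np.sum(S0 - (B + B * du_db0) / (2.0 * w))
        g1 = np.sum(S0x - (Bx + B * du_db1) / (2.0 * w))
        gs = np.sum(
            (u * u / s2 - 1.0) - (-2.0 / s2 + B * du_ds) / (2.0 * w)
        )
        return -ll, -np.array([g0, g1, gs])


def _wald_se_beta1(lik: _MarginalLik, theta: np.ndarray) -> float:
    """Observed-information SE of beta1 from the (beta0, beta1) Hessian at the
    optimum, variance parameter held fixed (the conventional mixed-model
    Wald summary)."""
    h = 1e-4
    f = lik.negll

    def at(d0, d1):
        return f(np.array([theta[0] + d0, theta[1] + d1, theta[2]]))

    f00 = (at(h, 0) - 2 * at(0, 0) + at(-h, 0)) / h**2
    f11 = (at(0, h) - 2 * at(0, 0) + at(0, -h)) / h**2
    f01 = (at(h, h) - at(h, -h) - at(-h, h) + at(-h, -h)) / (4 * h**2)
    H = np.array([[f00, f01], [f01, f11]])
    try:
        cov = np.linalg.inv(H)
        v = cov[1, 1]
    except np.linalg.LinAlgError:
        return math.nan
    return math.sqrt(v) if v > 0 else math.nan


def glmm_site_fit(
    c: Sequence[float],
    n: Sequence[float],
    is_fe: Sequence[bool],
    family: Sequence[str] | Sequence[int],
    config: GlmmConfig = GlmmConfig(),
    site: tuple = (),
) -> GlmmFit:
    """Maximum-likelihood fit of the binomial family-intercept GLMM at one site.

    ``c``/``n`` are methylated/total counts per sample (missing samples
    simply excluded by the caller), ``is_fe`` the personality indicator
    and ``family`` family labels.  Requires >= 2 distinct families.
    """
    config.validate()
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    x = np.asarray(is_fe, dtype=float)
    fam_labels, fam = np.unique(np.asarray(family), return_inverse=True)
    if len(fam_labels) < 2:
        raise ValueError(f"need >= 2 families, got {len(fam_labels)}")
    if np.any(n < 1):
        raise ValueError("zero-depth samples must be excluded before fitting")

    nan_fit = lambda flag: GlmmFit(  # noqa: E731
        site, math.nan, math.nan, math.nan, math.nan, math.nan, math.nan,
        math.nan, flag
    )
    if c.sum() == 0 or (n - c).sum() == 0:
        # all-unmethylated / all-methylated response: intercept diverges
        return nan_fit(FLAG_NONCONVERGED)

    lik = _MarginalLik(c, n, x, fam, len(fam_labels), config.method, config.agq_nodes)
    p0 = float(np.clip(c.sum() / n.sum(), 1e-3, 1 - 1e-3))
    theta0 = np.array([logit(p0), 0.0, math.log(0.3)])
    lo, hi = config.log_sigma_bounds
    if config.method == "laplace":
        fun, jac = lik.negll_grad, True
    else:
        fun, jac = lik.negll, None
    res = optimize.minimize(
        fun,
        theta0,
        jac=jac,
        method="L-BFGS-B",
        bounds=[(None, None), (None, None), (lo, hi)],
        options={"maxiter": config.maxiter, "gtol": config.gtol, "ftol": 1e-12},
    )
    if not res.success and "ROUNDING" not in str(res.message).upper():
        return nan_fit(FLAG_NONCONVERGED)
    beta0, beta1, s = res.x
    sigma2 = math.exp(2.0 * s)
    se = _wald_se_beta1(lik, res.x)
    z = beta1 / se if se and se > 0 else math.nan
    p = float(min(max(2.0 * stats.norm.sf(abs(z)), 5e-324), 1.0)) if np.isfinite(z) else math.nan
    flag = FLAG_SINGULAR if sigma2 < config.singular_tol else FLAG_OK
    if flag == FLAG_SINGULAR:
        sigma2 = 0.0
    u_modes, _, _ = lik._modes(beta0, beta1, max(sigma2, 1e-12))
    return GlmmFit(
        site, float(beta0), float(beta1), float(sigma2), float(se),
        float(z) if np.isfinite(z) else math.nan, p, float(-res.fun), flag,
        tuple(float(v) for v in u_modes),
    )


def dispersion_lambda(
    fit: GlmmFit,
    c: Sequence[float],
    n: Sequence[float],
    is_fe: Sequence[bool],
    family: Sequence[str] | Sequence[int],
    denominator_k: int = 6,
) -> DispersionRecord:
    """Overdispersion statistic: sum of squared Pearson residuals over k.

    Residuals are taken at the conditional (family-specific) fitted
    means, i.e. including the posterior-mode random intercepts.  The
    default k = 6 counts 2 x (2 fixed + 1 random) effects.
    """
    if fit.flag == FLAG_NONCONVERGED or not np.isfinite(fit.beta0):
        return DispersionRecord(fit.site, math.nan, False)
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    x = np.asarray(is_fe, dtype=float)
    fam_labels, fam = np.unique(np.asarray(family), return_inverse=True)
    u = np.asarray(fit.u_modes) if fit.u_modes else np.zeros(len(fam_labels))
    eta = fit.beta0 + fit.beta1 * x + u[fam]
    mu = expit(eta)
    denom = n * mu * (1 - mu)
    ok = denom > 0
    r2 = np.zeros_like(c)
    r2[ok] = (c[ok] - n[ok] * mu[ok]) ** 2 / denom[ok]
    return DispersionRecord(fit.site, float(r2.sum() / denominator_k), True)


def hpd_interval(values: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Empirical shortest interval holding ``mass`` of the values.

    Order-statistic construction: among all windows of ceil(mass * N)
    consecutive sorted values, the narrowest (ties: the lowest) wins.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0,1), got {mass}")
    v = np.sort(np.asarray([x for x in values if np.isfinite(x)], dtype=float))
    n = len(v)
    if n < 20:
        raise ValueError(f"need >= 20 finite values for an HPD interval, got {n}")
    m = math.ceil(mass * n)
    widths = v[m - 1:] - v[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) minimum
    return float(v[i]), float(v[i + m - 1])


def filter_dispersion(
    fits: Sequence[GlmmFit],
    records: Sequence[DispersionRecord],
    mass: float = 0.95,
) -> tuple[list[DispersionRecord], tuple[float, float]]:
    """Mark sites whose lambda falls outside the genome-wide HPD interval.

    Singular and non-converged fits are marked not-retained regardless
    (they are omitted from DMC calling).  Returns the updated records and
    the interval.
    """
    lam_pool = [
        r.lam
        for f, r in zip(fits, records)
        if f.flag == FLAG_OK and np.isfinite(r.lam)
    ]
    lo, hi = hpd_interval(lam_pool, mass)
    out = []
    for f, r in zip(fits, records):
        keep = f.flag == FLAG_OK and np.isfinite(r.lam) and lo <= r.lam <= hi
        out.append(DispersionRecord(r.site, r.lam, keep))
    return out, (lo, hi)


def family_site_tests(
    matrix: SiteMatrix,
    meta: Sequence[SampleMeta] | None = None,
    config: GlmmConfig = GlmmConfig(),
    hpd_mass: float = 0.95,
    min_families: int = 2,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Fit the GLMM at every site of a paired-design matrix.

    Per site, samples with missing counts are dropped; sites with fewer
    than ``min_families`` complete families are skipped.  Returns a
    results frame (one row per tested site, with effect, Wald p, family
    variance, lambda and retention flag) plus the fitted lambda HPD
    interval.  The mean FE - SE ratio difference uses per-group sample
    means, matching the pooled convention.
    """
    meta = list(meta) if meta is not None else matrix.meta
    check_paired_families(meta)
    by_id = {m.sample_id: m for m in meta}
    samples = matrix.samples
    is_fe = np.array([by_id[s].group == "FE" for s in samples])
    fam = np.array([by_id[s].family_id for s in samples])

    meth = matrix.meth.to_numpy()
    depth = matrix.depth.to_numpy()
    rows = []
    fits: list[GlmmFit] = []
    disp: list[DispersionRecord] = []
    for i, key in enumerate(matrix.meth.index):
        c_row, n_row = meth[i], depth[i]
        present = np.isfinite(n_row) & (n_row >= 1)
        fams_present = fam[present]
        fe_present = is_fe[present]
        complete = {
            f
            for f in np.unique(fams_present)
            if (fe_present[fams_present == f]).any()
            and (~fe_present[fams_present == f]).any()
        }
        if len(complete) < min_families:
            continue
        c, n = c_row[present], n_row[present]
        fit = glmm_site_fit(c, n, fe_present, fams_present, config, site=tuple(key))
        rec = dispersion_lambda(fit, c, n, fe_present, fams_present,
                                config.denominator_k)
        fits.append(fit)
        disp.append(rec)
        with np.errstate(invalid="ignore"):
            ratios = c / n
        rows.append(
            {
                "chrom": key[0], "pos": key[1], "strand_base": key[2],
                "n_samples": int(present.sum()), "n_families": len(complete),
                "ratio_fe": float(np.mean(ratios[fe_present])),
                "ratio_se": float(np.mean(ratios[~fe_present])),
                "meth_diff": float(
                    np.mean(ratios[fe_present]) - np.mean(ratios[~fe_present])
                ),
                "beta0": fit.beta0, "beta1": fit.beta1, "sigma2_u": fit.sigma2_u,
                "se_beta1": fit.se_beta1, "z": fit.z, "p": fit.p,
                "neglog10p": fit.neglog10p if np.isfinite(fit.p) else math.nan,
                "loglik": fit.loglik, "glmm_flag": fit.flag, "lam": rec.lam,
            }
        )
    results = pd.DataFrame(rows)
    if results.empty:
        return results.assign(retained=pd.Series(dtype=bool), flag=pd.Series(dtype=str)), (
            math.nan, math.nan
        )
    disp, (lo, hi) = filter_dispersion(fits, disp, hpd_mass)
    results["retained"] = [r.retained for r in disp]
    # unified flag column for DMC calling: only retained, converged sites pass
    results["flag"] = np.where(results["retained"], "retained", "omitted")
    return results, (lo, hi)
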