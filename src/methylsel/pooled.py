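"""Per-site two-group binomial test for pooled libraries, and DMC calling.

Each CpG is tested with a binomial logistic regression of methylated (C)
versus unmethylated (T) read counts on phenotype line (FE vs SE).  With
one pool per group the model is saturated, so the Wald test on the group
coefficient has a closed form:

    beta1 = logit(c_FE / n_FE) - logit(c_SE / n_SE)
    se    = sqrt(1/c_FE + 1/t_FE + 1/c_SE + 1/t_SE)
    z     = beta1 / se,   p = 2 * (1 - Phi(|z|))

which this module uses on non-degenerate counts; any zero cell means
complete separation, and the site is flagged and refit iteratively so the
reported numbers match what a GLM fitter would print.  Differentially
methylated cytosines (DMCs) are sites exceeding the genome-wide
Bonferroni threshold -log10(alpha / n_tests) AND a minimum absolute
FE - SE methylation-ratio difference (default 10 percentage points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

from .cgmap import SiteMatrix

__all__ = [
    "SiteTestResult",
    "CallConfig",
    "pooled_site_test",
    "irls_site_test",
    "methylation_difference",
    "bonferroni_neglog10",
    "pooled_site_tests",
    "call_dmcs",
    "results_to_bed",
]

FLAG_OK = "converged"
FLAG_SEPARATION = "separation"
FLAG_OMITTED = "omitted"


@dataclass(frozen=True)
class SiteTestResult:
    """Wald test of the FE-vs-SE coefficient at one CpG."""

    site: tuple  # (chrom, pos, strand_base)
    beta1: float
    se_beta1: float
    z: float
    p: float
    meth_diff: float  # FE ratio - SE ratio; positive = FE hypermethylated
    flag: str = FLAG_OK

    @property
    def neglog10p(self) -> float:
        return -math.log10(self.p) if self.p > 0 else math.inf


@dataclass(frozen=True)
class CallConfig:
    alpha: float = 0.05
    n_tests: int = 1
    min_abs_diff: float = 0.10

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


def _wald_from_cells(c1: float, t1: float, c0: float, t0: float):
    beta1 = float(logit(c1 / (c1 + t1)) - logit(c0 / (c0 + t0)))
    se = math.sqrt(1 / c1 + 1 / t1 + 1 / c0 + 1 / t0)
    z = beta1 / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta1, se, z, min(max(p, 5e-324), 1.0)


def irls_site_test(c_fe: int, t_fe: int, c_se: int, t_se: int,
                   maxiter: int = 100) -> SiteTestResult:
    """Iteratively-reweighted least-squares logistic fit of the same model.

    Kept as an explicit, independent route to the Wald numbers; used for
    separated sites and as the oracle the closed form is verified against.
    """
    import warnings

    import statsmodels.api as sm

    endog = np.array([[c_fe, t_fe], [c_se, t_se]], dtype=float)
    exog = np.array([[1.0, 1.0], [1.0, 0.0]])
    with warnings.catch_warnings():
        # the two-cell model is saturated: df_resid == 0 and fitted == observed,
        # which statsmodels reports as perfect separation / zero-division
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=1e-12
        )
    beta1 = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta1 / se if se > 0 else math.nan
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 1.0
    n_fe, n_se = c_fe + t_fe, c_se + t_se
    diff = c_fe / n_fe - c_se / n_se
    flag = FLAG_SEPARATION if 0 in (c_fe, t_fe, c_se, t_se) else FLAG_OK
    return SiteTestResult((), beta1, se, z, min(max(p, 5e-324), 1.0), diff, flag)


def pooled_site_test(
    c_fe: int, t_fe: int, c_se: int, t_se: int, site: tuple = ()
) -> SiteTestResult:
    """Closed-form Wald test; separated (zero-cell) sites are refit iteratively."""
    n_fe, n_se = c_fe + t_fe, c_se + t_se
    if min(c_fe, t_fe, c_se, t_se) < 0:
        raise ValueError("negative counts")
    if n_fe < 1 or n_se < 1:
        raise ValueError("each group needs at least one read (pre-filter upstream)")
    diff = c_fe / n_fe - c_se / n_se
    if 0 in (c_fe, t_fe, c_se, t_se):
        res = irls_site_test(c_fe, t_fe, c_se, t_se)
        return SiteTestResult(site, res.beta1, res.se_beta1, res.z, res.p, diff,
                              FLAG_SEPARATION)
    beta1, se, z, p = _wald_from_cells(c_fe, t_fe, c_se, t_se)
    return SiteTestResult(site, beta1, se, z, p, diff, FLAG_OK)


def methylation_difference(
    fe_ratios: Sequence[float], se_ratios: Sequence[float]
) -> float:
    """mean(FE ratios) - mean(SE ratios); positive means FE hypermethylated."""
    fe = [r for r in fe_ratios if not (isinstance(r, float) and math.isnan(r))]
    se = [r for r in se_ratios if not (isinstance(r, float) and math.isnan(r))]
    if not fe or not se:
        raise ValueError("each group needs at least one methylation ratio")
    return float(np.mean(fe) - np.mean(se))


def bonferroni_neglog10(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide Bonferroni significance threshold on the -log10(p) scale."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-math.log10(alpha / n_tests))


def pooled_site_tests(matrix: SiteMatrix) -> pd.DataFrame:
    """Run the pooled test at every site of a 2-pool matrix.

    Expects exactly one FE and one SE column (pools); returns a results
    frame with one row per site.
    """
    fe_cols = [m.sample_id for m in matrix.meta if m.group == "FE"]
    se_cols = [m.sample_id for m in matrix.meta if m.group == "SE"]
    if len(fe_cols) != 1 or len(se_cols) != 1:
        raise ValueError(
            f"pooled testing expects one FE and one SE library, got "
            f"{len(fe_cols)} FE / {len(se_cols)} SE"
        )
    c1 = matrix.meth[fe_cols[0]].to_numpy()
    n1 = matrix.depth[fe_cols[0]].to_numpy()
    c0 = matrix.meth[se_cols[0]].to_numpy()
    n0 = matrix.depth[se_cols[0]].to_numpy()
    t1, t0 = n1 - c1, n0 - c0

    ok = (
        np.isfinite(n1) & np.isfinite(n0) & (n1 >= 1) & (n0 >= 1)
        & (c1 > 0) & (t1 > 0) & (c0 > 0) & (t0 > 0)
    )
    beta1 = np.full(len(c1), np.nan)
    se = np.full_like(beta1, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta1[ok] = logit(c1[ok] / n1[ok]) - logit(c0[ok] / n0[ok])
        se[ok] = np.sqrt(1 / c1[ok] + 1 / t1[ok] + 1 / c0[ok] + 1 / t0[ok])
    z = beta1 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 5e-324, 1.0)
    diff = c1 / n1 - c0 / n0
    flags = np.where(ok, FLAG_OK, FLAG_SEPARATION)
    flags[~(np.isfinite(n1) & np.isfinite(n0))] = FLAG_OMITTED

    # refit separated-but-covered sites iteratively so reported values are finite
    sep = np.flatnonzero((flags == FLAG_SEPARATION))
    for i in sep:
        res = irls_site_test(int(c1[i]), int(t1[i]), int(c0[i]), int(t0[i]))
        beta1[i], se[i], z[i], p[i] = res.beta1, res.se_beta1, res.z, res.p

    idx = matrix.meth.index
    out = pd.DataFrame(
        {
            "chrom": idx.get_level_values(0),
            "pos": idx.get_level_values(1),
            "strand_base": idx.get_level_values(2),
            "c_fe": c1, "n_fe": n1, "c_se": c0, "n_se": n0,
            "ratio_fe": c1 / n1, "ratio_se": c0 / n0,
            "meth_diff": diff,
            "beta1": beta1, "se_beta1": se, "z": z, "p": p,
            "neglog10p": -np.log10(p),
            "flag": flags,
        }
    )
    return out


def call_dmcs(results: pd.DataFrame, config: CallConfig) -> pd.DataFrame:
    """Apply the DMC rule: -log10(p) above Bonferroni AND |diff| above minimum.

    Flagged (separated/omitted/non-converged) sites are excluded from
    calling but still count toward ``n_tests`` upstream.  Output sorted by
    significance, descending.
    """
    config.validate()
    if results.empty:
        return results.iloc[0:0].assign(dmc_call=pd.Series(dtype=bool))
    threshold = bonferroni_neglog10(config.n_tests, config.alpha)
    eligible = results["flag"].isin([FLAG_OK, "retained"]) if "flag" in results else True
    call = (
        (results["neglog10p"] > threshold)
        & (results["meth_diff"].abs() > config.min_abs_diff)
        & eligible
    )
    out = results.loc[call].copy()
    out["dmc_call"] = True
    return out.sort_values("neglog10p", ascending=False)


def results_to_bed(results: pd.DataFrame, path: str | Path) -> None:
    """Write sites as BED (0-based half-open), scored by -log10(p)."""
    with open(path, "w") as fh:
        for r in results.itertuples():
            fh.write(
                f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.chrom}:{r.pos}\t"
                f"{min(r.neglog10p, 1000):.4f}\t"
                f"{'+' if r.strand_base == 'C' else '-'}\n"
            )
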