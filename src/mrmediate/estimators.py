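"""Univariable and multivariable two-sample MR estimators.

All estimators consume a :class:`~mrmediate.summarystats.HarmonizedData`
(or :class:`~mrmediate.summarystats.MVHarmonizedData` for the multivariable
fit) and return an :class:`MREstimate`, optionally paired with
:class:`HeterogeneityStats`.

Conventions
-----------
* IVW is weighted least squares of the outcome betas on the exposure betas
  through the origin with weights 1/se_outcome².  The random-effects variant
  uses a multiplicative overdispersion scale floored at 1, so it is never
  narrower than the fixed-effect fit; ``auto`` selects random effects for
  three or more instruments and fixed effects otherwise.
* MR-Egger orients every record to a non-negative exposure beta, then fits the
  same weighted regression with a free intercept; inference uses t(J-2).
* The weighted median interpolates the per-variant Wald ratios at cumulative
  weight one half; its standard error comes from a seeded parametric
  bootstrap.
* 95% intervals use the normal multiplier 1.959964 throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summarystats import HarmonizedData, MVHarmonizedData

__all__ = [
    "Z95",
    "MREstimate",
    "HeterogeneityStats",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_median_point",
    "mvmr",
    "to_odds_ratio",
]

Z95 = 1.959964  # standard-normal 97.5th percentile, printed-precision convention


@dataclass
class MREstimate:
    """A causal effect estimate on the outcome scale per unit exposure."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    effects_model: str = "not_applicable"
    or_point: float | None = None
    or_low: float | None = None
    or_high: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class HeterogeneityStats:
    """Cochran's Q heterogeneity and (for Egger) the pleiotropy intercept."""

    q: float
    df: int
    pvalue: float
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _with_ci(method, beta, se, pvalue, n_snps, effects_model="not_applicable"):
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(pvalue),
        n_snps=int(n_snps),
        effects_model=effects_model,
    )


def ivw(
    data: HarmonizedData,
    effects_model: str = "auto",
) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    beta = Σ(βXⱼ βYⱼ / seYⱼ²) / Σ(βXⱼ² / seYⱼ²); the fixed-effect SE is
    1/sqrt(Σ βXⱼ²/seYⱼ²) and the random-effects SE multiplies it by
    max(1, sqrt(Q/(J-1))).
    """
    if effects_model not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    if len(data) == 0:
        raise ValueError("empty dataset")
    bx, _, by, sy = data.arrays()
    j = len(bx)
    if j == 1 and bx[0] == 0:
        raise ValueError("single instrument with zero exposure beta: Wald ratio undefined")
    w = 1.0 / sy**2
    sxx = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w)) / sxx
    fixed_se = 1.0 / math.sqrt(sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = j - 1
    if effects_model == "auto":
        effects_model = "random" if j >= 3 else "fixed"
    if effects_model == "random" and j >= 2:
        se = fixed_se * max(1.0, math.sqrt(q / df))
    else:
        se = fixed_se
    q_p = float(stats.chi2.sf(q, df)) if df >= 1 else float("nan")
    est = _with_ci("ivw", beta, se, _normal_p(beta, se), j, effects_model)
    return est, HeterogeneityStats(q=q, df=df, pvalue=q_p)


def mr_egger(data: HarmonizedData) -> tuple[MREstimate, HeterogeneityStats]:
    """MR-Egger weighted regression with a pleiotropy intercept.

    Records are oriented so every exposure beta is non-negative, then outcome
    betas are regressed on exposure betas with an intercept and weights
    1/se_outcome².  Standard errors carry the multiplicative overdispersion
    scale max(1, sqrt(RSS/(J-2))); p-values are two-sided t(J-2).
    """
    if len(data) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, _, by, sy = data.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise ValueError("degenerate design: all exposure betas equal after orientation")
    j = len(bx)
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    rss = float(fit.ssr)  # weighted residual sum of squares
    scale = max(1.0, math.sqrt(rss / (j - 2)))
    se_unit = np.sqrt(np.diag(fit.cov_params(scale=1.0)))
    intercept, slope = fit.params
    se_int, se_slope = se_unit * scale
    df = j - 2
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), df))
    est = _with_ci("mr_egger", slope, se_slope, p_slope, j)
    het = HeterogeneityStats(
        q=rss,
        df=df,
        pvalue=float(stats.chi2.sf(rss, df)),
        egger_intercept=float(intercept),
        egger_intercept_p=p_int,
    )
    return est, het


def weighted_median_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    """Weighted median of the Wald ratios βYⱼ/βXⱼ.

    Weights are proportional to βXⱼ²/seYⱼ² (first-order inverse variance of
    the ratio).  The sorted ratios are interpolated at cumulative midpoint
    weight 0.5.
    """
    ratios = by / bx
    w = bx**2 / sy**2
    w = w / w.sum()
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], w[order]
    p = np.cumsum(w) - w / 2.0
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(
    data: HarmonizedData,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median estimator with parametric-bootstrap standard error.

    Bootstrap replicates redraw βXⱼ* ~ N(βXⱼ, seXⱼ) and βYⱼ* ~ N(βYⱼ, seYⱼ)
    and recompute the weighted median; the SE is the standard deviation of
    the replicate estimates.
    """
    bx, sx, by, sy = data.arrays()
    nonzero = bx != 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} record(s) with zero exposure beta "
            "(undefined Wald ratio)",
            stacklevel=2,
        )
        bx, sx, by, sy = bx[nonzero], sx[nonzero], by[nonzero], sy[nonzero]
    j = len(bx)
    if j < 3:
        raise ValueError("weighted median requires at least 3 usable instruments")
    beta = weighted_median_point(bx, by, sy)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        ok = bx_s != 0
        boots[b] = weighted_median_point(bx_s[ok], by_s[ok], sy[ok])
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    return _with_ci("weighted_median", beta, se, _normal_p(beta, se), j)


def mvmr(data: MVHarmonizedData) -> list[MREstimate]:
    """Multivariable MR: direct effects of K exposures fitted jointly.

    Weighted least squares of the outcome betas on the K exposure-beta
    columns without intercept, weights 1/se_outcome²; per-exposure SEs carry
    the overdispersion scale max(1, sqrt(RSS/(J-K))).
    """
    X = np.asarray(data.beta_exposures, dtype=float)
    y = np.asarray(data.beta_outcome, dtype=float)
    sy = np.asarray(data.se_outcome, dtype=float)
    j, k = X.shape
    if j <= k:
        raise ValueError(f"need more instruments ({j}) than exposures ({k})")
    w = 1.0 / sy**2
    if np.linalg.matrix_rank(np.sqrt(w)[:, None] * X) < k:
        raise ValueError("rank-deficient exposure design matrix")
    fit = sm.WLS(y, X, weights=w).fit()
    scale = max(1.0, math.sqrt(float(fit.ssr) / (j - k)))
    se_unit = np.sqrt(np.diag(fit.cov_params(scale=1.0)))
    out = []
    for name, beta, se0 in zip(data.exposure_names, fit.params, se_unit):
        se = float(se0) * scale
        out.append(
            _with_ci(f"mvmr[{name}]", float(beta), se, _normal_p(beta, se), j)
        )
    return out


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Populate OR fields by exponentiating the beta and its CI bounds."""
    return replace(
        est,
        or_point=math.exp(est.beta),
        or_low=math.exp(est.ci_low),
        or_high=math.exp(est.ci_high),
    )
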