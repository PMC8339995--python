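"""Two-sample GWAS summary-statistic generator with known ground truth.

Emulates the statistical structure of the consortium inputs a two-sample MR
study consumes: on the order of a hundred independent genome-wide-significant
instruments of heterogeneous strength, exposure and outcome effect estimates
with independent sampling noise (the two-sample assumption), optional
balanced or directional pleiotropy on a subset of instruments, optional
planted outliers, and an exposure→mediator→outcome layer whose implied
mediated proportion is known in closed form.

The per-study standard error follows the standardized-trait approximation
se = 1/sqrt(2·maf·(1−maf)·n); binary outcomes are emulated on the log-odds
scale through the SE magnitude only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .summarystats import SUMMARY_COLUMNS

__all__ = [
    "SimConfig",
    "MediationSimConfig",
    "simulate_two_sample",
    "simulate_mediation",
    "plant_outlier",
]

# non-palindromic allele pairs, cycled across variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimConfig:
    """World definition for a two-sample simulation.

    Defaults describe a well-powered modern GWAS pair: 100 independent
    instruments with mean per-allele effect 0.04 SD (sd 0.015, so strengths
    are heterogeneous but comfortably genome-wide significant at n = 200,000),
    causal effect theta = 0.5, and no pleiotropy unless switched on.
    """

    n_snps: int = 100
    gamma_mean: float = 0.04
    gamma_sd: float = 0.015
    theta: float = 0.5
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    prop_invalid: float = 0.0
    n_exposure: float = 200_000
    n_outcome: float = 200_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.prop_invalid < 1:
            raise ValueError("prop_invalid must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")


@dataclass
class MediationSimConfig(SimConfig):
    """Adds an exposure→mediator→outcome causal layer.

    In the linear model the total effect decomposes as
    theta_direct + theta_xm·theta_my, so the true mediated proportion is
    theta_xm·theta_my / (theta_direct + theta_xm·theta_my).  Defaults mirror
    an adiposity→diabetes→outcome configuration (theta_xm = 1.087,
    theta_my = 0.16, theta_direct = 0.33, i.e. ~34.5% mediated).
    """

    theta_xm: float = 1.087
    theta_my: float = 0.16
    theta_direct: float = 0.33
    n_mediator: float = 200_000
    n_snps_mediator: int = 100
    delta_mean: float | None = None  # mediator-instrument effects; default gamma_*
    delta_sd: float | None = None


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    return np.maximum(se, 1e-12)  # noiseless limit as n -> inf


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def _frame(ids, chroms, pos, eas, oas, maf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chroms,
            "position_bp": pos,
            "effect_allele": eas,
            "other_allele": oas,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pvalue": np.clip(_two_sided_p(beta, se), np.finfo(float).tiny, 1.0),
            "n": float(n) if np.isfinite(n) else np.nan,
        }
    )[SUMMARY_COLUMNS]


def _variant_scaffold(n_snps: int, prefix: str = "snp"):
    ids = [f"{prefix}{j:05d}" for j in range(n_snps)]
    chroms = [str((j % 22) + 1) for j in range(n_snps)]
    # 10 Mb spacing within a chromosome: always outside any clumping window
    pos = [1 + (j // 22) * 10_000_000 for j in range(n_snps)]
    eas = [_ALLELE_PAIRS[j % 4][0] for j in range(n_snps)]
    oas = [_ALLELE_PAIRS[j % 4][1] for j in range(n_snps)]
    return ids, chroms, pos, eas, oas


def simulate_two_sample(config: SimConfig):
    """Draw exposure and outcome summary statistics plus the truth record.

    Per variant j: maf ~ U(maf_range); true instrument effect
    γⱼ ~ N(gamma_mean, gamma_sd); direct pleiotropic effect αⱼ drawn for a
    random prop_invalid subset (zero elsewhere); observed
    beta_exposure = γⱼ + εXⱼ and beta_outcome = θ·γⱼ + αⱼ + εYⱼ with
    independent noise at the study SEs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.n_snps
    maf = rng.uniform(*config.maf_range, size=j)
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=j)
    n_invalid = int(round(config.prop_invalid * j))
    invalid = np.sort(rng.choice(j, size=n_invalid, replace=False))
    alpha = np.zeros(j)
    if n_invalid:
        alpha[invalid] = rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid
        )
    se_x = _se(maf, config.n_exposure)
    se_y = _se(maf, config.n_outcome)
    beta_x = gamma + rng.normal(0.0, 1.0, size=j) * se_x
    beta_y = config.theta * gamma + alpha + rng.normal(0.0, 1.0, size=j) * se_y

    ids, chroms, pos, eas, oas = _variant_scaffold(j)
    exposure = _frame(ids, chroms, pos, eas, oas, maf, beta_x, se_x, config.n_exposure)
    outcome = _frame(ids, chroms, pos, eas, oas, maf, beta_y, se_y, config.n_outcome)
    truth = {
        "theta": config.theta,
        "gamma": gamma,
        "alpha": alpha,
        "invalid_indices": invalid.tolist(),
        "variant_ids": ids,
    }
    return exposure, outcome, truth


def simulate_mediation(config: MediationSimConfig):
    """Exposure, mediator and outcome summary statistics with a known
    mediated proportion.

    Exposure instruments (effects γ) act on the mediator with slope theta_xm
    and on the outcome through both paths; the mediator carries its own
    instruments (effects δ) that hit the outcome with slope theta_my only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j, k = config.n_snps, config.n_snps_mediator
    total_snps = j + k
    d_mean = config.gamma_mean if config.delta_mean is None else config.delta_mean
    d_sd = config.gamma_sd if config.delta_sd is None else config.delta_sd

    maf = rng.uniform(*config.maf_range, size=total_snps)
    gamma = np.concatenate([rng.normal(config.gamma_mean, config.gamma_sd, size=j),
                            np.zeros(k)])
    delta = np.concatenate([np.zeros(j),
                            rng.normal(d_mean, d_sd, size=k)])
    theta_total = config.theta_direct + config.theta_xm * config.theta_my
    se_x = _se(maf, config.n_exposure)
    se_m = _se(maf, config.n_mediator)
    se_y = _se(maf, config.n_outcome)
    beta_x = gamma + rng.normal(0.0, 1.0, size=total_snps) * se_x
    beta_m = (
        config.theta_xm * gamma + delta + rng.normal(0.0, 1.0, size=total_snps) * se_m
    )
    beta_y = (
        theta_total * gamma
        + config.theta_my * delta
        + rng.normal(0.0, 1.0, size=total_snps) * se_y
    )

    ids, chroms, pos, eas, oas = _variant_scaffold(total_snps)
    exposure = _frame(ids, chroms, pos, eas, oas, maf, beta_x, se_x, config.n_exposure)
    mediator = _frame(ids, chroms, pos, eas, oas, maf, beta_m, se_m, config.n_mediator)
    outcome = _frame(ids, chroms, pos, eas, oas, maf, beta_y, se_y, config.n_outcome)
    true_indirect = config.theta_xm * config.theta_my
    truth = {
        "theta_xm": config.theta_xm,
        "theta_my": config.theta_my,
        "theta_direct": config.theta_direct,
        "true_total": theta_total,
        "true_indirect": true_indirect,
        "true_proportion_pct": 100.0 * true_indirect / theta_total,
        "gamma": gamma,
        "delta": delta,
        "variant_ids": ids,
    }
    return exposure, mediator, outcome, truth


def plant_outlier(
    outcome: pd.DataFrame, index: int, displacement_sds: float
) -> pd.DataFrame:
    """Displace one outcome beta by ``displacement_sds`` standard errors.

    Everything else (including the printed p-value) is left untouched, so the
    record is exactly the original with a shifted effect.
    """
    if not 0 <= index < len(outcome):
        raise IndexError(f"index {index} out of range for {len(outcome)} records")
    out = outcome.copy()
    out.loc[out.index[index], "beta"] += displacement_sds * out.loc[out.index[index], "se"]
    return out
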