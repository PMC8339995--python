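"""Simulation-based pleiotropy residual-sum-of-squares outlier analysis.

The global test compares the observed leave-one-out weighted residual sum of
squares against its parametric null distribution; per-variant tails flag
outliers (Bonferroni-corrected), which are removed before re-estimating the
causal effect.  Empirical p-values use the add-one estimator, so the smallest
reportable p is 1/(n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw
from .summarystats import HarmonizedData

__all__ = ["PressoResult", "run_presso"]


@dataclass
class PressoResult:
    global_rss_obs: float
    global_p: float
    per_snp_rss: np.ndarray
    per_snp_p: np.ndarray
    outlier_indices: list[int]
    raw_estimate: MREstimate
    adjusted_estimate: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int | None
    variant_ids: list[str] = field(default_factory=list)

    @property
    def has_outliers(self) -> bool:
        return len(self.outlier_indices) > 0

    def outlier_table(self) -> pd.DataFrame:
        flagged = np.zeros(len(self.per_snp_p), dtype=bool)
        flagged[self.outlier_indices] = True
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids or list(range(len(self.per_snp_p))),
                "rss": self.per_snp_rss,
                "p": self.per_snp_p,
                "flagged": flagged,
            }
        )

    def to_dict(self) -> dict:
        return {
            "global_rss_obs": self.global_rss_obs,
            "global_p": self.global_p,
            "per_snp_p": [float(p) for p in self.per_snp_p],
            "outlier_indices": [int(i) for i in self.outlier_indices],
            "outlier_variant_ids": [self.variant_ids[i] for i in self.outlier_indices]
            if self.variant_ids
            else [],
            "raw_estimate": self.raw_estimate.to_dict(),
            "adjusted_estimate": self.adjusted_estimate.to_dict()
            if self.adjusted_estimate
            else None,
            "distortion_p": self.distortion_p,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorised over the left-out index.

    Works on 1-D arrays or on (n_sim, J) batches (last axis = variants).
    """
    sxy = np.sum(bx * by * w, axis=-1, keepdims=True)
    sxx = np.sum(bx * bx * w, axis=-1, keepdims=True)
    return (sxy - bx * by * w) / (sxx - bx * bx * w)


def _global_and_per_snp_rss(bx, by, w):
    b_loo = _loo_slopes(bx, by, w)
    rss_j = w * (by - b_loo * bx) ** 2
    return rss_j.sum(axis=-1), rss_j


def run_presso(
    data: HarmonizedData,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """Global heterogeneity test, outlier flags and outlier-corrected IVW.

    The observed statistic is Σⱼ wⱼ (βYⱼ − β₋ⱼ βXⱼ)² with β₋ⱼ the
    leave-one-out IVW slope and wⱼ = 1/seYⱼ².  The null redraws
    βXⱼ* ~ N(βXⱼ, seXⱼ) and βYⱼ* ~ N(β₋ⱼ βXⱼ, seYⱼ) and recomputes the same
    statistic ``n_sim`` times.  A variant is an outlier when its empirical
    per-variant tail probability falls below ``outlier_alpha``/J.
    """
    j = len(data)
    if j < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    input_ids = list(data.table["variant_id"])
    # run in canonical (id-sorted) order so flags do not depend on row order
    canon = np.array(sorted(range(j), key=lambda i: str(input_ids[i])))
    back = np.argsort(canon)
    data = HarmonizedData(
        table=data.table.iloc[canon].reset_index(drop=True), log=data.log
    )
    bx, sx, by, sy = data.arrays()
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    b_loo = _loo_slopes(bx, by, w)
    obs_global, obs_rss_j = _global_and_per_snp_rss(bx, by, w)
    obs_global = float(obs_global)

    # parametric null, batched (n_sim, J)
    bx_s = rng.normal(bx, sx, size=(n_sim, j))
    by_s = rng.normal(b_loo * bx, sy, size=(n_sim, j))
    sim_global, sim_rss_j = _global_and_per_snp_rss(bx_s, by_s, w)

    global_p = float((1 + np.sum(sim_global >= obs_global)) / (n_sim + 1))
    # plain empirical fraction per variant: the add-one floor of 1/(n_sim+1)
    # would make a Bonferroni alpha/J flag unreachable at moderate n_sim
    per_snp_p = np.sum(sim_rss_j >= obs_rss_j, axis=0) / n_sim
    outliers = [int(i) for i in np.flatnonzero(per_snp_p < outlier_alpha / j)]
    if len(outliers) == j:
        raise ValueError(
            "every instrument flagged as an outlier; the model is misspecified "
            "for these data (check harmonization and instrument selection)"
        )

    raw_est, _ = ivw(data, effects_model="auto")
    adjusted = None
    distortion_p = None
    if outliers:
        adjusted_data = data.drop_indices(outliers)
        adjusted, _ = ivw(adjusted_data, effects_model="auto")
        obs_contrast = raw_est.beta - adjusted.beta
        n_out = len(outliers)
        null_contrast = np.empty(n_sim)
        all_idx = np.arange(j)
        for s in range(n_sim):
            removed = rng.choice(all_idx, size=n_out, replace=False)
            sub = data.drop_indices(removed)
            sub_est, _ = ivw(sub, effects_model="auto")
            null_contrast[s] = raw_est.beta - sub_est.beta
        distortion_p = float(
            (1 + np.sum(np.abs(null_contrast) >= abs(obs_contrast))) / (n_sim + 1)
        )

    # map per-variant quantities back to the caller's row order
    return PressoResult(
        global_rss_obs=obs_global,
        global_p=global_p,
        per_snp_rss=obs_rss_j[back],
        per_snp_p=per_snp_p[back],
        outlier_indices=sorted(int(canon[i]) for i in outliers),
        raw_estimate=raw_est,
        adjusted_estimate=adjusted,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
        variant_ids=input_ids,
    )
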