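"""Model/Results objects wrapping the MR estimators.

:class:`MRModel` is built from a harmonized two-sample dataset; ``fit``
dispatches to one of the estimators and returns :class:`MRResults`, which
carries the estimate, its uncertainty, heterogeneity diagnostics and a
``summary()`` table.  :class:`MultivariableMRModel` does the same for the
joint K-exposure fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import estimators
from .estimators import HeterogeneityStats, MREstimate, to_odds_ratio
from .presso import PressoResult, run_presso
from .summarystats import HarmonizedData, MVHarmonizedData, mean_f_statistic

__all__ = ["MRModel", "MRResults", "MultivariableMRModel", "MVMRResults"]


class MRResults:
    """Results of a univariable two-sample MR fit."""

    def __init__(
        self,
        model: "MRModel",
        estimate: MREstimate,
        heterogeneity: HeterogeneityStats | None = None,
    ):
        self.model = model
        self.estimate = to_odds_ratio(estimate)
        self.heterogeneity = heterogeneity

    # statsmodels-flavoured accessors
    @property
    def params(self) -> float:
        return self.estimate.beta

    @property
    def bse(self) -> float:
        return self.estimate.se

    @property
    def pvalue(self) -> float:
        return self.estimate.pvalue

    @property
    def nobs(self) -> int:
        return self.estimate.n_snps

    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    def to_row(self) -> dict:
        e = self.estimate
        h = self.heterogeneity
        return {
            "method": e.method,
            "nsnp": e.n_snps,
            "beta": e.beta,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pvalue": e.pvalue,
            "or": e.or_point,
            "or_low": e.or_low,
            "or_high": e.or_high,
            "effects_model": e.effects_model,
            "q": None if h is None else h.q,
            "q_p": None if h is None else h.pvalue,
            "egger_intercept": None if h is None else h.egger_intercept,
            "egger_intercept_p": None if h is None else h.egger_intercept_p,
        }

    def summary(self) -> str:
        e = self.estimate
        lines = [
            f"Two-sample MR: {e.method}",
            "=" * 46,
            f"instruments (SNPs):    {e.n_snps}",
            f"effects model:         {e.effects_model}",
            f"beta:                  {e.beta:+.4f} (se {e.se:.4f})",
            f"95% CI:                ({e.ci_low:+.4f}, {e.ci_high:+.4f})",
            f"OR:                    {e.or_point:.3f} ({e.or_low:.3f}, {e.or_high:.3f})",
            f"p-value:               {e.pvalue:.3g}",
        ]
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(f"Cochran Q:             {h.q:.3f} (df {h.df}, p {h.pvalue:.3g})")
            if h.egger_intercept is not None:
                lines.append(
                    f"Egger intercept:       {h.egger_intercept:+.4f} "
                    f"(p {h.egger_intercept_p:.3g})"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - convenience
        e = self.estimate
        return f"<MRResults {e.method}: beta={e.beta:.4f}, p={e.pvalue:.3g}>"


class MRModel:
    """Univariable two-sample MR model over harmonized summary data."""

    def __init__(self, data: HarmonizedData):
        if len(data) == 0:
            raise ValueError("empty harmonized dataset")
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MRModel":
        """Build from a frame with columns variant_id, beta_exposure,
        se_exposure, beta_outcome, se_outcome."""
        needed = ["variant_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        table = df[needed].reset_index(drop=True)
        log = pd.DataFrame(columns=["variant_id", "action", "reason"])
        return cls(HarmonizedData(table=table, log=log))

    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        """Fit one estimator: ``ivw``, ``egger`` or ``weighted_median``."""
        if method == "ivw":
            est, het = estimators.ivw(self.data, **kwargs)
            return MRResults(self, est, het)
        if method in ("egger", "mr_egger"):
            est, het = estimators.mr_egger(self.data, **kwargs)
            return MRResults(self, est, het)
        if method in ("weighted_median", "median"):
            est = estimators.weighted_median(self.data, **kwargs)
            return MRResults(self, est, None)
        raise ValueError(f"unknown method {method!r}")

    def fit_presso(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                   seed: int | None = None) -> PressoResult:
        return run_presso(self.data, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)

    def mean_f_statistic(self) -> tuple[float, bool]:
        return mean_f_statistic(self.data)


class MVMRResults:
    """Results of a multivariable MR fit (one direct effect per exposure)."""

    def __init__(self, model: "MultivariableMRModel", estimates: list[MREstimate]):
        self.model = model
        self.estimates = [to_odds_ratio(e) for e in estimates]

    @property
    def params(self) -> np.ndarray:
        return np.array([e.beta for e in self.estimates])

    @property
    def bse(self) -> np.ndarray:
        return np.array([e.se for e in self.estimates])

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([e.pvalue for e in self.estimates])

    def estimate_for(self, exposure: str) -> MREstimate:
        for name, e in zip(self.model.data.exposure_names, self.estimates):
            if name == exposure:
                return e
        raise KeyError(exposure)

    def summary(self) -> str:
        lines = [
            f"Multivariable MR ({len(self.model.data)} SNPs, "
            f"{len(self.estimates)} exposures)",
            "=" * 60,
            f"{'exposure':<20}{'beta':>10}{'se':>10}{'OR':>8}{'p':>12}",
        ]
        for name, e in zip(self.model.data.exposure_names, self.estimates):
            lines.append(
                f"{name:<20}{e.beta:>+10.4f}{e.se:>10.4f}"
                f"{e.or_point:>8.3f}{e.pvalue:>12.3g}"
            )
        return "\n".join(lines)


class MultivariableMRModel:
    def __init__(self, data: MVHarmonizedData):
        self.data = data

    def fit(self) -> MVMRResults:
        return MVMRResults(self, estimators.mvmr(self.data))
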