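"""Two-step MR mediation: product-of-coefficients indirect effect.

The indirect (mediated) effect of the exposure on the outcome through the
mediator is the product of the exposure→mediator effect (effect X) and the
mediator→outcome effect adjusted for the exposure (effect M, from
multivariable MR).  Its standard error uses the first-order delta method for
a product; the mediated proportion is the indirect effect as a percentage of
the total effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .estimators import Z95, MREstimate, _normal_p

__all__ = ["MediationResult", "se_from_ci", "mediation_analysis"]


@dataclass
class MediationResult:
    total: MREstimate
    effect_x: MREstimate
    effect_m: MREstimate
    indirect_beta: float
    indirect_se: float
    indirect_ci_low: float
    indirect_ci_high: float
    indirect_p: float
    proportion_pct: float
    proportion_ci_pct: tuple[float, float]
    proportion_ci_method: str

    def to_dict(self) -> dict:
        return {
            "total": self.total.to_dict(),
            "effect_x": self.effect_x.to_dict(),
            "effect_m": self.effect_m.to_dict(),
            "indirect_beta": self.indirect_beta,
            "indirect_se": self.indirect_se,
            "indirect_ci_low": self.indirect_ci_low,
            "indirect_ci_high": self.indirect_ci_high,
            "indirect_p": self.indirect_p,
            "proportion_pct": self.proportion_pct,
            "proportion_ci_pct": list(self.proportion_ci_pct),
            "proportion_ci_method": self.proportion_ci_method,
        }

    def table_row(self, exposure: str = "exposure", mediator: str = "mediator") -> dict:
        """Report-shaped row: effects to 3 decimals, proportions to 1."""

        def eff(e: MREstimate) -> str:
            return f"{e.beta:.3f} ({e.ci_low:.3f}, {e.ci_high:.3f})"

        return {
            "exposure": exposure,
            "mediator": mediator,
            "total_effect": eff(self.total),
            "effect_x": eff(self.effect_x),
            "effect_m": eff(self.effect_m),
            "mediation_effect": (
                f"{self.indirect_beta:.3f} "
                f"({self.indirect_ci_low:.3f}, {self.indirect_ci_high:.3f})"
            ),
            "p": f"{self.indirect_p:.3g}",
            "mediated_proportion": (
                f"{self.proportion_pct:.1f}% "
                f"({self.proportion_ci_pct[0]:.1f}, {self.proportion_ci_pct[1]:.1f})"
            ),
        }


def se_from_ci(low: float, high: float, level: float = 0.95) -> float:
    """Recover a standard error from a symmetric normal confidence interval."""
    if high <= low:
        raise ValueError(f"degenerate interval ({low}, {high})")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = Z95 if level == 0.95 else float(stats.norm.ppf((1 + level) / 2))
    return (high - low) / (2 * z)


def mediation_analysis(
    total: MREstimate,
    effect_x: MREstimate,
    effect_m: MREstimate,
    proportion_ci_method: str = "delta",
    include_second_order: bool = False,
) -> MediationResult:
    """Product-of-coefficients mediation with delta-method uncertainty.

    Parameters
    ----------
    total : MREstimate
        Univariable exposure→outcome effect (outlier-corrected when
        applicable).
    effect_x : MREstimate
        Univariable exposure→mediator effect.
    effect_m : MREstimate
        Mediator→outcome effect adjusted for the exposure (multivariable MR).
    proportion_ci_method : {"delta", "ratio_of_bounds"}
        ``delta`` treats indirect/total as a ratio of independent normals;
        ``ratio_of_bounds`` divides the indirect CI bounds by the total CI
        bounds (a nonstandard compatibility rule some reports use).
    include_second_order : bool
        Add the seX²·seM² term to the product variance (exact variance of a
        product of independent normals); off by default.
    """
    for name, est in (("total", total), ("effect_x", effect_x), ("effect_m", effect_m)):
        if est.se is None or not math.isfinite(est.se):
            raise ValueError(f"{name} estimate is missing a finite standard error")
    if total.beta == 0:
        raise ValueError("total effect is zero: mediated proportion undefined")
    if proportion_ci_method not in ("delta", "ratio_of_bounds"):
        raise ValueError(f"unknown proportion_ci_method {proportion_ci_method!r}")

    bx, sx = effect_x.beta, effect_x.se
    bm, sm_ = effect_m.beta, effect_m.se
    indirect = bx * bm
    var_ind = bx**2 * sm_**2 + bm**2 * sx**2
    if include_second_order:
        var_ind += sx**2 * sm_**2
    se_ind = math.sqrt(var_ind)
    ci_low = indirect - Z95 * se_ind
    ci_high = indirect + Z95 * se_ind
    p_ind = _normal_p(indirect, se_ind)

    prop = 100.0 * indirect / total.beta
    if proportion_ci_method == "delta":
        # first-order delta method for the ratio of two independent normals
        var_frac = var_ind / total.beta**2 + (indirect**2 * total.se**2) / total.beta**4
        half = Z95 * 100.0 * math.sqrt(var_frac)
        prop_ci = (prop - half, prop + half)
    else:
        prop_ci = (
            100.0 * ci_low / total.ci_low,
            100.0 * ci_high / total.ci_high,
        )

    return MediationResult(
        total=total,
        effect_x=effect_x,
        effect_m=effect_m,
        indirect_beta=indirect,
        indirect_se=se_ind,
        indirect_ci_low=ci_low,
        indirect_ci_high=ci_high,
        indirect_p=p_ind,
        proportion_pct=prop,
        proportion_ci_pct=prop_ci,
        proportion_ci_method=proportion_ci_method,
    )
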