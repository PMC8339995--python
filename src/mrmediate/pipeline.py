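"""End-to-end orchestration of the MR analysis chain.

``univariable_analysis``, ``multivariable_analysis`` and
``mediation_analysis_pipeline`` operate on in-memory summary-statistic
frames; the ``run_*`` wrappers read files per an :class:`AnalysisConfig` and
write machine-readable reports.  Every filtering stage logs counts in/out so
instrument attrition is auditable, and reports are byte-identical for
identical inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MREstimate
from .mediation import mediation_analysis
from .model import MRModel, MultivariableMRModel
from .summarystats import (
    LDMatrix,
    harmonize,
    harmonize_multi,
    ld_clump,
    read_ld_matrix,
    read_summary_stats,
    select_instruments,
)

__all__ = [
    "AnalysisConfig",
    "bonferroni_threshold",
    "significance_tier",
    "univariable_analysis",
    "multivariable_analysis",
    "mediation_analysis_pipeline",
    "run_univariable",
    "run_multivariable",
    "run_mediation",
    "write_report",
]

logger = logging.getLogger("mrmediate")

ESTIMATE_COLUMNS = [
    "method", "nsnp", "beta", "se", "ci_low", "ci_high", "pvalue",
    "or", "or_low", "or_high", "effects_model",
    "q", "q_p", "egger_intercept", "egger_intercept_p", "significance",
]


@dataclass
class AnalysisConfig:
    """Everything needed to run one analysis from files."""

    exposure: str | None = None
    outcome: str | None = None
    mediator: str | None = None
    exposures: list[str] = field(default_factory=list)  # multivariable
    ld: str | None = None
    column_map: dict | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 5000
    methods: tuple = ("ivw", "median", "egger", "presso")
    palindrome_policy: str = "infer_by_eaf"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int | None = None
    alpha_family: float = 0.05
    n_tests_family: int = 1

    def validate(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must lie in [0, 1]")
        if self.clump_window_kb < 0:
            raise ValueError("clump_window_kb must be >= 0")
        if not 0 < self.alpha_family < 1:
            raise ValueError("alpha_family must lie in (0, 1)")
        if self.n_tests_family < 1:
            raise ValueError("n_tests_family must be >= 1")
        stochastic = {"median", "weighted_median", "presso"}
        if stochastic & set(self.methods) and self.seed is None:
            raise ValueError("seed is mandatory when stochastic methods are requested")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def significance_tier(p: float, alpha: float, m: int) -> str:
    """Label a p-value against the Bonferroni and nominal thresholds."""
    thr = bonferroni_threshold(alpha, m)
    if p < thr:
        return "significant"
    if p < alpha:
        return "suggestive"
    return "not_significant"


def _prepare_instruments(
    assocs: pd.DataFrame,
    ld: LDMatrix | None,
    p_threshold: float,
    clump_r2: float,
    clump_window_kb: float,
) -> tuple[pd.DataFrame, dict]:
    counts = {"input": len(assocs)}
    instruments = select_instruments(assocs, p_threshold)
    counts["after_p_filter"] = len(instruments)
    if ld is not None and len(instruments):
        instruments = ld_clump(instruments, ld, clump_r2, clump_window_kb)
    counts["after_clump"] = len(instruments)
    return instruments, counts


def _estimate_rows(results: list, alpha: float, m: int) -> list[dict]:
    rows = []
    for res in results:
        row = res.to_row()
        row["significance"] = significance_tier(row["pvalue"], alpha, m)
        rows.append({c: row.get(c) for c in ESTIMATE_COLUMNS})
    return rows


def univariable_analysis(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix | None = None,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.01,
    clump_window_kb: float = 5000,
    methods: tuple = ("ivw", "median", "egger", "presso"),
    palindrome_policy: str = "infer_by_eaf",
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
    seed: int | None = None,
    alpha_family: float = 0.05,
    n_tests_family: int = 1,
) -> dict:
    """Instrument selection → clumping → harmonization → estimators.

    Returns a JSON-serialisable report with per-method estimates (OR scale
    included), heterogeneity/intercept diagnostics, the mean F statistic,
    stage attrition counts and the harmonization log.
    """
    instruments, counts = _prepare_instruments(
        exposure, ld, p_threshold, clump_r2, clump_window_kb
    )
    if len(instruments) < 1:
        raise ValueError(
            f"no instruments survive filtering (counts: {counts}); "
            "lower p_threshold or check the exposure file"
        )
    data = harmonize(instruments, outcome, palindrome_policy)
    counts["harmonized"] = len(data)
    if len(data) < 1:
        raise ValueError(f"no variants survive harmonization (counts: {counts})")
    model = MRModel(data)
    mean_f, weak = model.mean_f_statistic()
    logger.info("univariable: %d instruments, mean F = %.1f", len(data), mean_f)

    results = []
    if "ivw" in methods:
        results.append(model.fit("ivw", effects_model="auto"))
    if ("median" in methods or "weighted_median" in methods) and len(data) >= 3:
        results.append(model.fit("weighted_median", n_boot=n_boot, seed=seed))
    if "egger" in methods and len(data) >= 3:
        results.append(model.fit("egger"))
    report = {
        "analysis": "univariable",
        "counts": counts,
        "mean_f_statistic": mean_f,
        "weak_instruments": bool(weak),
        "significance_threshold": bonferroni_threshold(alpha_family, n_tests_family),
        "estimates": _estimate_rows(results, alpha_family, n_tests_family),
        "harmonization_log": data.log.to_dict("records"),
        "seed": seed,
    }
    if "presso" in methods and len(data) >= 4:
        presso = model.fit_presso(n_sim=presso_n_sim, seed=seed)
        report["presso"] = presso.to_dict()
    return report


def multivariable_analysis(
    exposures: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    ld: LDMatrix | None = None,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.01,
    clump_window_kb: float = 5000,
    palindrome_policy: str = "infer_by_eaf",
    alpha_family: float = 0.05,
    n_tests_family: int = 1,
) -> dict:
    """Multivariable MR over the union of per-exposure instruments.

    A variant enters the instrument set when genome-wide significant for at
    least one exposure; all exposures and the outcome are then harmonized on
    the shared variants and fitted jointly.
    """
    if len(exposures) < 2:
        raise ValueError("multivariable analysis requires >= 2 exposures; "
                         "use univariable_analysis for a single exposure")
    union_ids: list[str] = []
    seen = set()
    counts = {}
    for name, df in exposures.items():
        sig = select_instruments(df, p_threshold)
        if ld is not None and len(sig):
            sig = ld_clump(sig, ld, clump_r2, clump_window_kb)
        counts[name] = len(sig)
        for vid in sig["variant_id"]:
            if vid not in seen:
                seen.add(vid)
                union_ids.append(vid)
    counts["union"] = len(union_ids)
    restricted = {
        name: df[df["variant_id"].isin(seen)].reset_index(drop=True)
        for name, df in exposures.items()
    }
    data = harmonize_multi(restricted, outcome, palindrome_policy)
    counts["harmonized"] = len(data)
    fit = MultivariableMRModel(data).fit()
    return {
        "analysis": "multivariable",
        "counts": counts,
        "exposures": data.exposure_names,
        "estimates": _estimate_rows(
            [_MVRowAdapter(e) for e in fit.estimates], alpha_family, n_tests_family
        ),
        "harmonization_log": data.log.to_dict("records"),
    }


class _MVRowAdapter:
    """Present a bare MREstimate with the same row surface as MRResults."""

    def __init__(self, est: MREstimate):
        self.estimate = est

    def to_row(self) -> dict:
        e = self.estimate
        return {
            "method": e.method, "nsnp": e.n_snps, "beta": e.beta, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue,
            "or": e.or_point, "or_low": e.or_low, "or_high": e.or_high,
            "effects_model": e.effects_model,
            "q": None, "q_p": None, "egger_intercept": None, "egger_intercept_p": None,
        }


def _total_effect_estimate(report: dict) -> MREstimate:
    """IVW total effect, MR-PRESSO-corrected when outliers were found."""
    presso = report.get("presso")
    if presso and presso["outlier_indices"]:
        d = presso["adjusted_estimate"]
    else:
        d = next(r for r in report["estimates"] if r["method"] == "ivw")
    return MREstimate(
        method=d.get("method", "ivw"),
        beta=d["beta"], se=d["se"], ci_low=d["ci_low"], ci_high=d["ci_high"],
        pvalue=d["pvalue"], n_snps=d.get("nsnp") or d.get("n_snps"),
        effects_model=d.get("effects_model", "not_applicable"),
    )


def mediation_analysis_pipeline(
    exposure: pd.DataFrame,
    mediator: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    ld: LDMatrix | None = None,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.01,
    clump_window_kb: float = 5000,
    palindrome_policy: str = "infer_by_eaf",
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
    seed: int | None = None,
    proportion_ci_method: str = "delta",
) -> dict:
    """Two-step MR mediation.

    total = univariable exposure→outcome IVW (outlier-corrected when MR-PRESSO
    flags outliers); effect X = univariable exposure→mediator IVW (same rule);
    effect M = the mediator's direct effect from multivariable MR of the
    outcome on exposure and mediator jointly.
    """
    common = dict(
        ld=ld, p_threshold=p_threshold, clump_r2=clump_r2,
        clump_window_kb=clump_window_kb, palindrome_policy=palindrome_policy,
    )
    total_report = univariable_analysis(
        exposure, outcome, methods=("ivw", "presso"),
        n_boot=n_boot, presso_n_sim=presso_n_sim, seed=seed, **common,
    )
    step1_report = univariable_analysis(
        exposure, mediator, methods=("ivw", "presso"),
        n_boot=n_boot, presso_n_sim=presso_n_sim, seed=seed, **common,
    )
    mv_report = multivariable_analysis(
        {exposure_name: exposure, mediator_name: mediator}, outcome, **common
    )
    total = _total_effect_estimate(total_report)
    effect_x = _total_effect_estimate(step1_report)
    m_row = next(
        r for r in mv_report["estimates"] if r["method"] == f"mvmr[{mediator_name}]"
    )
    effect_m = MREstimate(
        method=m_row["method"], beta=m_row["beta"], se=m_row["se"],
        ci_low=m_row["ci_low"], ci_high=m_row["ci_high"],
        pvalue=m_row["pvalue"], n_snps=m_row["nsnp"],
    )
    med = mediation_analysis(total, effect_x, effect_m,
                             proportion_ci_method=proportion_ci_method)
    return {
        "analysis": "mediation",
        "exposure": exposure_name,
        "mediator": mediator_name,
        "mediation": med.to_dict(),
        "table_row": med.table_row(exposure_name, mediator_name),
        "total_report": total_report,
        "step1_report": step1_report,
        "multivariable_report": mv_report,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# file-level wrappers


def _read(path, column_map):
    df, report = read_summary_stats(path, column_map)
    logger.info("read %s: %d valid rows (%d dropped)", path, report.n_valid,
                report.n_dropped)
    return df


def run_univariable(config: AnalysisConfig) -> dict:
    config.validate()
    exposure = _read(config.exposure, config.column_map)
    outcome = _read(config.outcome, config.column_map)
    ld = read_ld_matrix(config.ld) if config.ld else None
    return univariable_analysis(
        exposure, outcome, ld=ld,
        p_threshold=config.p_threshold, clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb, methods=config.methods,
        palindrome_policy=config.palindrome_policy, n_boot=config.n_boot,
        presso_n_sim=config.presso_n_sim, seed=config.seed,
        alpha_family=config.alpha_family, n_tests_family=config.n_tests_family,
    )


def run_multivariable(config: AnalysisConfig) -> dict:
    config.validate()
    paths = config.exposures or ([config.exposure] if config.exposure else [])
    if len(paths) < 2:
        raise ValueError("multivariable analysis requires >= 2 exposure files; "
                         "use the univariable command for one exposure")
    exposures = {p: _read(p, config.column_map) for p in paths}
    outcome = _read(config.outcome, config.column_map)
    ld = read_ld_matrix(config.ld) if config.ld else None
    return multivariable_analysis(
        exposures, outcome, ld=ld,
        p_threshold=config.p_threshold, clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
        palindrome_policy=config.palindrome_policy,
        alpha_family=config.alpha_family, n_tests_family=config.n_tests_family,
    )


def run_mediation(config: AnalysisConfig) -> dict:
    config.validate()
    if not config.mediator:
        raise ValueError("mediation analysis requires a mediator file")
    exposure = _read(config.exposure, config.column_map)
    mediator = _read(config.mediator, config.column_map)
    outcome = _read(config.outcome, config.column_map)
    ld = read_ld_matrix(config.ld) if config.ld else None
    return mediation_analysis_pipeline(
        exposure, mediator, outcome, ld=ld,
        p_threshold=config.p_threshold, clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
        palindrome_policy=config.palindrome_policy,
        n_boot=config.n_boot, presso_n_sim=config.presso_n_sim, seed=config.seed,
    )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_report(report: dict, json_path=None, tsv_path=None) -> str:
    """Serialise a report: full-precision JSON and a rounded estimate TSV."""
    text = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    if json_path:
        with open(json_path, "w") as fh:
            fh.write(text + "\n")
    if tsv_path and "estimates" in report:
        rows = []
        for row in report["estimates"]:
            rounded = {}
            for key, val in row.items():
                if isinstance(val, float):
                    rounded[key] = round(val, 4) if key != "pvalue" else f"{val:.3g}"
                else:
                    rounded[key] = val
            rows.append(rounded)
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return text
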