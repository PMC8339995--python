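"""Reading, validation, filtering, clumping and harmonization of GWAS summary statistics.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per variant and the columns

``variant_id, chromosome, position_bp, effect_allele, other_allele, eaf, beta,
se, pvalue, n``

(beta is the additive effect per copy of the effect allele: log-odds for binary
traits, SD units for continuous ones).  Files are delimited text with a header
row; the default column names follow the GWAS-SSF-style dialect
``variant_id, chr, pos, ea, oa, eaf, beta, se, pval, n`` and can be remapped
with ``column_map``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SUMMARY_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "VariantAssociation",
    "ReadReport",
    "LDMatrix",
    "HarmonizedData",
    "MVHarmonizedData",
    "read_summary_stats",
    "write_summary_stats",
    "validate_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "select_instruments",
    "ld_clump",
    "harmonize",
    "harmonize_multi",
    "mean_f_statistic",
]

#: canonical column order of the in-memory container
SUMMARY_COLUMNS = [
    "variant_id",
    "chromosome",
    "position_bp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: canonical name -> default file column name
DEFAULT_COLUMN_MAP = {
    "variant_id": "variant_id",
    "chromosome": "chr",
    "position_bp": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

_NUCLEOTIDES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class VariantAssociation:
    """One variant's summary association with a single trait."""

    variant_id: str
    chromosome: str
    position_bp: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float | None = None

    def is_valid(self) -> bool:
        return _row_problem(self.__dict__) is None


@dataclass
class ReadReport:
    """Row-level accounting for :func:`read_summary_stats`."""

    n_read: int = 0
    n_valid: int = 0
    n_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)


def _row_problem(rec: dict) -> str | None:
    """Return a reason code if the record violates an invariant, else None."""
    ea = rec.get("effect_allele")
    oa = rec.get("other_allele")
    if not (isinstance(ea, str) and ea.upper() in _NUCLEOTIDES):
        return "bad_effect_allele"
    if not (isinstance(oa, str) and oa.upper() in _NUCLEOTIDES):
        return "bad_other_allele"
    if ea.upper() == oa.upper():
        return "identical_alleles"
    beta = rec.get("beta")
    se = rec.get("se")
    p = rec.get("pvalue")
    if beta is None or not math.isfinite(beta):
        return "bad_beta"
    if se is None or not math.isfinite(se) or se <= 0:
        return "nonpositive_se"
    if p is None or not math.isfinite(p) or not (0 < p <= 1):
        return "bad_pvalue"
    eaf = rec.get("eaf")
    if eaf is not None and not (isinstance(eaf, float) and math.isnan(eaf)):
        if not (0 < eaf < 1):
            return "bad_eaf"
    n = rec.get("n")
    if n is not None and not (isinstance(n, float) and math.isnan(n)):
        if n <= 0:
            return "bad_n"
    pos = rec.get("position_bp")
    if pos is None or (isinstance(pos, float) and math.isnan(pos)) or pos < 1:
        return "bad_position"
    return None


def validate_summary_stats(df: pd.DataFrame) -> tuple[pd.DataFrame, ReadReport]:
    """Drop rows violating the per-variant invariants; count them by reason."""
    report = ReadReport(n_read=len(df))
    keep = np.ones(len(df), dtype=bool)
    records = df.to_dict("records")
    for i, rec in enumerate(records):
        problem = _row_problem(rec)
        if problem is not None:
            keep[i] = False
            report.drop_reasons[problem] += 1
    out = df.loc[keep].copy()
    out["effect_allele"] = out["effect_allele"].str.upper()
    out["other_allele"] = out["other_allele"].str.upper()
    out["chromosome"] = out["chromosome"].astype(str)
    out["position_bp"] = out["position_bp"].astype(np.int64)
    report.n_valid = len(out)
    report.n_dropped = report.n_read - report.n_valid
    return out.reset_index(drop=True), report


def read_summary_stats(
    path,
    column_map: dict | None = None,
    sep: str = "\t",
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a delimited summary-statistics file into the canonical frame.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with a header row.
    column_map : dict, optional
        Mapping from canonical names (keys of :data:`DEFAULT_COLUMN_MAP`) to
        the column names used in the file.  Unspecified entries fall back to
        the defaults.  ``eaf`` and ``n`` are optional columns.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ValueError(f"unknown canonical column names: {sorted(unknown)}")
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if raw.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    optional = {"eaf", "n"}
    data = {}
    for canon, src in cmap.items():
        if src not in raw.columns:
            if canon in optional:
                data[canon] = np.nan
                continue
            raise ValueError(f"missing mandatory column {src!r} (for {canon}) in {path}")
        data[canon] = raw[src]
    df = pd.DataFrame(data)[SUMMARY_COLUMNS]
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return validate_summary_stats(df)


def write_summary_stats(df: pd.DataFrame, path, column_map: dict | None = None) -> None:
    """Write the canonical frame back to the TSV dialect read_summary_stats reads."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = df[SUMMARY_COLUMNS].rename(columns=cmap)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD matrix


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        ids = list(self.variant_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in LD matrix")
        if self.r2.shape != (len(ids), len(ids)):
            raise ValueError("LD matrix shape does not match variant id count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r² values must lie in [0, 1]")
        self.variant_ids = ids
        self._index = {v: i for i, v in enumerate(ids)}

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index


def read_ld_matrix(path) -> LDMatrix:
    """Read a square TSV r² matrix with an id header row and id first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(variant_ids=[str(c) for c in df.columns], r2=df.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# Instrument selection and clumping


def select_instruments(df: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep variants with p strictly below the genome-wide threshold.

    The comparison is strict (<), so boundary values are excluded.  Original
    row order is preserved.  An empty survivor set is returned as an empty
    frame (downstream estimators raise on empty input).
    """
    if len(df) == 0:
        raise ValueError("no variants supplied to select_instruments")
    out = df.loc[df["pvalue"] < p_threshold].reset_index(drop=True)
    return out


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), chrom)
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


def ld_clump(
    df: pd.DataFrame,
    ld: LDMatrix,
    r2_threshold: float = 0.01,
    window_kb: float = 5000,
) -> pd.DataFrame:
    """Greedy LD clumping.

    Repeatedly keep the remaining variant with the smallest p-value (ties
    broken by smaller position, then lexicographic id) and discard all
    remaining variants on the same chromosome within ``window_kb`` kilobases
    whose r² with the kept variant exceeds ``r2_threshold``.  The result is
    sorted by chromosome then position.
    """
    missing = [v for v in df["variant_id"] if v not in ld]
    if missing:
        raise ValueError(f"variant id {missing[0]!r} absent from LD matrix")
    window_bp = window_kb * 1000.0
    remaining = df.to_dict("records")
    kept: list[dict] = []
    while remaining:
        best = min(
            remaining,
            key=lambda r: (r["pvalue"], r["position_bp"], r["variant_id"]),
        )
        kept.append(best)
        survivors = []
        for rec in remaining:
            if rec is best:
                continue
            same_chrom = str(rec["chromosome"]) == str(best["chromosome"])
            close = abs(rec["position_bp"] - best["position_bp"]) <= window_bp
            linked = ld.r2_between(rec["variant_id"], best["variant_id"]) > r2_threshold
            if same_chrom and close and linked:
                continue
            survivors.append(rec)
        remaining = survivors
    kept.sort(key=lambda r: (_chrom_sort_key(str(r["chromosome"])), r["position_bp"]))
    return pd.DataFrame(kept, columns=df.columns).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizedData:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``table`` has columns ``variant_id, beta_exposure, se_exposure,
    beta_outcome, se_outcome``; ``log`` records every flip and drop as
    ``(variant_id, action, reason)``.
    """

    table: pd.DataFrame
    log: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (
            t["beta_exposure"].to_numpy(float),
            t["se_exposure"].to_numpy(float),
            t["beta_outcome"].to_numpy(float),
            t["se_outcome"].to_numpy(float),
        )

    def drop_indices(self, indices) -> "HarmonizedData":
        mask = np.ones(len(self.table), dtype=bool)
        mask[list(indices)] = False
        return HarmonizedData(table=self.table.loc[mask].reset_index(drop=True),
                              log=self.log)


@dataclass
class MVHarmonizedData:
    """Per-variant effects for K >= 2 exposures aligned with one outcome."""

    variant_ids: list[str]
    exposure_names: list[str]
    beta_exposures: np.ndarray  # J x K
    se_exposures: np.ndarray  # J x K
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    log: pd.DataFrame

    def __len__(self) -> int:
        return len(self.variant_ids)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC_PAIRS


def _ambiguous_eaf(eaf, lo=0.42, hi=0.58) -> bool:
    return eaf is None or (isinstance(eaf, float) and math.isnan(eaf)) or lo <= eaf <= hi


def _align_orientation(ref_ea, ref_oa, ea, oa, eaf_ref, eaf_other, palindrome_policy):
    """Decide how to map a second study's effect onto the reference allele.

    Returns (sign, reason) where sign is +1 (same orientation), -1 (flip) or
    None (drop, with the reason code).
    """
    if _is_palindromic(ref_ea, ref_oa):
        if {ea, oa} != {ref_ea, ref_oa}:
            return None, "allele_mismatch"
        if palindrome_policy == "drop_all":
            return None, "palindromic"
        # letters cannot resolve the strand: align by allele frequency
        if _ambiguous_eaf(eaf_ref) or _ambiguous_eaf(eaf_other):
            return None, "ambiguous_palindrome"
        eaf_oriented = eaf_other if ea == ref_ea else 1.0 - eaf_other
        same_side = (eaf_ref < 0.5) == (eaf_oriented < 0.5)
        letter_sign = 1 if ea == ref_ea else -1
        return (letter_sign if same_side else -letter_sign), "palindrome_eaf"
    if (ea, oa) == (ref_ea, ref_oa):
        return 1, "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return -1, "swapped"
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return 1, "strand_flip"
    if (cea, coa) == (ref_oa, ref_ea):
        return -1, "strand_flip_swapped"
    return None, "allele_mismatch"


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "infer_by_eaf",
) -> HarmonizedData:
    """Align outcome effects to the exposure's effect alleles.

    Swapped alleles (allowing strand complements) negate the outcome beta and
    reflect its allele frequency.  Palindromic variants (A/T, G/C) are dropped
    under ``drop_all`` or aligned by allele frequency under ``infer_by_eaf``
    (dropped when either frequency is missing or inside [0.42, 0.58]).
    """
    if palindrome_policy not in ("drop_all", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp = exposure.drop_duplicates("variant_id", keep="first")
    out = outcome.drop_duplicates("variant_id", keep="first")
    out_by_id = {r["variant_id"]: r for r in out.to_dict("records")}
    shared = [v for v in exp["variant_id"] if v in out_by_id]
    if not shared:
        raise ValueError("exposure and outcome share no variant ids")
    rows, log = [], []
    for rec_x in exp.to_dict("records"):
        vid = rec_x["variant_id"]
        if vid not in out_by_id:
            continue
        rec_y = out_by_id[vid]
        sign, reason = _align_orientation(
            rec_x["effect_allele"],
            rec_x["other_allele"],
            rec_y["effect_allele"],
            rec_y["other_allele"],
            rec_x.get("eaf"),
            rec_y.get("eaf"),
            palindrome_policy,
        )
        if sign is None:
            log.append((vid, "drop", reason))
            continue
        if sign == -1 or reason not in ("same",):
            action = "flip" if sign == -1 else "keep"
            log.append((vid, action, reason))
        rows.append(
            {
                "variant_id": vid,
                "beta_exposure": rec_x["beta"],
                "se_exposure": rec_x["se"],
                "beta_outcome": sign * rec_y["beta"],
                "se_outcome": rec_y["se"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["variant_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"],
    )
    log_df = pd.DataFrame(log, columns=["variant_id", "action", "reason"])
    return HarmonizedData(table=table, log=log_df)


def harmonize_multi(
    exposures: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    palindrome_policy: str = "infer_by_eaf",
) -> MVHarmonizedData:
    """Align K >= 2 exposures and the outcome to the first exposure's alleles.

    Only variants present in every study with reconcilable alleles are kept.
    """
    names = list(exposures)
    if len(names) < 2:
        raise ValueError("multivariable harmonization requires >= 2 exposures")
    ref_name = names[0]
    ref = exposures[ref_name].drop_duplicates("variant_id", keep="first")
    others = {name: {r["variant_id"]: r
                     for r in exposures[name].drop_duplicates("variant_id").to_dict("records")}
              for name in names[1:]}
    others["__outcome__"] = {
        r["variant_id"]: r
        for r in outcome.drop_duplicates("variant_id").to_dict("records")
    }
    rows, log = [], []
    for rec_ref in ref.to_dict("records"):
        vid = rec_ref["variant_id"]
        if any(vid not in table for table in others.values()):
            continue
        betas = {ref_name: rec_ref["beta"]}
        ses = {ref_name: rec_ref["se"]}
        dropped = False
        for name, table in others.items():
            rec = table[vid]
            sign, reason = _align_orientation(
                rec_ref["effect_allele"],
                rec_ref["other_allele"],
                rec["effect_allele"],
                rec["other_allele"],
                rec_ref.get("eaf"),
                rec.get("eaf"),
                palindrome_policy,
            )
            if sign is None:
                log.append((vid, "drop", reason))
                dropped = True
                break
            if sign == -1:
                log.append((vid, "flip", f"{name}:{reason}"))
            betas[name] = sign * rec["beta"]
            ses[name] = rec["se"]
        if dropped:
            continue
        rows.append((vid, betas, ses))
    if not rows:
        raise ValueError("no variants shared by all studies after harmonization")
    variant_ids = [r[0] for r in rows]
    beta_x = np.array([[r[1][name] for name in names] for r in rows], dtype=float)
    se_x = np.array([[r[2][name] for name in names] for r in rows], dtype=float)
    beta_y = np.array([r[1]["__outcome__"] for r in rows], dtype=float)
    se_y = np.array([r[2]["__outcome__"] for r in rows], dtype=float)
    log_df = pd.DataFrame(log, columns=["variant_id", "action", "reason"])
    return MVHarmonizedData(
        variant_ids=variant_ids,
        exposure_names=names,
        beta_exposures=beta_x,
        se_exposures=se_x,
        beta_outcome=beta_y,
        se_outcome=se_y,
        log=log_df,
    )


def mean_f_statistic(data: HarmonizedData) -> tuple[float, bool]:
    """Mean per-instrument F (squared exposure Z) and a weak-instrument flag.

    The per-variant F is approximated by (beta_exposure / se_exposure)²; the
    flag is raised when the mean falls below the conventional threshold of 10.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    bx, sx, _, _ = data.arrays()
    f = float(np.mean((bx / sx) ** 2))
    return f, f < 10.0
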