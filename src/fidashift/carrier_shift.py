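"""Cohort pipeline: the Delta R_h carrier-shift statistic and its clinical
associations.

Per sample, two apparent radii are measured: r_capmix (capillary-mix method,
sensitive to the fast S1P-FITC/HSA association) and r_capdis
(complex-dissociation method, additionally reflecting equilibrated
S1P-FITC/HDL complexes).  Their difference

    Delta R_h = r_capdis - r_capmix

indexes the reallocation of the indicator from albumin to HDL: positive and
growing values mean HDL-shifted binding.  Group contrasts use two-sided
Mann-Whitney U tests (exact null enumeration for small groups), method
agreement with LC-MS/MS fractionation uses Spearman rank correlation, and
outcome association compares r_capdis (and CRP) between ventilated /
non-ventilated and surviving / deceased patients.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "SOFA_BINS",
    "delta_rh",
    "add_delta_rh",
    "sofa_reclassify",
    "group_compare",
    "mannwhitney_exact_bruteforce",
    "spearman",
    "correlate_with_lcms",
    "outcome_association",
    "analyze_cohort",
    "CohortResult",
]

GROUPS = ("control", "trauma", "sepsis", "septic_shock")
PATIENT_GROUPS = ("trauma", "sepsis", "septic_shock")
SOFA_BINS = ("<=3", "4-7", ">=8")

#: Largest min(n) at which the exact Mann-Whitney null is used.
EXACT_MIN_N = 8


# ---------------------------------------------------------------------------
# Delta R_h
# ---------------------------------------------------------------------------

def delta_rh(r_capmix, r_capdis, hdl_positive: bool = True):
    """Carrier-shift statistic (nm).

    Default sign convention ``hdl_positive=True`` returns
    r_capdis - r_capmix, so a shift of the indicator toward HDL is positive.
    Set ``hdl_positive=False`` to flip the sign.  Missing inputs (NaN/None)
    propagate to a missing output.
    """
    a = np.asarray(r_capmix, dtype=float)
    b = np.asarray(r_capdis, dtype=float)
    out = b - a if hdl_positive else a - b
    n_missing = int(np.sum(~np.isfinite(np.atleast_1d(out))))
    if n_missing:
        logger.info("delta_rh: %d sample(s) missing one of the two radii", n_missing)
    return float(out) if out.ndim == 0 else out


def add_delta_rh(cohort: pd.DataFrame, hdl_positive: bool = True) -> pd.DataFrame:
    """Return a copy of the cohort table with a ``delta_rh`` column."""
    out = cohort.copy()
    out["delta_rh"] = delta_rh(out["r_capmix"].to_numpy(),
                               out["r_capdis"].to_numpy(), hdl_positive)
    return out


# ---------------------------------------------------------------------------
# SOFA reclassification
# ---------------------------------------------------------------------------

def sofa_reclassify(cohort: pd.DataFrame) -> pd.Series:
    """Bin patients by SOFA score: '<=3', '4-7', '>=8'; controls stay 'control'.

    Controls are labelled by group, not by any SOFA value they might carry.
    Patients with missing SOFA get NA.  Negative scores are an error.
    """
    sofa = pd.to_numeric(cohort["sofa"], errors="coerce")
    if (sofa.dropna() < 0).any():
        raise ValueError("SOFA scores must be >= 0")
    labels = pd.Series(pd.NA, index=cohort.index, dtype="object")
    is_control = cohort["group"] == "control"
    labels[is_control] = "control"
    patient = ~is_control
    labels[patient & (sofa <= 3)] = "<=3"
    labels[patient & (sofa >= 4) & (sofa <= 7)] = "4-7"
    labels[patient & (sofa >= 8)] = ">=8"
    return labels


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a versus b with average-rank ties."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2.0


def mannwhitney_exact_bruteforce(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Brute-force permutation of group labels over the pooled sample; handles
    ties by average ranks.  Exponential in n -- use only at oracle scale.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    u_obs = _u_statistic(a, b)
    mid = n1 * b.size / 2.0
    dev_obs = abs(u_obs - mid)
    count = 0
    total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(idx)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mid) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def group_compare(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U comparison of two groups.

    Exact null enumeration when min(n) <= 8 and the pooled data are
    tie-free; tie-corrected normal approximation otherwise.  All-tied data
    yield p = 1 with a warning flag.  Each group needs n >= 3.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("group_compare requires n >= 3 in each group")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        logger.warning("group_compare: all values tied; p set to 1")
        return {"U": a.size * b.size / 2.0, "p": 1.0, "n_a": int(a.size),
                "n_b": int(b.size), "method": "degenerate_all_tied"}
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= EXACT_MIN_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        method = "asymptotic_tie_corrected"
    return {"U": float(res.statistic), "p": float(res.pvalue),
            "n_a": int(a.size), "n_b": int(b.size), "method": method}


def spearman(x, y) -> dict:
    """Spearman rank correlation with pairwise deletion of missing values.

    Average ranks for ties.  Refuses fewer than 4 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 4:
        raise ValueError(f"spearman requires >= 4 complete pairs, got {n}")
    rho, p = stats.spearmanr(x[keep], y[keep])
    return {"rho": float(rho), "p": float(p), "n": n}


def correlate_with_lcms(cohort: pd.DataFrame) -> dict:
    """Cross-method agreement: FIDA radii versus LC-MS/MS S1P fractions.

    r_capdis should track the HDL-bound S1P fraction and r_capmix the
    HSA-bound fraction (both positively).
    """
    return {
        "capdis_vs_hdl_frac": spearman(cohort["r_capdis"],
                                       cohort["lcms_frac_hdl"]),
        "capmix_vs_hsa_frac": spearman(cohort["r_capmix"],
                                       cohort["lcms_frac_hsa"]),
    }


def _binary_outcome_compare(df: pd.DataFrame, value_col: str,
                            outcome_col: str) -> dict | None:
    """MW comparison of ``value_col`` between the two outcome classes."""
    sub = df.dropna(subset=[value_col, outcome_col])
    pos = sub.loc[sub[outcome_col].astype(bool), value_col].to_numpy(float)
    neg = sub.loc[~sub[outcome_col].astype(bool), value_col].to_numpy(float)
    if pos.size < 3 or neg.size < 3:
        logger.info("outcome comparison %s by %s skipped (n=%d/%d)",
                    value_col, outcome_col, pos.size, neg.size)
        return None
    cmp = group_compare(pos, neg)
    cmp["median_positive"] = float(np.median(pos))
    cmp["median_negative"] = float(np.median(neg))
    cmp["direction"] = ("positive_higher" if cmp["median_positive"]
                        > cmp["median_negative"] else "positive_lower")
    return cmp


def outcome_association(cohort: pd.DataFrame, subgroup: str = "septic_shock",
                        alpha: float = 0.05) -> dict:
    """Outcome analysis within the severe subgroup.

    ``subgroup`` is 'septic_shock' (group label) or 'sofa>=8' (reclassified
    bin).  Compares r_capdis and CRP between ventilated / non-ventilated and
    deceased / surviving patients.  Also reports the diagnostic contrast of
    interest: whether r_capdis separates both outcomes while CRP separates
    ventilation only.
    """
    if subgroup == "septic_shock":
        sub = cohort[cohort["group"] == "septic_shock"]
    elif subgroup in ("sofa>=8", ">=8"):
        sub = cohort[sofa_reclassify(cohort) == ">=8"]
    else:
        raise ValueError(f"unknown subgroup {subgroup!r}")

    out: dict = {"subgroup": subgroup, "n": int(len(sub))}
    if len(sub) < 5:
        logger.info("outcome_association: subgroup %s too small (n=%d), skipped",
                    subgroup, len(sub))
        out["skipped"] = True
        return out
    out["skipped"] = False
    for value in ("r_capdis", "crp"):
        for outcome in ("ventilated", "survived"):
            out[f"{value}_by_{outcome}"] = _binary_outcome_compare(sub, value, outcome)

    rv, rs = out["r_capdis_by_ventilated"], out["r_capdis_by_survived"]
    cv, cs = out["crp_by_ventilated"], out["crp_by_survived"]
    out["rh_separates_both_outcomes"] = bool(
        rv and rs and rv["p"] < alpha and rs["p"] < alpha
    )
    out["crp_separates_ventilation_only"] = bool(
        cv and cs and cv["p"] < alpha and cs["p"] >= alpha
    )
    return out


# ---------------------------------------------------------------------------
# full cohort analysis
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Aggregated cohort analysis: group summaries, contrasts, correlations."""

    group_summary: pd.DataFrame
    pairwise_tests: dict
    sofa_summary: pd.DataFrame
    lcms_correlations: dict
    outcome: dict
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group_summary": self.group_summary.to_dict(orient="index"),
            "pairwise_tests": self.pairwise_tests,
            "sofa_summary": self.sofa_summary.to_dict(orient="index"),
            "lcms_correlations": self.lcms_correlations,
            "outcome": self.outcome,
            "config": self.config,
        }


_MEASURES = ("r_capmix", "r_capdis", "delta_rh")


def _summary_table(cohort: pd.DataFrame, by: pd.Series, order) -> pd.DataFrame:
    rows = {}
    for level in order:
        sub = cohort[by == level]
        row = {}
        for m in _MEASURES:
            vals = pd.to_numeric(sub[m], errors="coerce").dropna()
            row[f"{m}_n"] = int(vals.size)
            row[f"{m}_mean"] = float(vals.mean()) if vals.size else math.nan
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
        rows[level] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def analyze_cohort(cohort: pd.DataFrame, hdl_positive: bool = True) -> CohortResult:
    """Run the full cohort analysis on a sample table.

    Expects columns: sample_id, group, r_capmix, r_capdis, sofa, ventilated,
    survived, crp, lcms_frac_hsa, lcms_frac_hdl (missing values allowed,
    pairwise deletion per comparison).  No multiple-testing adjustment is
    applied; p-values are reported per contrast.
    """
    cohort = add_delta_rh(cohort, hdl_positive)
    group = cohort["group"]
    group_summary = _summary_table(cohort, group, GROUPS)

    pairwise: dict = {}
    for m in _MEASURES:
        pairwise[m] = {}
        for ga, gb in itertools.combinations(GROUPS, 2):
            va = pd.to_numeric(cohort.loc[group == ga, m], errors="coerce").dropna()
            vb = pd.to_numeric(cohort.loc[group == gb, m], errors="coerce").dropna()
            if va.size >= 3 and vb.size >= 3:
                pairwise[m][f"{ga}_vs_{gb}"] = group_compare(va, vb)

    sofa_bins = sofa_reclassify(cohort)
    sofa_summary = _summary_table(cohort, sofa_bins, ("control",) + SOFA_BINS)

    try:
        lcms = correlate_with_lcms(cohort)
    except (KeyError, ValueError):
        lcms = {}

    outcome = {
        "septic_shock": outcome_association(cohort, "septic_shock"),
        "sofa>=8": outcome_association(cohort, "sofa>=8"),
    }
    return CohortResult(
        group_summary=group_summary, pairwise_tests=pairwise,
        sofa_summary=sofa_summary, lcms_correlations=lcms,
        outcome=outcome, config={"hdl_positive": hdl_positive},
    )
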