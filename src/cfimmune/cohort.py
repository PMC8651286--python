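"""Cohort-level statistics for longitudinal cell-type cfDNA measurements.

Covers intra-/inter-individual coefficient-of-variation analysis with
balanced subset enumeration, baseline fold change, vaccination responder
classification from HI titers, ROC analysis, nonparametric group tests and
cfDNA/count ratios. Long-format tables carry columns (donor_id, timepoint,
source, analyte, value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .constants import HI_TITER_CUTOFF

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("donor_id", "timepoint", "source", "analyte", "value")


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) over the mean.

    NaN when the mean is zero (undefined); requires n >= 2.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def _subset(table: pd.DataFrame, analyte: str, source: str) -> pd.DataFrame:
    sub = table[(table["analyte"] == analyte) & (table["source"] == source)]
    if sub.empty:
        raise ValueError(f"no rows for analyte={analyte!r} source={source!r}")
    return sub


def intra_cv(table: pd.DataFrame, analyte: str, source: str) -> float:
    """Mean over donors of each donor's CV across their timepoints."""
    sub = _subset(table, analyte, source)
    cvs = []
    for donor, grp in sub.groupby("donor_id"):
        if len(grp) < 2:
            logger.info("donor %s: <2 timepoints, skipped", donor)
            continue
        cv = coefficient_of_variation(grp["value"].to_numpy())
        if math.isnan(cv):
            logger.info("donor %s: undefined CV (zero mean), excluded", donor)
            continue
        cvs.append(cv)
    if not cvs:
        raise ValueError("no donor with a defined intra-individual CV")
    return float(np.mean(cvs))


def inter_cv_balanced(table: pd.DataFrame, analyte: str, source: str,
                      group_size: int = 6, per_timepoint: bool = True,
                      max_exact: int = 10**6, n_samples: int = 10**5,
                      seed: int | None = None,
                      return_detail: bool = False,
                      ) -> float | tuple[float, int]:
    """Mean across-donor CV over all donor subsets of ``group_size``.

    For each subset, the CV across the subset's donors is computed per
    timepoint and averaged over timepoints (``per_timepoint=False``
    computes a single CV of the donors' time-averaged values). All
    subsets are enumerated exactly when their number is at most
    ``max_exact``; beyond that, ``n_samples`` subsets are drawn with
    ``seed``.
    """
    sub = _subset(table, analyte, source)
    wide = sub.pivot_table(index="donor_id", columns="timepoint",
                           values="value")
    donors = wide.index.to_numpy()
    n = len(donors)
    if group_size > n:
        raise ValueError(f"group_size {group_size} > {n} donors")
    mat = wide.to_numpy()

    n_subsets = math.comb(n, group_size)
    if n_subsets <= max_exact:
        subsets = combinations(range(n), group_size)
    else:
        rng = np.random.default_rng(seed)
        subsets = (tuple(rng.choice(n, size=group_size, replace=False))
                   for _ in range(n_samples))

    cvs = []
    for idx in subsets:
        block = mat[list(idx), :]
        if per_timepoint:
            means = np.nanmean(block, axis=0)
            sds = np.nanstd(block, axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                per_tp = np.where(means != 0, sds / means, np.nan)
            cvs.append(np.nanmean(per_tp))
        else:
            donor_means = np.nanmean(block, axis=1)
            cvs.append(coefficient_of_variation(donor_means))
    mean_cv = float(np.nanmean(cvs))
    if return_detail:
        return mean_cv, len(cvs)
    return mean_cv


@dataclass(frozen=True)
class CVSummary:
    analyte: str
    source: str
    intra_cv: float
    inter_cv: float
    n_donors: int
    group_size: int


def cv_summary(table: pd.DataFrame, analyte: str, source: str,
               group_size: int = 6, seed: int | None = None) -> CVSummary:
    n_donors = _subset(table, analyte, source)["donor_id"].nunique()
    return CVSummary(
        analyte=analyte, source=source,
        intra_cv=intra_cv(table, analyte, source),
        inter_cv=inter_cv_balanced(table, analyte, source,
                                   group_size=group_size, seed=seed),
        n_donors=n_donors, group_size=group_size)


def fold_change_from_baseline(table: pd.DataFrame,
                              baseline_timepoint: str = "D0") -> pd.DataFrame:
    """Per donor/source/analyte: value(t) / value(baseline).

    Donors whose baseline is zero or missing are excluded for that analyte
    (no pseudo-count), with a log entry.
    """
    out_rows = []
    for (donor, source, analyte), grp in table.groupby(
            ["donor_id", "source", "analyte"]):
        base = grp.loc[grp["timepoint"] == baseline_timepoint, "value"]
        if base.empty or base.iloc[0] == 0:
            logger.info("donor %s %s/%s: baseline missing or zero, excluded",
                        donor, source, analyte)
            continue
        b = float(base.iloc[0])
        for _, row in grp.iterrows():
            out_rows.append({
                "donor_id": donor, "timepoint": row["timepoint"],
                "source": source, "analyte": analyte,
                "fold_change": row["value"] / b})
    return pd.DataFrame(out_rows, columns=["donor_id", "timepoint", "source",
                                           "analyte", "fold_change"])


RESPONDER = "responder"
NON_RESPONDER = "non_responder"
EXCLUDED = "excluded"


def classify_responders(titers: pd.DataFrame,
                        cutoff: float = HI_TITER_CUTOFF) -> pd.DataFrame:
    """Classify donors by hemagglutination-inhibition seroconversion.

    Columns required: donor_id, strain, baseline_titer, post_titer
    (reciprocal dilutions). Strains with baseline titer < cutoff are
    eligible; a donor with no eligible strain (antibodies against all
    strains at baseline) is excluded. Responder iff at least one eligible
    strain has post titer strictly above the cutoff.
    """
    rows = []
    for donor, grp in titers.groupby("donor_id"):
        eligible = grp[grp["baseline_titer"] < cutoff]
        if eligible.empty:
            rows.append({"donor_id": donor, "status": EXCLUDED,
                         "reason": "antibodies against all strains at "
                                   "baseline"})
            continue
        post = eligible["post_titer"]
        if post.isna().all():
            rows.append({"donor_id": donor, "status": EXCLUDED,
                         "reason": "no post titer on any eligible strain"})
            continue
        status = RESPONDER if (post > cutoff).any() else NON_RESPONDER
        rows.append({"donor_id": donor, "status": status, "reason": ""})
    return pd.DataFrame(rows, columns=["donor_id", "status", "reason"])


def roc_auc(case_scores: Sequence[float], control_scores: Sequence[float],
            ) -> tuple[float, pd.DataFrame]:
    """Empirical ROC for cases vs controls.

    AUC follows the rank/trapezoid convention (equals the Mann-Whitney U
    statistic over n1*n2). Returns (auc, curve) with curve columns fpr and
    tpr.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be non-empty")
    labels = np.r_[np.ones(cases.size), np.zeros(controls.size)]
    scores = np.r_[cases, controls]
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr})


def group_compare(groups: Sequence[Sequence[float]], method: str,
                  alternative: str = "two-sided") -> tuple[float, float]:
    """Nonparametric (or correlation) comparison of value series.

    ``rank_sum_2``: Mann-Whitney U for two groups (exact at small n
    without ties, normal approximation with tie correction otherwise);
    ``kruskal_wallis``: >= 2 groups; ``pearson``: two paired series.
    Returns (statistic, p_value).
    """
    if method == "rank_sum_2":
        if len(groups) != 2:
            raise ValueError("rank_sum_2 needs exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1],
                                 alternative=alternative, method="auto")
        return float(res.statistic), float(res.pvalue)
    if method == "kruskal_wallis":
        if len(groups) < 2:
            raise ValueError("kruskal_wallis needs >= 2 groups")
        res = stats.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    if method == "pearson":
        if len(groups) != 2 or len(groups[0]) != len(groups[1]):
            raise ValueError("pearson needs two paired series")
        res = stats.pearsonr(groups[0], groups[1])
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def cfdna_count_ratio(table: pd.DataFrame, cfdna_source: str = "cfDNA",
                      count_source: str = "CBC") -> pd.DataFrame:
    """Per donor/analyte ratio of cfDNA percentage to blood-count
    percentage; zero denominators yield NaN with a flag."""
    keys = ["donor_id", "analyte"]
    if "timepoint" in table.columns and table["timepoint"].nunique() > 1:
        keys = ["donor_id", "timepoint", "analyte"]
    cf = table[table["source"] == cfdna_source]
    cc = table[table["source"] == count_source]
    merged = cf.merge(cc, on=keys, suffixes=("_cfdna", "_count"))
    if merged.empty:
        raise ValueError("no matched cfDNA/count pairs")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(merged["value_count"] != 0,
                         merged["value_cfdna"] / merged["value_count"],
                         np.nan)
    out = merged[keys].copy()
    out["ratio"] = ratio
    out["flag"] = np.where(merged["value_count"] == 0, "zero_denominator", "")
    return out


def mad_outlier_mask(values: Sequence[float], k: float = 5.0) -> np.ndarray:
    """Median +/- k*MAD outlier rule (documented substitute for proprietary
    outlier detection; off by default in all pipelines)."""
    arr = np.asarray(values, dtype=float)
    med = np.median(arr)
    mad = np.median(np.abs(arr - med))
    if mad == 0:
        return np.zeros(arr.size, dtype=bool)
    return np.abs(arr - med) > k * mad
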