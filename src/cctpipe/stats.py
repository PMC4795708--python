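"""Cohort-level statistics: inter-reader agreement, correlation, group
comparison and ROC-based diagnostic evaluation.

The layer mirrors a two-observer clinical study: ICC(2,1) (two-way random
effects, absolute agreement, single measure) for reader agreement, Pearson
correlation between indices and against the Glasgow Coma Scale, pooled
Student's t for group means, chi-square for categorical tables, and an
empirical ROC with the Youden-optimal cutoff, Hanley–McNeil confidence
interval and a normal-approximation test of AUC against 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import (
    ALL_INDEXES, CT_INDEXES, XA_INDEXES, GROUP_CONTROL, GROUP_VASOSPASM,
)

DEFAULT_ALPHA = 0.05

FLAG_DEGENERATE = "degenerate"

#: scatter panels relating CT-based to DSA-based circulation times
CT_XA_PAIRS = (
    ("CT-CCT_A2", "XA-CCT_RA2"),
    ("CT-CCT_A2", "XA-CCT_LA2"),
    ("CT-CCT_RM2", "XA-CCT_RM2"),
    ("CT-CCT_LM2", "XA-CCT_LM2"),
)

PERFUSION_VARS = ("cbv", "cbf", "mtt", "ttp")
#: reduced CBV/CBF indicate vasospasm, so their ROC direction is "less"
ROC_DIRECTION = {"cbv": "less", "cbf": "less"}


class SingleClassError(ValueError):
    """Raised when an ROC is requested for a single-class cohort."""


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model_descriptor: str
    n_subjects: int
    flags: set = field(default_factory=set)


def icc_two_reader(values_a: Sequence[float], values_b: Sequence[float],
                   alpha: float = DEFAULT_ALPHA) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares with the standard F-based
    confidence interval (McGraw & Wong); identical readers are a degenerate
    case reported as ICC = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D score vectors required")
    n = len(a)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("scores must be finite")
    if np.array_equal(a, b):
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0,
                         model_descriptor="ICC(2,1) absolute agreement",
                         n_subjects=n, flags={FLAG_DEGENERATE})

    k = 2
    x = np.column_stack([a, b])
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = ss_total - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0,
                         model_descriptor="ICC(2,1) absolute agreement",
                         n_subjects=n, flags={FLAG_DEGENERATE})
    icc = (msr - mse) / denom

    # Satterthwaite df for the absolute-agreement interval
    fj = msc / mse if mse > 0 else np.inf
    a_ = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b_ = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(fj) or not np.isfinite(a_):
        ci_low, ci_high = icc, icc
    else:
        v = (a_ * fj + b_) ** 2 / (
            (a_ * fj) ** 2 / (k - 1) + b_ ** 2 / ((n - 1) * (k - 1)))
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        ci_high = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(icc=float(icc), ci_low=float(ci_low),
                     ci_high=float(ci_high),
                     model_descriptor="ICC(2,1) absolute agreement",
                     n_subjects=n)


# ---------------------------------------------------------------------------
# correlation and group comparison


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Product-moment correlation: returns (r, r_squared, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r * r), float(p)


@dataclass
class GroupComparison:
    variable: str
    mean_control: float
    sd_control: float
    mean_vasospasm: float
    sd_vasospasm: float
    t_statistic: float
    p_value: float
    test_descriptor: str


def two_group_t(x: Sequence[float], y: Sequence[float],
                variant: str = "pooled", variable: str = "") -> GroupComparison:
    """Two-sided two-sample t-test; pooled-variance Student's t by default,
    Welch's unequal-variance variant on request."""
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return GroupComparison(
        variable=variable,
        mean_control=float(x.mean()), sd_control=float(x.std(ddof=1)),
        mean_vasospasm=float(y.mean()), sd_vasospasm=float(y.std(ddof=1)),
        t_statistic=float(t), p_value=float(p),
        test_descriptor=f"{variant} t, two-sided")


def chi_square_table(counts) -> Tuple[float, float]:
    """Pearson chi-square without continuity correction on an r x c table."""
    counts = np.asarray(counts)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has an all-zero row or column")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC analysis


@dataclass
class ROCResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    p_value: float
    direction: str = "greater"
    n_positive: int = 0
    n_negative: int = 0
    flags: set = field(default_factory=set)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(scores: Sequence[float], labels: Sequence[str],
                 positive_label: str = GROUP_VASOSPASM,
                 direction: str = "greater",
                 alpha: float = DEFAULT_ALPHA) -> ROCResult:
    """Empirical ROC with Youden-optimal cutoff.

    The AUC is the trapezoidal area under the empirical curve, computed in
    integer count arithmetic so it equals the Mann–Whitney statistic
    U/(n1*n0) with ties counted 1/2.  The optimal cutoff maximizes Youden's
    J = sensitivity + specificity - 1 over all achievable thresholds, with
    ties broken toward higher sensitivity, and is reported as the midpoint
    between the adjacent distinct scores.  The confidence interval uses the
    Hanley–McNeil standard error; the p-value tests AUC = 0.5 by normal
    approximation.

    ``direction="greater"`` (default) treats higher scores as evidence for
    the positive class; ``"less"`` treats lower scores that way (CBV/CBF
    fall in vasospasm), with the cutoff reported on the original scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be paired 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")
    y = labels == positive_label
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("both classes must be present for ROC")

    flags: set = set()
    s = scores if direction == "greater" else -scores

    # cumulative TP/FP walking thresholds down through the distinct scores
    distinct = np.unique(s)[::-1]
    tp = np.array([(y & (s >= u)).sum() for u in distinct], dtype=int)
    fp = np.array([(~y & (s >= u)).sum() for u in distinct], dtype=int)

    # trapezoid in integer counts: exact Mann-Whitney equivalence incl. ties
    tp_pad = np.concatenate([[0], tp])
    fp_pad = np.concatenate([[0], fp])
    auc2 = int(np.sum((fp_pad[1:] - fp_pad[:-1]) * (tp_pad[1:] + tp_pad[:-1])))
    auc = auc2 / (2 * n_pos * n_neg)

    if len(distinct) == 1:
        flags.add(FLAG_DEGENERATE)

    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j == best_j)
    best = candidates[np.argmax(sens[candidates])]   # tie -> higher sensitivity
    # the rule is "positive iff score >= distinct[best]"; report the midpoint
    # between that score and the next lower one (below the minimum nothing
    # is excluded, so the minimum itself is the cutoff)
    if best == len(distinct) - 1:
        cutoff_internal = float(distinct[best])
    else:
        cutoff_internal = float(0.5 * (distinct[best] + distinct[best + 1]))
    cutoff = cutoff_internal if direction == "greater" else -cutoff_internal

    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    z = sps.norm.ppf(1 - alpha / 2)
    ci_low = float(np.clip(auc - z * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + z * se, 0.0, 1.0))
    if se > 0:
        p = float(2 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return ROCResult(auc=float(auc), auc_ci_low=ci_low, auc_ci_high=ci_high,
                     optimal_cutoff=float(cutoff),
                     sensitivity=float(sens[best]),
                     specificity=float(spec[best]), p_value=p,
                     direction=direction, n_positive=n_pos, n_negative=n_neg,
                     flags=flags)


# ---------------------------------------------------------------------------
# cohort report


def _roc_entry(df: pd.DataFrame, column: str, alpha: float) -> dict:
    direction = ROC_DIRECTION.get(column, "greater")
    try:
        r = roc_analysis(df[column].to_numpy(), df["group"].to_numpy(),
                         direction=direction, alpha=alpha)
    except (SingleClassError, ValueError) as exc:
        return {"error": str(exc)}
    return {"auc": r.auc, "auc_ci_low": r.auc_ci_low,
            "auc_ci_high": r.auc_ci_high, "optimal_cutoff": r.optimal_cutoff,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "p_value": r.p_value, "direction": r.direction,
            "flags": sorted(r.flags)}


def build_report(cohort: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                 t_variant: str = "pooled") -> dict:
    """Full statistical report for a cohort table.

    Expects one row per subject with columns ``subject_id``, ``group``,
    ``gcs``, ``fisher_grade``, one column per circulation-time index (reader
    average), optional ``<index>_reader_a`` / ``<index>_reader_b`` columns,
    and the perfusion parameters ``cbv``/``cbf``/``mtt``/``ttp``.  Output is
    a plain nested dict (JSON-serializable, deterministic key order for a
    deterministic input table).
    """
    report: dict = {"alpha": alpha,
                    "n_subjects": int(len(cohort)),
                    "n_control": int((cohort["group"] == GROUP_CONTROL).sum()),
                    "n_vasospasm": int((cohort["group"] == GROUP_VASOSPASM).sum())}

    # inter-reader agreement
    icc_section = {}
    for name in ALL_INDEXES:
        ca, cb = f"{name}_reader_a", f"{name}_reader_b"
        if ca in cohort.columns and cb in cohort.columns:
            res = icc_two_reader(cohort[ca].to_numpy(),
                                 cohort[cb].to_numpy(), alpha=alpha)
            icc_section[name] = {"icc": res.icc, "ci_low": res.ci_low,
                                 "ci_high": res.ci_high,
                                 "model": res.model_descriptor,
                                 "n_subjects": res.n_subjects,
                                 "flags": sorted(res.flags)}
    report["icc"] = icc_section

    # correlations: CT-CCT vs XA-CCT panels and every CCT vs GCS
    corr: dict = {"ct_vs_xa": {}, "cct_vs_gcs": {}}
    for ct_name, xa_name in CT_XA_PAIRS:
        if ct_name in cohort.columns and xa_name in cohort.columns:
            r, r2, p = pearson_r(cohort[xa_name], cohort[ct_name])
            corr["ct_vs_xa"][f"{ct_name} vs {xa_name}"] = {
                "r": r, "r_squared": r2, "p_value": p}
    if "gcs" in cohort.columns:
        for name in ALL_INDEXES:
            if name in cohort.columns:
                r, r2, p = pearson_r(cohort[name], cohort["gcs"])
                corr["cct_vs_gcs"][name] = {"r": r, "r_squared": r2,
                                            "p_value": p}
    report["correlations"] = corr

    # group comparisons
    ctrl = cohort[cohort["group"] == GROUP_CONTROL]
    vaso = cohort[cohort["group"] == GROUP_VASOSPASM]
    comparisons = {}
    two_groups = len(ctrl) >= 2 and len(vaso) >= 2
    for name in list(ALL_INDEXES) + list(PERFUSION_VARS) + ["gcs"]:
        if name not in cohort.columns:
            continue
        if not two_groups:
            comparisons[name] = {"error": "both groups need n >= 2"}
            continue
        gc = two_group_t(ctrl[name], vaso[name], variant=t_variant,
                         variable=name)
        comparisons[name] = {
            "mean_control": gc.mean_control, "sd_control": gc.sd_control,
            "mean_vasospasm": gc.mean_vasospasm,
            "sd_vasospasm": gc.sd_vasospasm,
            "t_statistic": gc.t_statistic, "p_value": gc.p_value,
            "test": gc.test_descriptor}
    report["group_comparison"] = comparisons

    # Fisher-grade distribution (categorical)
    if "fisher_grade" in cohort.columns and two_groups:
        table = pd.crosstab(cohort["group"], cohort["fisher_grade"])
        table = table.loc[:, table.sum(axis=0) > 0]
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            stat, p = chi_square_table(table.to_numpy())
            report["fisher_grade_chi_square"] = {
                "statistic": stat, "p_value": p,
                "grades": list(map(str, table.columns))}

    # ROC for every circulation-time index and perfusion comparator
    roc_section = {}
    for name in list(ALL_INDEXES) + list(PERFUSION_VARS):
        if name in cohort.columns:
            roc_section[name] = _roc_entry(cohort, name, alpha)
    report["roc"] = roc_section
    return report
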