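"""Screening-performance evaluation: ROC, likelihood ratios, LOO scoring.

First-trimester PP13 MoMs are *low* in pregnancies that later develop
preeclampsia or IUGR, so the first-trimester screen flags low scores as
positive; in the second and third trimesters disease MoMs are elevated and
the direction flips. Leave-one-out scoring refits every fitted component
(median curve, covariate model, blood-group factors) with the scored
subject excluded, to avoid over-fitting bias in the reported accuracy.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .config import PipelineConfig
from . import mom as mom_engine

logger = logging.getLogger(__name__)


@dataclass
class ROCCurve:
    """Operating points of a screening test.

    `direction` is "low" when a low score is screen-positive (first
    trimester) and "high" otherwise. Thresholds are on the original score
    scale; FPR/TPR are nondecreasing along the curve and include the (0,0)
    and (1,1) endpoints.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    direction: str
    n_cases: int
    n_controls: int


@dataclass
class ScreeningPerformance:
    """AUC plus fixed-FPR operating characteristics of one evaluation."""

    auc: float
    n_cases: int
    n_controls: int
    at_fpr: dict[float, dict[str, float]] = field(default_factory=dict)


@dataclass
class GroupComparison:
    labels: tuple
    test: str
    statistic: float
    p_value: float


def roc_curve(scores, labels, direction: str = "low") -> ROCCurve:
    """Build the ROC curve, collapsing tied scores into single steps.

    `labels` is boolean (True = case). `direction="low"` means lower scores
    are more disease-like.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_cases = int(labels.sum())
    n_controls = int((~labels).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("ROC requires at least one case and one control")
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    s = -scores if direction == "low" else scores
    fpr, tpr, thr = _sk_roc_curve(labels, s, drop_intermediate=False)
    thresholds = -thr if direction == "low" else thr
    return ROCCurve(
        thresholds=thresholds, tpr=tpr, fpr=fpr,
        direction=direction, n_cases=n_cases, n_controls=n_controls,
    )


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve (ties earn half credit, so this
    equals the pairwise probability that a random case scores more
    disease-like than a random control)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def sensitivity_at_fpr(curve: ROCCurve, fpr_target: float) -> float:
    """Highest sensitivity (percent) among operating points with a false
    positive rate at most `fpr_target` (percent); conservative step
    convention, no interpolation."""
    target = fpr_target / 100.0
    ok = curve.fpr <= target + 1e-12
    return float(curve.tpr[ok].max() * 100.0)


def realized_fpr_at(curve: ROCCurve, fpr_target: float) -> float:
    """FPR (percent) actually attained at the chosen operating point."""
    target = fpr_target / 100.0
    ok = curve.fpr <= target + 1e-12
    best = curve.tpr[ok].max()
    return float(curve.fpr[ok][curve.tpr[ok] == best].max() * 100.0)


def likelihood_ratios(
    sensitivity: float, fpr: float, reporting: bool = False
) -> tuple[float, float, float]:
    """(LR+, LR-, overall LR) from a sensitivity / FPR pair in percent.

    LR+ = sens / (1 - spec), LR- = (1 - sens) / spec, overall = LR+ / LR-.
    With `reporting=True`, LR+ and LR- are rounded to two decimals before
    forming their ratio, mirroring how screening tables are printed.
    """
    if not (0 <= sensitivity <= 100):
        raise ValueError("sensitivity must be in [0, 100] percent")
    if not (0 <= fpr < 100):
        raise ValueError("FPR must be in [0, 100) percent")
    if fpr == 0:
        if sensitivity > 0:
            logger.warning("FPR = 0 with positive sensitivity: LR+ is infinite")
            lr_pos = math.inf
        else:
            lr_pos = 0.0
    else:
        lr_pos = sensitivity / fpr
    lr_neg = (100.0 - sensitivity) / (100.0 - fpr)
    if reporting:
        lr_pos = round(lr_pos, 2)
        lr_neg = round(lr_neg, 2)
    if lr_neg == 0:
        overall = math.inf if lr_pos > 0 else 0.0
    else:
        overall = lr_pos / lr_neg
    return lr_pos, lr_neg, overall


def evaluate_performance(
    scores, labels, direction: str = "low", fpr_targets=(15.0, 20.0)
) -> ScreeningPerformance:
    """AUC, sensitivity, realized FPR and likelihood ratios at fixed FPRs."""
    curve = roc_curve(scores, labels, direction)
    perf = ScreeningPerformance(
        auc=auc(curve), n_cases=curve.n_cases, n_controls=curve.n_controls
    )
    for target in fpr_targets:
        sens = sensitivity_at_fpr(curve, target)
        realized = realized_fpr_at(curve, target)
        lr_pos, lr_neg, overall = likelihood_ratios(sens, target)
        perf.at_fpr[float(target)] = {
            "sensitivity": sens,
            "realized_fpr": realized,
            "positive_lr": lr_pos,
            "negative_lr": lr_neg,
            "overall_lr": overall,
        }
    return perf


# ---------------------------------------------------------------------------
# scoring pipelines

def _fit_and_score(
    subjects: pd.DataFrame,
    samples: pd.DataFrame,
    config: PipelineConfig,
    fit_subject_mask: np.ndarray | None = None,
    fallback: str = "error",
) -> pd.DataFrame:
    """Fit median curve + adjustments on (masked) unaffected subjects and
    apply them to every sample. Returns the fully adjusted MoM table."""
    merged = samples.merge(subjects, on="subject_id", how="left", validate="m:1")
    unaffected = merged["outcome"] == "unaffected"
    in_fit = unaffected.to_numpy()
    if fit_subject_mask is not None:
        keep = merged["subject_id"].isin(
            subjects.loc[fit_subject_mask, "subject_id"]
        ).to_numpy()
        in_fit = in_fit & keep
    if not in_fit.any():
        raise mom_engine.FittingError("no unaffected samples available for fitting")

    curve = mom_engine.fit_median_curve(
        merged.loc[in_fit], min_bin_count=config.min_bin_count
    )
    moms = mom_engine.to_mom(merged, curve, fallback=fallback)
    model = mom_engine.fit_covariate_adjustment(
        moms.loc[in_fit], moms.loc[in_fit],
        order=config.covariate_order, joint=config.joint_covariates,
    )
    moms = mom_engine.apply_covariate_adjustment(moms, moms, model)
    factors = mom_engine.fit_blood_group_factors(
        moms.loc[in_fit],
        per_trimester=config.per_trimester_factors,
        min_count=config.min_group_count,
    )
    return mom_engine.adjust_for_blood_group(moms, factors)


def score_cohort(
    subjects: pd.DataFrame, samples: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """In-sample pipeline: MoM conversion, covariate and ABO adjustment."""
    config = config or PipelineConfig()
    return _fit_and_score(subjects, samples, config)


def first_trimester_scores(moms: pd.DataFrame, column: str = "mom_abo_adj") -> pd.Series:
    """Per-subject first-trimester score (geometric mean when a subject has
    several first-window samples; the study design yields exactly one)."""
    t1 = moms[moms["trimester"] == 1]
    return np.exp(np.log(t1.set_index("subject_id")[column]).groupby(level=0).mean())


def loo_scores(
    subjects: pd.DataFrame, samples: pd.DataFrame, config: PipelineConfig | None = None,
    column: str = "mom_abo_adj",
) -> pd.Series:
    """Out-of-sample first-trimester adjusted MoM per subject.

    For each subject all fitted components (median curve, covariate model,
    blood-group factors) are refitted with that subject excluded, then
    applied to her samples. Excluding an affected subject leaves the
    fitting set unchanged, so only unaffected subjects require a refit.
    """
    config = config or PipelineConfig()
    n = len(subjects)
    scores: dict[str, float] = {}
    base = None
    for i in range(n):
        sid = subjects["subject_id"].iloc[i]
        if subjects["outcome"].iloc[i] != "unaffected":
            if base is None:
                base = _fit_and_score(subjects, samples, config, fallback="nearest")
            sub = base[base["subject_id"] == sid]
        else:
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            adjusted = _fit_and_score(
                subjects, samples, config, fit_subject_mask=mask, fallback="nearest"
            )
            sub = adjusted[adjusted["subject_id"] == sid]
        t1 = sub[sub["trimester"] == 1]
        if len(t1):
            scores[sid] = float(np.exp(np.log(t1[column]).mean()))
    return pd.Series(scores, name=column)


# ---------------------------------------------------------------------------
# statistical comparisons

def _sensitivity_from_scores(cases, controls, fpr_target, direction="low") -> float:
    """Sensitivity (percent) at FPR <= target, directly from score vectors.

    The positivity cutoff sits just above the (k+1)-th most positive-like
    control, k = floor(target * n_controls), which is the highest-TPR
    operating point whose FPR never exceeds the budget (ties with the
    cutoff control count as negative). Matches `sensitivity_at_fpr` on the
    full ROC curve.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    s_cases = -cases if direction == "low" else cases
    s_controls = -controls if direction == "low" else controls
    n = len(s_controls)
    allowed = int(np.floor(fpr_target / 100.0 * n + 1e-9))
    if allowed >= n:
        return 100.0
    cutoff = np.partition(s_controls, n - 1 - allowed)[n - 1 - allowed]
    return float((s_cases > cutoff).mean() * 100.0)


def compare_sensitivities(
    scores_a, scores_b, labels, fpr_target: float,
    n_boot: int = 2000, seed: int | None = None, direction: str = "low",
) -> float:
    """Two-sided paired-bootstrap p-value for a sensitivity difference.

    `scores_a` and `scores_b` are paired per subject (e.g. before and after
    ABO adjustment); subjects are resampled stratified by case status and
    the sensitivity at the fixed FPR recomputed on each resample.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable bootstrap p-value")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(labels)
    ctrl_idx = np.flatnonzero(~labels)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.choice(case_idx, len(case_idx))
        ki = rng.choice(ctrl_idx, len(ctrl_idx))
        sa = _sensitivity_from_scores(scores_a[ci], scores_a[ki], fpr_target, direction)
        sb = _sensitivity_from_scores(scores_b[ci], scores_b[ki], fpr_target, direction)
        diffs[b] = sb - sa
    p_low = (diffs <= 0).mean()
    p_high = (diffs >= 0).mean()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def rank_test(groups, test: str = "wilcoxon_rank_sum") -> GroupComparison:
    """Nonparametric group comparison with tie correction.

    `wilcoxon_rank_sum` and `mann_whitney` are the same two-sample test and
    return identical p-values (asymptotic, tie-corrected, no continuity
    correction, so the two-group Kruskal-Wallis agrees); `kruskal_wallis`
    accepts two or more groups.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("rank_test requires nonempty groups")
    if test in ("wilcoxon_rank_sum", "mann_whitney"):
        if len(arrays) != 2:
            raise ValueError(f"{test} requires exactly two groups")
        res = stats.mannwhitneyu(
            arrays[0], arrays[1], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        if len(arrays) < 2:
            raise ValueError("kruskal_wallis requires at least two groups")
        res = stats.kruskal(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        labels=tuple(range(len(arrays))), test=test, statistic=stat, p_value=p
    )
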