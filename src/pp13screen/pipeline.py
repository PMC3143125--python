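"""End-to-end pipeline: simulate -> MoM fit -> screening evaluation -> report.

The report mirrors the layout of the screening study's summary tables:
median MoM with binomial order-statistic 95% CIs per study group and
trimester (before and after ABO adjustment), and sensitivity / likelihood
ratios per disease group at the fixed false-positive rates.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import mom as mom_engine
from . import screening
from .config import CohortConfig, PipelineConfig, TRIMESTERS
from .io import RunManifest, file_checksum, read_cohort, write_cohort
from .simulate import generate_cohort

logger = logging.getLogger(__name__)

#: evaluation groups -> generator outcome classes (PE includes PE with IUGR,
#: matching how the study counts its 20 preeclampsia cases)
DISEASE_GROUPS = {
    "IUGR": ("IUGR",),
    "PE": ("PE", "PE_IUGR"),
    "PE_IUGR": ("PE_IUGR",),
    "any_complication": ("IUGR", "PE", "PE_IUGR"),
}


def median_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Median with a distribution-free binomial order-statistic CI."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    med = float(np.median(x))
    if n < 3:
        return med, float(x[0]), float(x[-1])
    alpha = 1.0 - level
    lo = int(sps.binom.ppf(alpha / 2, n, 0.5))
    hi = int(sps.binom.ppf(1 - alpha / 2, n, 0.5))
    lo = max(lo, 0)
    hi = min(hi, n - 1)
    return med, float(x[lo]), float(x[hi])


def mom_summary_table(moms: pd.DataFrame) -> pd.DataFrame:
    """Per study-group, per-trimester median MoM with 95% CI, before and
    after ABO adjustment (layout of the study's cohort summary table)."""
    rows = []
    for group in ("unaffected", "IUGR", "PE", "PE_IUGR"):
        sub = moms[moms["outcome"] == group]
        for t in TRIMESTERS:
            tri = sub[sub["trimester"] == t]
            if len(tri) == 0:
                continue
            for col, label in (("mom", "mom"), ("mom_abo_adj", "mom_abo_adj")):
                med, lo, hi = median_ci(tri[col].to_numpy())
                rows.append(
                    {
                        "study_group": group,
                        "trimester": t,
                        "quantity": label,
                        "median": med,
                        "ci_low": lo,
                        "ci_high": hi,
                        "n": len(tri),
                    }
                )
    return pd.DataFrame(rows)


def performance_table(
    subjects: pd.DataFrame,
    moms: pd.DataFrame,
    config: PipelineConfig,
    loo_series: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Sensitivity, LRs and AUC per disease group, adjustment state and FPR.

    First-trimester evaluation, low adjusted MoM = screen positive. When
    `loo_series` maps score columns to leave-one-out per-subject scores,
    those are used instead of the in-sample scores.
    """
    outcome = subjects.set_index("subject_id")["outcome"]
    rows = []
    for column, state in (("mom_cov_adj", "before_abo"), ("mom_abo_adj", "after_abo")):
        if loo_series is not None and column in loo_series:
            scores = loo_series[column]
        else:
            scores = screening.first_trimester_scores(moms, column)
        labels_all = outcome.loc[scores.index]
        for disease, classes in DISEASE_GROUPS.items():
            keep = labels_all.isin(classes + ("unaffected",))
            s = scores[keep]
            y = labels_all[keep].isin(classes).to_numpy()
            if y.sum() == 0 or (~y).sum() == 0:
                logger.warning("skipping %s/%s: single-class data", disease, state)
                continue
            perf = screening.evaluate_performance(
                s.to_numpy(), y, direction="low", fpr_targets=config.fpr_targets
            )
            for fpr, metrics in perf.at_fpr.items():
                rows.append(
                    {
                        "disease": disease,
                        "adjustment": state,
                        "fpr_target": fpr,
                        "n_cases": perf.n_cases,
                        "n_controls": perf.n_controls,
                        "auc": perf.auc,
                        **metrics,
                    }
                )
    return pd.DataFrame(rows)


def roc_points_table(subjects: pd.DataFrame, moms: pd.DataFrame) -> pd.DataFrame:
    """Flat table of first-trimester ROC operating points per disease group."""
    outcome = subjects.set_index("subject_id")["outcome"]
    rows = []
    for column, state in (("mom_cov_adj", "before_abo"), ("mom_abo_adj", "after_abo")):
        scores = screening.first_trimester_scores(moms, column)
        labels_all = outcome.loc[scores.index]
        for disease, classes in DISEASE_GROUPS.items():
            keep = labels_all.isin(classes + ("unaffected",))
            y = labels_all[keep].isin(classes).to_numpy()
            if y.sum() == 0 or (~y).sum() == 0:
                continue
            curve = screening.roc_curve(scores[keep].to_numpy(), y, direction="low")
            for thr, tpr, fpr in zip(curve.thresholds, curve.tpr, curve.fpr):
                rows.append(
                    {
                        "disease": disease,
                        "adjustment": state,
                        "threshold": thr,
                        "tpr": tpr,
                        "fpr": fpr,
                    }
                )
    return pd.DataFrame(rows)


def _format_report(summary: pd.DataFrame, performance: pd.DataFrame) -> str:
    lines = ["PP13 MoM screening pipeline report", ""]
    lines.append("Median MoM by study group and trimester (95% CI)")
    lines.append(
        f"{'group':<14}{'trimester':<10}{'quantity':<14}{'median':>8}"
        f"{'ci_low':>8}{'ci_high':>9}{'n':>6}"
    )
    for row in summary.itertuples(index=False):
        lines.append(
            f"{row.study_group:<14}{row.trimester:<10}{row.quantity:<14}"
            f"{row.median:>8.2f}{row.ci_low:>8.2f}{row.ci_high:>9.2f}{row.n:>6d}"
        )
    lines.append("")
    lines.append("First-trimester screening performance (low MoM = positive)")
    lines.append(
        f"{'disease':<18}{'state':<12}{'FPR%':>6}{'sens%':>7}{'LR+':>7}"
        f"{'LR-':>7}{'LR':>8}{'AUC':>7}"
    )
    for row in performance.itertuples(index=False):
        lr_pos, lr_neg, overall = screening.likelihood_ratios(
            row.sensitivity, row.fpr_target, reporting=True
        )
        lines.append(
            f"{row.disease:<18}{row.adjustment:<12}{row.fpr_target:>6.0f}"
            f"{row.sensitivity:>7.1f}{lr_pos:>7.2f}{lr_neg:>7.2f}"
            f"{overall:>8.1f}{row.auc:>7.3f}"
        )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    out_dir: str | Path,
    cohort_config: CohortConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    subjects_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> dict:
    """Run simulate -> fit -> evaluate -> report into `out_dir`.

    Either an existing cohort (subjects/samples CSV paths) or a cohort
    configuration to simulate from must be provided. Returns the in-memory
    results; all tables, the report and the manifest are written to disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pipeline_config = pipeline_config or PipelineConfig()
    manifest = RunManifest(
        seed=cohort_config.seed if cohort_config else None,
        config={
            "cohort": asdict(cohort_config) if cohort_config else None,
            "pipeline": asdict(pipeline_config),
        },
    )

    if subjects_path is not None and samples_path is not None:
        subjects, samples = read_cohort(subjects_path, samples_path)
        manifest.input_checksums = {
            "subjects": file_checksum(subjects_path),
            "samples": file_checksum(samples_path),
        }
    else:
        if cohort_config is None:
            raise ValueError("need either a cohort config or cohort file paths")
        subjects, samples = generate_cohort(cohort_config)
        sub_path, samp_path = write_cohort(subjects, samples, out)
        manifest.input_checksums = {
            "subjects": file_checksum(sub_path),
            "samples": file_checksum(samp_path),
        }
    manifest.add_stage("cohort", subjects=len(subjects), samples=len(samples))

    moms = screening.score_cohort(subjects, samples, pipeline_config)
    moms_out = moms[
        [
            "subject_id", "ga_week", "trimester", "concentration_pg_ml",
            "blood_group", "outcome", "mom", "mom_cov_adj", "mom_abo_adj",
        ]
    ]
    moms_out.to_csv(out / "moms.csv", index=False)
    manifest.add_stage("mom", records=len(moms_out))
    if len(moms_out) != len(samples):
        raise RuntimeError("record count changed across MoM stages")

    loo_series = None
    if pipeline_config.loo:
        loo_series = {
            col: screening.loo_scores(subjects, samples, pipeline_config, col)
            for col in ("mom_cov_adj", "mom_abo_adj")
        }

    summary = mom_summary_table(moms)
    performance = performance_table(subjects, moms, pipeline_config, loo_series)
    roc_points = roc_points_table(subjects, moms)
    summary.to_csv(out / "mom_summary.csv", index=False)
    performance.to_csv(out / "performance.csv", index=False)
    roc_points.to_csv(out / "roc_points.csv", index=False)
    manifest.add_stage("evaluate", performance_rows=len(performance))

    report = _format_report(summary, performance)
    (out / "report.txt").write_text(report, encoding="utf-8")
    manifest.write(out)
    return {
        "subjects": subjects,
        "samples": samples,
        "moms": moms,
        "summary": summary,
        "performance": performance,
        "report": report,
    }
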