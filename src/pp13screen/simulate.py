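"""Synthetic cohort and erythrocyte-binding-panel generators.

The cohort generator produces subject and sample tables with the statistical
structure the downstream MoM / adjustment / screening analysis assumes:
log-normal serum concentrations rising with gestation, multiplicative ABO
blood-group and disease effects, covariate effects on the log scale, and
per-subject dropout of the later visits. Every subject draws from her own
deterministic random stream spawned from the global seed, so cohorts are
fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    BLOOD_GROUPS,
    OUTCOMES,
    SAMPLING_WINDOWS,
    BindingConfig,
    CohortConfig,
)

SUBJECT_COLUMNS = [
    "subject_id", "blood_group", "rh", "outcome",
    "bmi", "age", "smoking", "parity", "ethnicity",
]
SAMPLE_COLUMNS = ["subject_id", "ga_week", "concentration_pg_ml"]

ETHNICITIES = ("general", "minority")


def trimester_of_week(week: int) -> int:
    """Map a gestational week to its sampling-window trimester (6-10 -> 1,
    16-20 -> 2, 24-28 -> 3)."""
    for visit, (lo, hi) in SAMPLING_WINDOWS.items():
        if lo <= week <= hi:
            return visit
    raise ValueError(f"gestational week {week} lies outside all sampling windows")


def baseline_median(week, config: CohortConfig):
    """Baseline (unaffected) median concentration at a gestational week.

    Piecewise-linear through the window-midweek anchors, linearly
    extrapolated with the end-segment slope outside the anchor range.
    """
    xs = np.asarray(config.window_midweeks, dtype=float)
    ys = np.asarray(config.baseline_medians, dtype=float)
    w = np.asarray(week, dtype=float)
    out = np.interp(w, xs, ys)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    out = np.where(w < xs[0], ys[0] + (w - xs[0]) * lo_slope, out)
    out = np.where(w > xs[-1], ys[-1] + (w - xs[-1]) * hi_slope, out)
    return out if out.ndim else float(out)


def _covariate_log_effect(config: CohortConfig, bmi, age, smoking, parity, ethnicity):
    eff = config.covariate_effects
    total = 0.0
    total += eff.get("bmi", 0.0) * (bmi - config.covariate_params["bmi_mean"])
    total += eff.get("age", 0.0) * (age - config.covariate_params["age_mean"])
    total += eff.get("smoking", 0.0) * float(smoking)
    total += eff.get("parity", 0.0) * parity
    total += eff.get("ethnicity", 0.0) * float(ethnicity == "minority")
    return total


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (subjects, samples) tables for one synthetic cohort.

    Every subject contributes a first-window sample; the second and third
    visits are each kept independently with probability 1 - dropout_prob.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_subjects)

    bg_probs = [config.blood_group_freqs[g] for g in BLOOD_GROUPS]
    out_probs = [config.outcome_prevalence[o] for o in OUTCOMES]
    cp = config.covariate_params

    subjects = []
    samples = []
    for i, child in enumerate(streams):
        rng = np.random.default_rng(child)
        group = BLOOD_GROUPS[rng.choice(len(BLOOD_GROUPS), p=bg_probs)]
        outcome = OUTCOMES[rng.choice(len(OUTCOMES), p=out_probs)]
        rh = "-" if rng.random() < config.rh_neg_freq else "+"
        bmi = max(15.0, rng.normal(cp["bmi_mean"], cp["bmi_sd"]))
        age = float(np.clip(rng.normal(cp["age_mean"], cp["age_sd"]), 16.0, 45.0))
        smoking = bool(rng.random() < cp["smoking_freq"])
        parity = int(rng.poisson(cp["parity_mean"]))
        ethnicity = "minority" if rng.random() < cp["minority_freq"] else "general"
        sid = f"S{i:05d}"
        subjects.append((sid, group, rh, outcome, bmi, age, smoking, parity, ethnicity))

        cov_term = _covariate_log_effect(config, bmi, age, smoking, parity, ethnicity)
        for visit in (1, 2, 3):
            if visit > 1 and rng.random() < config.dropout_prob:
                continue
            lo, hi = SAMPLING_WINDOWS[visit]
            week = int(rng.integers(lo, hi + 1))
            log_c = (
                np.log(baseline_median(week, config))
                + np.log(config.group_serum_multipliers[group][visit - 1])
                + np.log(config.disease_mom_multipliers[outcome][visit - 1])
                + cov_term
            )
            if config.log_sd > 0:
                log_c += rng.normal(0.0, config.log_sd)
            samples.append((sid, week, float(np.exp(log_c))))

    subjects_df = pd.DataFrame(subjects, columns=SUBJECT_COLUMNS)
    samples_df = pd.DataFrame(samples, columns=SAMPLE_COLUMNS)
    return subjects_df, samples_df


def generate_binding_panel(
    config: BindingConfig, seed: int, senescent: bool = False
) -> pd.DataFrame:
    """Generate a summarized flow-cytometry binding panel.

    Returns one row per (ligand, blood group, concentration) with the mean
    and SEM of the replicate mean fluorescence intensities, plus trPP13 and
    BSA control rows at the top concentration. `senescent` scales binding by
    the old-RBC factor (senescent cells bind 1.5-2-fold more lectin).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1D]))
    scale = config.senescent_factor if senescent else 1.0
    rows = []
    for group in BLOOD_GROUPS:
        bmax = config.bmax[group] * scale
        k = config.half_sat_ug_ml[group]
        for conc in config.concentrations_ug_ml:
            expected = bmax * conc / (k + conc)
            reps = expected * rng.lognormal(0.0, config.noise_cv, config.n_replicates)
            rows.append((group, conc, float(reps.mean()),
                         float(reps.std(ddof=1) / np.sqrt(len(reps))), "PP13"))
    top = max(config.concentrations_ug_ml)
    for ligand in ("trPP13", "BSA"):
        reps = config.control_mfi * rng.lognormal(0.0, config.noise_cv, config.n_replicates)
        rows.append(("all", top, float(reps.mean()),
                     float(reps.std(ddof=1) / np.sqrt(len(reps))), ligand))
    return pd.DataFrame(
        rows, columns=["blood_group", "conc_ug_ml", "mean_mfi", "sem_mfi", "ligand"]
    )
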