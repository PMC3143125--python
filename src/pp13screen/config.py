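"""Configuration objects for cohort simulation and the analysis pipeline.

Defaults encode the statistical structure of the screening study the package
emulates: three sampling windows (6-10, 16-20, 24-28 weeks of gestation),
log-normally distributed serum PP13 rising with gestation, ABO blood-group
serum multipliers (group B highest throughout pregnancy, group AB lowest in
the first trimester), and trimester-specific disease effects for IUGR,
preeclampsia, and preeclampsia complicated by IUGR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

BLOOD_GROUPS = ("O", "A", "B", "AB")
OUTCOMES = ("unaffected", "IUGR", "PE", "PE_IUGR")
TRIMESTERS = (1, 2, 3)

#: sampling windows in gestational weeks, keyed by trimester visit
SAMPLING_WINDOWS: dict[int, tuple[int, int]] = {1: (6, 10), 2: (16, 20), 3: (24, 28)}

#: first-trimester median serum PP13 MoM by maternal ABO group in the
#: cross-sectional Hispanic cohort; used as default group multipliers.
HISPANIC_T1_MOM = {"O": 0.94, "A": 1.01, "B": 1.57, "AB": 0.58}

#: first-trimester median serum PP13 concentration (pg/ml) by ABO group in
#: the Hispanic cohort; handy as a reference serum profile.
HISPANIC_T1_CONC = {"O": 89.0, "A": 114.0, "B": 183.0, "AB": 60.0}


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_prob_map(name: str, mapping: Mapping[str, float], keys: Sequence[str]) -> None:
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise ConfigurationError(f"{name} is missing entries for {missing}")
    total = sum(mapping[k] for k in keys)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")
    if any(mapping[k] < 0 for k in keys):
        raise ConfigurationError(f"{name} has negative entries")


@dataclass
class CohortConfig:
    """Parameters of the synthetic longitudinal cohort generator.

    The log-concentration of a sample taken at gestational week *w* from a
    subject with blood group *g* and outcome *o* in trimester *t* is

        log C = log(baseline median at w) + log(group multiplier[g][t])
                + log(disease multiplier[o][t]) + covariate terms
                + Normal(0, log_sd)

    so all effects are multiplicative on the concentration scale.
    """

    n_subjects: int = 1078
    blood_group_freqs: dict[str, float] = field(
        default_factory=lambda: {"O": 0.47, "A": 0.29, "B": 0.17, "AB": 0.07}
    )
    rh_neg_freq: float = 0.10
    # study group sizes 1006 / 52 / 20 (of which 5 with IUGR) out of 1078
    outcome_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "unaffected": 1006 / 1078,
            "IUGR": 52 / 1078,
            "PE": 15 / 1078,
            "PE_IUGR": 5 / 1078,
        }
    )
    window_midweeks: tuple[int, int, int] = (8, 18, 26)
    baseline_medians: tuple[float, float, float] = (119.0, 121.0, 212.0)
    # per-trimester serum multipliers by ABO group; trimester 1 takes the
    # Hispanic-cohort MoM ratios, later trimesters converge AB toward A/O
    # while B stays highest (the published curves are graphical only, so
    # trimester 2/3 values are approximate interpolations).
    group_serum_multipliers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "O": (0.94, 0.97, 1.00),
            "A": (1.01, 1.00, 1.00),
            "B": (1.57, 1.35, 1.25),
            "AB": (0.58, 0.85, 1.00),
        }
    )
    # trimester-specific disease effects on the MoM scale
    disease_mom_multipliers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "unaffected": (1.0, 1.0, 1.0),
            "IUGR": (0.37, 1.38, 1.22),
            "PE": (0.27, 1.71, 1.82),
            "PE_IUGR": (0.25, 1.91, 1.62),
        }
    )
    log_sd: float = 0.8
    covariate_params: dict[str, float] = field(
        default_factory=lambda: {
            "bmi_mean": 24.0,
            "bmi_sd": 4.0,
            "age_mean": 29.0,
            "age_sd": 5.0,
            "smoking_freq": 0.15,
            "parity_mean": 1.0,
            "minority_freq": 0.15,
        }
    )
    # log-scale coefficients linking covariates to concentration; only a
    # small BMI effect by default (the study reports BMI as the strongest
    # non-GA covariate but publishes no coefficient).
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.005}
    )
    dropout_prob: float = 0.10
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        _check_prob_map("blood_group_freqs", self.blood_group_freqs, BLOOD_GROUPS)
        _check_prob_map("outcome_prevalence", self.outcome_prevalence, OUTCOMES)
        if not 0 <= self.rh_neg_freq <= 1:
            raise ConfigurationError("rh_neg_freq must be a probability")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigurationError("dropout_prob must be a probability")
        if self.log_sd < 0:
            raise ConfigurationError("log_sd must be >= 0")
        if list(self.window_midweeks) != sorted(set(self.window_midweeks)):
            raise ConfigurationError("window_midweeks must be strictly increasing")
        for g in BLOOD_GROUPS:
            if any(m <= 0 for m in self.group_serum_multipliers[g]):
                raise ConfigurationError(f"group_serum_multipliers[{g}] must be > 0")
        for o in OUTCOMES:
            if any(m <= 0 for m in self.disease_mom_multipliers[o]):
                raise ConfigurationError(f"disease_mom_multipliers[{o}] must be > 0")
        if any(m <= 0 for m in self.baseline_medians):
            raise ConfigurationError("baseline_medians must be > 0")
        return self


@dataclass
class BindingConfig:
    """Parameters of the erythrocyte-binding (flow-cytometry MFI) generator.

    Binding follows a monotone saturating curve MFI = bmax * c / (half_sat + c)
    per blood group; the default bmax ordering AB > A ~ O > B mirrors the
    observed affinity ordering, which is inverse to the serum ordering.
    """

    concentrations_ug_ml: tuple[float, ...] = (6.25, 12.5, 25.0, 50.0)
    bmax: dict[str, float] = field(
        default_factory=lambda: {"O": 680.0, "A": 700.0, "B": 420.0, "AB": 1000.0}
    )
    half_sat_ug_ml: dict[str, float] = field(
        default_factory=lambda: {"O": 15.0, "A": 15.0, "B": 20.0, "AB": 10.0}
    )
    control_mfi: float = 60.0  # trPP13 / BSA background level
    noise_cv: float = 0.05
    n_replicates: int = 5
    senescent_factor: float = 1.75  # old vs young RBC binding fold

    def validate(self) -> "BindingConfig":
        for g in BLOOD_GROUPS:
            if self.bmax[g] <= 0 or self.half_sat_ug_ml[g] <= 0:
                raise ConfigurationError(f"binding parameters for {g} must be > 0")
        if self.control_mfi < 0 or self.noise_cv < 0 or self.n_replicates < 1:
            raise ConfigurationError("invalid binding noise/control parameters")
        return self


@dataclass
class PipelineConfig:
    """Knobs of the MoM / adjustment / evaluation pipeline."""

    covariate_order: tuple[str, ...] = ("bmi", "ethnicity", "smoking", "age", "parity")
    joint_covariates: bool = False
    per_trimester_factors: bool = True
    min_group_count: int = 5
    min_bin_count: int = 1
    fpr_targets: tuple[float, ...] = (15.0, 20.0)
    loo: bool = False


def _flatten(prefix: str, value) -> dict:
    out = {}
    if isinstance(value, dict):
        for k, v in value.items():
            out.update(_flatten(f"{prefix}.{k}" if prefix else str(k), v))
    else:
        out[prefix] = value
    return out


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Read a cohort configuration from a flat or nested YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = CohortConfig()
    nested: dict[str, dict] = {}
    for key, value in raw.items():
        if "." in key:  # flat "map.key: value" form
            head, sub = key.split(".", 1)
            nested.setdefault(head, {})[sub] = value
        elif isinstance(value, dict):
            nested.setdefault(key, {}).update(value)
        else:
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown configuration key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple) and isinstance(value, (list, tuple)):
                value = tuple(value)
            setattr(cfg, key, value)
    for head, sub in nested.items():
        if not hasattr(cfg, head):
            raise ConfigurationError(f"unknown configuration key {head!r}")
        current = dict(getattr(cfg, head))
        for k, v in sub.items():
            current[k] = tuple(v) if isinstance(v, (list, tuple)) else v
        setattr(cfg, head, current)
    return cfg.validate()


def dump_cohort_config(config: CohortConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
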