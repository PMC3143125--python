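"""Gestational-age-specific MoM conversion and sequential adjustment.

A serum concentration is converted to a multiple of the median (MoM) by
dividing by the gestational-week-specific median among unaffected women.
MoMs are then sequentially adjusted, on the log scale, to maternal covariates
(BMI, ethnicity, smoking, maternal age, parity, in that order) and finally to
ABO blood group by dividing by the per-group median adjusted MoM of
unaffected women. Because effects are multiplicative and MoMs right-skewed,
all regression happens on log(MoM); centering every predictor at its
fitting-set mean makes each step a pure re-centering that preserves the
geometric mean of the fitting set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import BLOOD_GROUPS, TRIMESTERS
from .simulate import trimester_of_week

logger = logging.getLogger(__name__)

CATEGORICAL_COVARIATES = {"ethnicity", "smoking"}


class FittingError(ValueError):
    """Raised when a model cannot be fitted from the provided records."""


class CurveLookupError(KeyError):
    """Raised when a gestational week has no fitted median."""


@dataclass
class MedianCurve:
    """Gestational week -> median concentration among unaffected women."""

    medians: dict[int, float]
    counts: dict[int, int]

    @property
    def weeks(self) -> list[int]:
        return sorted(self.medians)

    def __getitem__(self, week: int) -> float:
        try:
            return self.medians[int(week)]
        except KeyError:
            raise CurveLookupError(
                f"no fitted median for gestational week {week}"
            ) from None

    def value(self, week: int, fallback: str = "error") -> float:
        """Median at `week`; with fallback="nearest", fall back to the
        closest fitted week (used when leave-one-out refits empty a bin)."""
        week = int(week)
        if week in self.medians:
            return self.medians[week]
        if fallback == "nearest":
            nearest = min(self.medians, key=lambda w: (abs(w - week), w))
            logger.warning(
                "week %d not in fitted curve; using nearest fitted week %d",
                week, nearest,
            )
            return self.medians[nearest]
        raise CurveLookupError(f"no fitted median for gestational week {week}")


def fit_median_curve(
    samples: pd.DataFrame, bin_width: int = 1, min_bin_count: int = 1
) -> MedianCurve:
    """Fit the per-gestational-week median curve from unaffected samples.

    Bins of `bin_width` weeks are computed with the midpoint convention for
    even counts; bins with fewer than `min_bin_count` samples are merged
    into their nearest neighbouring bin (pooled median) until all bins meet
    the minimum.
    """
    if len(samples) == 0:
        raise FittingError("cannot fit a median curve from zero samples")
    weeks = samples["ga_week"].to_numpy()
    conc = samples["concentration_pg_ml"].to_numpy(dtype=float)
    bin_id = weeks // bin_width
    bins: dict[int, list[int]] = {}  # bin id -> member week list
    values: dict[int, np.ndarray] = {}
    for b in np.unique(bin_id):
        mask = bin_id == b
        bins[int(b)] = sorted(set(int(w) for w in weeks[mask]))
        values[int(b)] = conc[mask]

    def center(b: int) -> float:
        return float(np.mean(bins[b]))

    while len(bins) > 1:
        small = [b for b in bins if len(values[b]) < min_bin_count]
        if not small:
            break
        b = small[0]
        others = [o for o in bins if o != b]
        nearest = min(others, key=lambda o: (abs(center(o) - center(b)), o))
        bins[nearest] = sorted(bins[nearest] + bins[b])
        values[nearest] = np.concatenate([values[nearest], values[b]])
        del bins[b], values[b]

    medians: dict[int, float] = {}
    counts: dict[int, int] = {}
    for b, week_list in bins.items():
        med = float(np.median(values[b]))
        for w in week_list:
            medians[w] = med
            counts[w] = int(len(values[b]))
    return MedianCurve(medians=medians, counts=counts)


def to_mom(samples: pd.DataFrame, curve: MedianCurve, fallback: str = "error") -> pd.DataFrame:
    """Convert a sample table to MoM records.

    Adds `trimester` (from the sampling window) and `mom` columns; the
    adjusted columns are filled by the adjustment steps.
    """
    out = samples.copy()
    out["trimester"] = [trimester_of_week(int(w)) for w in out["ga_week"]]
    denom = np.array([curve.value(int(w), fallback=fallback) for w in out["ga_week"]])
    out["mom"] = out["concentration_pg_ml"].to_numpy(dtype=float) / denom
    if not np.all(np.isfinite(out["mom"])) or (out["mom"] <= 0).any():
        raise FittingError("MoM conversion produced nonpositive or nonfinite values")
    return out


@dataclass
class AdjustmentModel:
    """Sequential covariate adjustment plus ABO blood-group factors.

    `terms` stores, in fitting order, one entry per covariate:
    ("numeric", mean, slope) or ("categorical", {level: effect}) with
    effects centered so that applying the model to its own fitting set
    preserves the mean log-MoM.
    """

    covariate_order: tuple[str, ...]
    terms: dict[str, tuple] = field(default_factory=dict)
    blood_group_factors: dict = field(default_factory=dict)
    per_trimester: bool = True
    n_fit: int = 0

    def log_adjustment(self, covariates: pd.DataFrame) -> np.ndarray:
        """Total log-scale correction to subtract from log(MoM)."""
        total = np.zeros(len(covariates), dtype=float)
        for name in self.covariate_order:
            kind, *payload = self.terms[name]
            if kind == "numeric":
                mean, slope = payload
                x = covariates[name].to_numpy(dtype=float)
                total += slope * (x - mean)
            else:
                (effects,) = payload
                levels = covariates[name].astype(str)
                total += np.array([effects.get(lv, 0.0) for lv in levels])
        return total


def _fit_one_covariate(y: np.ndarray, x: pd.Series, name: str) -> tuple:
    """OLS of y on one centered covariate; returns the stored term."""
    if name in CATEGORICAL_COVARIATES or x.dtype == object or x.dtype == bool:
        levels = x.astype(str)
        uniq = sorted(levels.unique())
        if len(uniq) < 2:
            logger.warning("covariate %r is constant; coefficient set to 0", name)
            return ("categorical", {})
        dummies = pd.get_dummies(levels, dtype=float)[uniq]
        centered = dummies - dummies.mean(axis=0)
        # drop one column to avoid collinearity; effects recovered per level
        design = centered.iloc[:, :-1].to_numpy()
        fit = sm.OLS(y, design).fit()
        coefs = dict(zip(uniq[:-1], fit.params))
        coefs[uniq[-1]] = 0.0
        # re-center so the fitting-set-weighted mean effect is zero
        weights = dummies.mean(axis=0)
        offset = sum(weights[lv] * coefs[lv] for lv in uniq)
        effects = {lv: coefs[lv] - offset for lv in uniq}
        return ("categorical", effects)
    xv = x.to_numpy(dtype=float)
    if np.ptp(xv) < 1e-12:
        logger.warning("covariate %r is constant; coefficient set to 0", name)
        return ("numeric", float(xv.mean()) if len(xv) else 0.0, 0.0)
    mean = float(xv.mean())
    fit = sm.OLS(y, (xv - mean)[:, None]).fit()
    return ("numeric", mean, float(fit.params[0]))


def fit_covariate_adjustment(
    moms: pd.DataFrame,
    covariates: pd.DataFrame,
    order: Sequence[str] = ("bmi", "ethnicity", "smoking", "age", "parity"),
    joint: bool = False,
) -> AdjustmentModel:
    """Fit the sequential (or joint) covariate adjustment on unaffected MoMs.

    `moms` and `covariates` must be row-aligned. In sequential mode each
    covariate is fitted against the residual of the previous step, matching
    a step-wise adjustment; in joint mode a single multiple regression on
    all centered predictors is used.
    """
    missing_cols = [c for c in order if c not in covariates.columns]
    if missing_cols:
        raise FittingError(f"missing covariate columns: {missing_cols}")
    na_rows = covariates[list(order)].isna().any(axis=1)
    if na_rows.any():
        bad = covariates.loc[na_rows, "subject_id"].tolist() if "subject_id" in covariates else list(np.where(na_rows)[0])
        raise FittingError(f"missing covariate values for subjects {bad}")
    if len(moms) == 0:
        raise FittingError("cannot fit covariate adjustment on zero records")

    y = np.log(moms["mom"].to_numpy(dtype=float))
    model = AdjustmentModel(covariate_order=tuple(order), n_fit=len(moms))
    if joint:
        # single multiple regression; store per-covariate partial terms
        resid = y.copy()
        parts = {}
        blocks = []
        meta = []
        for name in order:
            term = _prepare_joint_block(covariates, name)
            if term is None:
                parts[name] = ("numeric", 0.0, 0.0)
                continue
            block, info = term
            blocks.append(block)
            meta.append((name, info))
        if blocks:
            design = np.column_stack(blocks)
            fit = sm.OLS(y, design).fit()
            pos = 0
            for name, info in meta:
                kind = info[0]
                if kind == "numeric":
                    parts[name] = ("numeric", info[1], float(fit.params[pos]))
                    pos += 1
                else:
                    uniq, weights = info[1], info[2]
                    coefs = dict(zip(uniq[:-1], fit.params[pos:pos + len(uniq) - 1]))
                    coefs[uniq[-1]] = 0.0
                    offset = sum(weights[lv] * coefs[lv] for lv in uniq)
                    parts[name] = ("categorical", {lv: coefs[lv] - offset for lv in uniq})
                    pos += len(uniq) - 1
        for name in order:
            model.terms[name] = parts.get(name, ("numeric", 0.0, 0.0))
        return model

    resid = y.copy()
    for name in order:
        term = _fit_one_covariate(resid, covariates[name], name)
        model.terms[name] = term
        kind, *payload = term
        if kind == "numeric":
            mean, slope = payload
            resid = resid - slope * (covariates[name].to_numpy(dtype=float) - mean)
        else:
            (effects,) = payload
            levels = covariates[name].astype(str)
            resid = resid - np.array([effects.get(lv, 0.0) for lv in levels])
    return model


def _prepare_joint_block(covariates: pd.DataFrame, name: str):
    x = covariates[name]
    if name in CATEGORICAL_COVARIATES or x.dtype == object or x.dtype == bool:
        levels = x.astype(str)
        uniq = sorted(levels.unique())
        if len(uniq) < 2:
            logger.warning("covariate %r is constant; coefficient set to 0", name)
            return None
        dummies = pd.get_dummies(levels, dtype=float)[uniq]
        centered = (dummies - dummies.mean(axis=0)).iloc[:, :-1].to_numpy()
        return centered, ("categorical", uniq, dummies.mean(axis=0))
    xv = x.to_numpy(dtype=float)
    if np.ptp(xv) < 1e-12:
        logger.warning("covariate %r is constant; coefficient set to 0", name)
        return None
    mean = float(xv.mean())
    return (xv - mean)[:, None], ("numeric", mean)


def apply_covariate_adjustment(
    moms: pd.DataFrame, covariates: pd.DataFrame, model: AdjustmentModel
) -> pd.DataFrame:
    """Add the `mom_cov_adj` column; `covariates` must be row-aligned."""
    out = moms.copy()
    corr = model.log_adjustment(covariates)
    out["mom_cov_adj"] = np.exp(np.log(out["mom"].to_numpy(dtype=float)) - corr)
    return out


def fit_blood_group_factors(
    moms: pd.DataFrame,
    per_trimester: bool = True,
    min_count: int = 5,
) -> dict:
    """Median adjusted MoM of unaffected women per ABO group.

    `moms` must carry `blood_group`, `mom_cov_adj` and (when per_trimester)
    `trimester`. Strata below `min_count` fall back to a factor of 1.0 with
    a logged warning. Keys are group or (group, trimester).
    """
    factors: dict = {}
    if per_trimester:
        strata = [(g, t) for g in BLOOD_GROUPS for t in TRIMESTERS]
    else:
        strata = list(BLOOD_GROUPS)
    for key in strata:
        if per_trimester:
            g, t = key
            mask = (moms["blood_group"] == g) & (moms["trimester"] == t)
        else:
            mask = moms["blood_group"] == key
        n = int(mask.sum())
        if n < min_count:
            logger.warning(
                "blood-group stratum %r has %d (< %d) records; factor set to 1.0",
                key, n, min_count,
            )
            factors[key] = 1.0
        else:
            factors[key] = float(np.median(moms.loc[mask, "mom_cov_adj"]))
    return factors


def adjust_for_blood_group(moms: pd.DataFrame, factors: Mapping) -> pd.DataFrame:
    """Divide the covariate-adjusted MoM by the blood-group factor."""
    per_trimester = any(isinstance(k, tuple) for k in factors)
    out = moms.copy()
    denom = np.empty(len(out), dtype=float)
    groups = out["blood_group"].to_numpy()
    trims = out["trimester"].to_numpy() if per_trimester else None
    for i in range(len(out)):
        key = (groups[i], int(trims[i])) if per_trimester else groups[i]
        if key not in factors:
            raise KeyError(f"no blood-group factor for {key!r}")
        denom[i] = factors[key]
    out["mom_abo_adj"] = out["mom_cov_adj"].to_numpy(dtype=float) / denom
    return out


def change_rate(x1, w1, x2, w2) -> float:
    """Longitudinal change statistic (X2 - X1) / (W2 - W1).

    Computed in exact rational arithmetic before conversion to float.
    """
    if w1 == w2:
        raise ZeroDivisionError("change_rate requires W2 != W1")
    return float((Fraction(x2) - Fraction(x1)) / (Fraction(w2) - Fraction(w1)))


def median_slope(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """OLS slope and intercept through per-window (midweek, median) points."""
    if len(points) < 2:
        raise FittingError("median_slope needs at least two points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) < 1e-12:
        raise FittingError("median_slope needs distinct midweeks")
    with warnings.catch_warnings():
        # two-point fits make the p-value degenerate; we only use slope/intercept
        warnings.simplefilter("ignore")
        fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)
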