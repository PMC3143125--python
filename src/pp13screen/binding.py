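"""Erythrocyte-binding panel summaries and the inverse-mirror statistic.

Serum PP13 and erythrocyte-bound PP13 partition oppositely across ABO
blood groups: groups whose red cells bind (sequester) the lectin most
strongly show the lowest circulating levels. The module turns per-group
values into percent-of-total profiles and quantifies the inversion as a
rank correlation between the serum and binding profiles.
"""

from __future__ import annotations

import logging
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import BLOOD_GROUPS

logger = logging.getLogger(__name__)


class MirrorScore(NamedTuple):
    score: float
    degenerate: bool


def proportional_profile(values: Mapping[str, float]) -> dict[str, float]:
    """Percent share of each blood group in the four-group total.

    Idempotent and scale-invariant; rejects nonpositive inputs.
    """
    missing = [g for g in BLOOD_GROUPS if g not in values]
    if missing:
        raise ValueError(f"profile is missing blood groups {missing}")
    vals = np.array([float(values[g]) for g in BLOOD_GROUPS])
    if (vals <= 0).any():
        bad = [g for g, v in zip(BLOOD_GROUPS, vals) if v <= 0]
        raise ValueError(f"nonpositive values for blood groups {bad}")
    shares = 100.0 * vals / vals.sum()
    return dict(zip(BLOOD_GROUPS, shares.tolist()))


def inverse_mirror_score(
    serum_profile: Mapping[str, float], binding_profile: Mapping[str, float]
) -> MirrorScore:
    """Spearman rank correlation (mid-ranks for ties) between the serum and
    binding shares over the four blood groups; a strong inverse mirror
    yields a score near -1. Constant profiles are degenerate and score 0.
    """
    x = np.array([float(serum_profile[g]) for g in BLOOD_GROUPS])
    y = np.array([float(binding_profile[g]) for g in BLOOD_GROUPS])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant profile: inverse-mirror score is undefined, reporting 0")
        return MirrorScore(0.0, True)
    rho = stats.spearmanr(x, y).statistic
    return MirrorScore(float(rho), False)


def specific_binding_ratio(panel: pd.DataFrame) -> dict[str, float]:
    """Fold of PP13 binding over the non-specific controls, per blood group.

    Uses the top PP13 concentration against the mean of the trPP13 / BSA
    control MFIs (the truncated protein lacks the carbohydrate-recognition
    domain and binds only at background level).
    """
    controls = panel[panel["ligand"].isin(("trPP13", "BSA"))]
    if len(controls) == 0:
        raise ValueError("binding panel has no trPP13/BSA control rows")
    control_mfi = float(controls["mean_mfi"].mean())
    pp13 = panel[panel["ligand"] == "PP13"]
    top = pp13["conc_ug_ml"].max()
    at_top = pp13[pp13["conc_ug_ml"] == top]
    out = {}
    for g in BLOOD_GROUPS:
        rows = at_top[at_top["blood_group"] == g]
        if len(rows) == 0:
            raise ValueError(f"binding panel lacks a top-concentration row for group {g}")
        out[g] = float(rows["mean_mfi"].iloc[0] / control_mfi)
    return out


def panel_profile(panel: pd.DataFrame, conc_ug_ml: float | None = None) -> dict[str, float]:
    """Proportional binding profile of the panel at one PP13 concentration
    (top concentration by default)."""
    pp13 = panel[panel["ligand"] == "PP13"]
    conc = pp13["conc_ug_ml"].max() if conc_ug_ml is None else conc_ug_ml
    sel = pp13[pp13["conc_ug_ml"] == conc]
    values = {g: float(sel[sel["blood_group"] == g]["mean_mfi"].iloc[0]) for g in BLOOD_GROUPS}
    return proportional_profile(values)
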