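"""Nutritional-status classification, growth velocity, response labels, dosing.

Anthropometry follows WHO z-score conventions: WAZ (weight-for-age), WLZ
(weight-for-length) and LAZ (length-for-age).  The package consumes z-scores
directly; conversion from raw weight/length is out of scope.

Response to the 8-week RUSF course is defined on weight-for-age velocity
(ΔWAZ per month) over the intervention window: > 0.5/month marks a responder,
≤ 0/month a nonresponder, anything between is intermediate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

StatusFlag = Literal[
    "stunted", "underweight", "at_risk_wasting", "moderate_wasting", "severe_wasting"
]


@dataclass(frozen=True)
class NutritionalStatus:
    flags: frozenset[str]

    def __contains__(self, flag: str) -> bool:
        return flag in self.flags

    @property
    def wasted(self) -> bool:
        return "moderate_wasting" in self.flags or "severe_wasting" in self.flags


@dataclass(frozen=True)
class GrowthVelocity:
    delta_waz_per_month: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValidationError("velocity window must have positive length")


@dataclass
class GrowthRecord:
    """Longitudinal WAZ/WLZ/LAZ observations for one subject.

    ``observations`` columns: age_months, waz, wlz, laz; ages strictly
    increasing.
    """

    subject_id: str
    observations: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"age_months", "waz", "wlz", "laz"}
        if not required <= set(self.observations.columns):
            raise ValidationError(f"growth record needs columns {sorted(required)}")
        ages = self.observations["age_months"].to_numpy(float)
        if len(ages) and not (np.diff(ages) > 0).all():
            raise ValidationError("ages must be strictly increasing within a subject")
        vals = self.observations[["waz", "wlz", "laz"]].to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValidationError("z-scores must be finite")

    def nearest(self, age_months: float, tolerance: float = 0.5) -> pd.Series:
        ages = self.observations["age_months"].to_numpy(float)
        i = int(np.argmin(np.abs(ages - age_months)))
        if abs(ages[i] - age_months) > tolerance:
            raise InsufficientDataError(
                f"subject {self.subject_id}: no visit within {tolerance} months of "
                f"age {age_months}"
            )
        return self.observations.iloc[i]


def classify_status(wlz: float, laz: float, waz: float) -> NutritionalStatus:
    """Flag nutritional status from the standard z-score cut-offs.

    Wasting partitions the WLZ axis: at-risk means −2 ≤ WLZ < −1, moderate
    −3 ≤ WLZ < −2, severe WLZ < −3.  Stunting is LAZ < −2 and underweight
    WAZ < −2, independently of wasting.
    """
    for name, z in (("wlz", wlz), ("laz", laz), ("waz", waz)):
        if not math.isfinite(z):
            raise ValidationError(f"{name} must be finite, got {z}")
    flags: set[str] = set()
    if laz < -2:
        flags.add("stunted")
    if waz < -2:
        flags.add("underweight")
    if wlz < -3:
        flags.add("severe_wasting")
    elif wlz < -2:
        flags.add("moderate_wasting")
    elif wlz < -1:
        flags.add("at_risk_wasting")
    return NutritionalStatus(frozenset(flags))


def waz_velocity(
    record: GrowthRecord,
    start_age: float,
    end_age: float,
    tolerance: float = 0.5,
) -> GrowthVelocity:
    """ΔWAZ per month between the visits nearest the two window endpoints."""
    if end_age <= start_age:
        raise ValidationError("end_age must exceed start_age")
    start = record.nearest(start_age, tolerance)
    end = record.nearest(end_age, tolerance)
    months = float(end["age_months"] - start["age_months"])
    if months <= 0:
        raise InsufficientDataError(
            f"subject {record.subject_id}: window endpoints resolve to the same visit"
        )
    delta = float(end["waz"] - start["waz"]) / months
    return GrowthVelocity(delta, (float(start["age_months"]), float(end["age_months"])))


def assign_response(
    velocity: GrowthVelocity, upper: float = 0.5, lower: float = 0.0
) -> str:
    """Label a WAZ velocity: responder (> upper), nonresponder (≤ lower), else intermediate."""
    if upper <= lower:
        raise ValidationError("upper threshold must exceed lower threshold")
    v = velocity.delta_waz_per_month
    if v > upper:
        return "responder"
    if v <= lower:
        return "nonresponder"
    return "intermediate"


def parent_study_response(wlz_one_week_post: float) -> bool:
    """Parent-study criterion: WLZ ≥ −2 one week after the intervention."""
    if not math.isfinite(wlz_one_week_post):
        raise ValidationError("WLZ must be finite")
    return wlz_one_week_post >= -2


def compliance_percent(packets_used: int, packets_given: int) -> float:
    """Compliance as percent of distributed sachets actually consumed."""
    if packets_given <= 0:
        raise ValidationError("packets_given must be positive")
    if not 0 <= packets_used <= packets_given:
        raise ValidationError("packets_used must lie in [0, packets_given]")
    return 100.0 * packets_used / packets_given


def rusf_dose(
    status: NutritionalStatus, weight_kg: float, kcal_per_sachet: float = 520.0
) -> int:
    """Daily RUSF sachets: 1 for moderate wasting; weight-based (200 kcal/kg/day,
    rounded up to whole sachets) for severe wasting."""
    if weight_kg <= 0:
        raise ValidationError("weight must be positive")
    if kcal_per_sachet <= 0:
        raise ValidationError("kcal_per_sachet must be positive")
    if "severe_wasting" in status:
        return math.ceil(200.0 * weight_kg / kcal_per_sachet)
    if "moderate_wasting" in status:
        return 1
    raise ValidationError("RUSF dosing is indicated only for moderate or severe wasting")


# ---------------------------------------------------------------------------
# Long-format growth I/O


def read_growth_records(path: str | Path) -> dict[str, GrowthRecord]:
    """Read long-format TSV (subject_id, age_months, waz, wlz, laz)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    out: dict[str, GrowthRecord] = {}
    for subject, grp in df.groupby("subject_id", sort=True):
        obs = grp.sort_values("age_months").reset_index(drop=True)
        out[str(subject)] = GrowthRecord(str(subject), obs[["age_months", "waz", "wlz", "laz"]])
    return out


def write_growth_records(records: dict[str, GrowthRecord], path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    frames = []
    for subject in sorted(records):
        obs = records[subject].observations.copy()
        obs.insert(0, "subject_id", subject)
        frames.append(obs)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
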