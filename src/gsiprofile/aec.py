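"""Scan-time automatic-exposure-control simulation for dual-energy profiles.

In dual-energy mode the tube currents are fixed for the whole helical
acquisition — there is no longitudinal modulation — so the scanner
derives a *single* target CTDIvol from the patient thickness along the
scan, picks the tube current in the selected preset family whose dose
comes closest, and shows the operator the *projected noise index*
(PNI): the noise expected at each table position given the dose
actually delivered, plus its scan-length average (AvgPNI).

The patient is a water-equivalent thickness profile d(z).  Two
empirical laws close the model:

* attenuation: the dose required to hold noise constant doubles for
  every ``d_double`` (default 5 cm) of added thickness — abdominal
  transmission changes by about a factor of 2 over 5 cm;
* noise statistics: noise ∝ dose^(-1/2), so halving the noise index
  quadruples the required dose.

Both are anchored by a calibration point: ``ctdi_ref`` is the dose that
achieves noise ``ni_ref`` at thickness ``d_ref``.

The operator's rule is simulated too: keep the primary family unless
the AvgPNI deviates from the prescribed noise index by more than a
threshold (default 2 HU), in which case switch to the small (quieter
than needed → dose can drop) or large (noisier than wanted → dose must
rise) family.
"""

from __future__ import annotations

from enum import Enum
from typing import Literal, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .builder import GsiProfile, Role
from .coverage import nearest_achievable
from .presets import PresetFamily, ctdi_grid

__all__ = [
    "PatientModel",
    "NoiseFlag",
    "Recommendation",
    "FamilyAssessment",
    "AecResult",
    "required_ctdi",
    "target_ctdi",
    "choose_current",
    "projected_ni",
    "technologist_rule",
    "simulate_exam",
]

SWITCH_THRESHOLD_HU = 2.0


class PatientModel(BaseModel):
    """Water-equivalent thickness profile along the table axis.

    ``ctdi_ref`` (mGy) is the dose that yields noise ``ni_ref`` (HU) at
    the reference thickness ``d_ref`` (cm); ``d_double`` is the extra
    thickness that doubles the required dose.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    z: tuple[float, ...]
    d: tuple[float, ...]
    d_ref: float = Field(default=30.0, gt=0)
    d_double: float = Field(default=5.0, gt=0)
    ctdi_ref: float = Field(default=12.0, gt=0)
    ni_ref: float = Field(default=18.0, gt=0)

    @field_validator("z", "d", mode="before")
    @classmethod
    def _coerce(cls, v):
        return tuple(float(x) for x in np.asarray(v, dtype=float).ravel())

    @model_validator(mode="after")
    def _check(self) -> "PatientModel":
        z = np.asarray(self.z)
        d = np.asarray(self.d)
        if z.size == 0 or z.size != d.size:
            raise ValueError("z and d must be equal-length and non-empty")
        if z.size > 1 and np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("thickness must be positive everywhere")
        return self

    def thickness(self) -> np.ndarray:
        return np.asarray(self.d, dtype=float)

    @property
    def scan_length_cm(self) -> float:
        return self.z[-1] - self.z[0]


class NoiseFlag(str, Enum):
    """Display state of the projected noise: orange when above target."""

    ABOVE = "above"
    AT_OR_BELOW = "at_or_below"


class Recommendation(str, Enum):
    SWITCH_SMALL = "switch_small"
    KEEP_PRIMARY = "keep_primary"
    SWITCH_LARGE = "switch_large"


class FamilyAssessment(BaseModel):
    """One row of the operator's solutions dialog: a family, the current
    chosen for it, and the noise it would deliver."""

    model_config = ConfigDict(frozen=True)

    role: Role
    family_name: str
    chosen_ma: Optional[float]
    actual_ctdi: float
    pni_profile: tuple[float, ...]
    avg_pni: float
    flag: NoiseFlag


class AecResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    target_ctdi: float
    prescribed_ni: float
    per_family: tuple[FamilyAssessment, ...]
    selected_role: Role
    recommendation: Recommendation


def required_ctdi(
    d: Union[float, np.ndarray], patient: PatientModel, ni: float
) -> Union[float, np.ndarray]:
    """Dose (mGy) needed to hit noise index ``ni`` at thickness ``d`` (cm).

        ctdi_ref · (ni_ref/ni)² · 2^((d − d_ref)/d_double)
    """
    if ni <= 0:
        raise ValueError(f"noise index must be positive, got {ni}")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("thickness must be positive")
    out = (
        patient.ctdi_ref
        * (patient.ni_ref / ni) ** 2
        * np.exp2((d_arr - patient.d_ref) / patient.d_double)
    )
    return float(out) if np.isscalar(d) else out


AggregationRule = Literal["mean", "max", "quantile"]


def target_ctdi(
    patient: PatientModel,
    ni: float,
    rule: AggregationRule = "mean",
    quantile: float = 0.9,
) -> float:
    """Single target dose for the whole scan.

    The per-slice requirements are aggregated with ``rule``: the default
    unweighted mean over scan positions; ``max`` (no slice noisier than
    the target) and ``quantile`` are available since the vendor's
    aggregation is unpublished.
    """
    req = required_ctdi(patient.thickness(), patient, ni)
    if rule == "mean":
        return float(np.mean(req))
    if rule == "max":
        return float(np.max(req))
    if rule == "quantile":
        return float(np.quantile(req, quantile))
    raise ValueError(f"unknown aggregation rule {rule!r}")


def choose_current(
    family: PresetFamily, target: float, n_grid: int = 20
) -> tuple[Optional[float], float]:
    """Tube current (if the family has an mA list) and the achievable
    CTDIvol closest to ``target``.  Targets outside the family's range
    clamp to the nearest endpoint."""
    grid = ctdi_grid(family, n_grid=n_grid)
    actual = nearest_achievable(grid, target)
    ma = None
    if family.ma_grid is not None:
        idx = int(np.argmin(np.abs(grid.as_array() - actual)))
        ma = family.ma_grid[idx]
    return ma, actual


def projected_ni(
    patient: PatientModel, actual_ctdi: float, ni: float
) -> tuple[np.ndarray, float, np.ndarray]:
    """Projected noise index along z for a delivered dose.

    pni(z) = ni · sqrt(required(d(z), ni) / actual); returns the
    profile, its unweighted mean (AvgPNI) and the mask of positions
    where the projection exceeds the prescribed noise index (shown
    orange on the scout view).
    """
    if actual_ctdi <= 0:
        raise ValueError(f"delivered CTDIvol must be positive, got {actual_ctdi}")
    req = required_ctdi(patient.thickness(), patient, ni)
    pni = ni * np.sqrt(req / actual_ctdi)
    return pni, float(np.mean(pni)), pni > ni


def technologist_rule(
    avg_pni: float, ni: float, threshold: float = SWITCH_THRESHOLD_HU
) -> Recommendation:
    """Keep the primary family unless AvgPNI is more than ``threshold``
    HU away from the prescribed noise index (strictly more: a deviation
    of exactly the threshold keeps the primary)."""
    if avg_pni < ni - threshold:
        return Recommendation.SWITCH_SMALL
    if avg_pni > ni + threshold:
        return Recommendation.SWITCH_LARGE
    return Recommendation.KEEP_PRIMARY


def simulate_exam(
    profile: GsiProfile,
    patient: PatientModel,
    ni: float,
    threshold: float = SWITCH_THRESHOLD_HU,
    n_grid: int = 20,
    rule: AggregationRule = "mean",
) -> AecResult:
    """Run the full scan-time workflow for one patient.

    Computes the target dose once, assesses every member family
    (current choice, PNI profile, flag), applies the switching rule to
    the primary family's AvgPNI, and maps the recommendation onto the
    profile's small/large roles (keeping the primary when the
    recommended role is absent).
    """
    target = target_ctdi(patient, ni, rule=rule)
    assessments = []
    for m in profile.members:
        ma, actual = choose_current(m.family, target, n_grid=n_grid)
        pni, avg, _above = projected_ni(patient, actual, ni)
        assessments.append(
            FamilyAssessment(
                role=m.role,
                family_name=m.family.name,
                chosen_ma=ma,
                actual_ctdi=actual,
                pni_profile=tuple(pni.tolist()),
                avg_pni=avg,
                flag=NoiseFlag.ABOVE if avg > ni else NoiseFlag.AT_OR_BELOW,
            )
        )
    by_role = {a.role: a for a in assessments}
    primary = by_role[profile.primary_role]
    rec = technologist_rule(primary.avg_pni, ni, threshold=threshold)
    selected = profile.primary_role
    if rec is Recommendation.SWITCH_SMALL and Role.SMALL in by_role:
        selected = Role.SMALL
    elif rec is Recommendation.SWITCH_LARGE and Role.LARGE in by_role:
        selected = Role.LARGE
    return AecResult(
        target_ctdi=target,
        prescribed_ni=ni,
        per_family=tuple(assessments),
        selected_role=selected,
        recommendation=rec,
    )
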