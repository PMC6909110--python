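"""Preset-family data model and the tube-current → CTDIvol mapping.

A *preset family* is one fixed acquisition mode of a dual-energy CT
scanner: scan field of view (SFOV), focal spot, collimation, gantry
rotation time and helical pitch, together with a discrete list of
allowed tube currents.  Because the current list is discrete, each
family can produce only a discrete set of CTDIvol values; the span of
that set is the family's achievable dose range.

Vendor documentation publishes the range endpoints (min/max CTDIvol)
but not the mA lists themselves, so bounds-only families are
first-class here: :func:`ctdi_grid` substitutes a uniform synthetic
grid between the printed endpoints when no mA list is available.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "FocalSpot",
    "PresetFamily",
    "AchievableDoseSet",
    "ctdi_for_ma",
    "ctdi_grid",
    "family_matches",
    "calibrate_dose_coeff",
]

#: Families printed in dose tables carry one-decimal mGy precision; two
#: representations of the same family must agree to half a ULP of that.
DOSE_TABLE_TOLERANCE_MGY = 0.05


class FocalSpot(str, Enum):
    """X-ray tube focal spot size; XLarge permits higher currents at some
    cost in spatial resolution."""

    LARGE = "Large"
    XLARGE = "XLarge"


class PresetFamily(BaseModel):
    """One scanner acquisition mode and its achievable CTDIvol values.

    Exactly one of the two dose representations must be supplied:

    * ``ma_grid`` + ``dose_coeff`` — explicit tube-current list with a
      per-family dose coefficient (mGy per mA·s at pitch 1);
    * ``ctdi_min`` + ``ctdi_max`` — published range endpoints only.

    If both are present they must agree to ``DOSE_TABLE_TOLERANCE_MGY``.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    sfov: str
    focal_spot: FocalSpot = FocalSpot.LARGE
    collimation_mm: float = Field(gt=0)
    rotation_time_s: float = Field(gt=0)
    pitch: float = Field(gt=0)
    ma_grid: Optional[tuple[float, ...]] = None
    dose_coeff: Optional[float] = Field(default=None, gt=0)
    ctdi_min: Optional[float] = Field(default=None, gt=0)
    ctdi_max: Optional[float] = Field(default=None, gt=0)

    @field_validator("ma_grid", mode="before")
    @classmethod
    def _coerce_grid(cls, v):
        if v is None:
            return None
        return tuple(float(x) for x in v)

    @model_validator(mode="after")
    def _check_representation(self) -> "PresetFamily":
        has_grid = self.ma_grid is not None
        has_bounds = self.ctdi_min is not None and self.ctdi_max is not None
        if has_grid:
            if self.dose_coeff is None:
                raise ValueError(f"family {self.name!r}: ma_grid requires dose_coeff")
            arr = np.asarray(self.ma_grid)
            if arr.size == 0:
                raise ValueError(f"family {self.name!r}: ma_grid is empty")
            if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise ValueError(
                    f"family {self.name!r}: ma_grid must be positive and strictly increasing"
                )
        elif self.dose_coeff is not None:
            raise ValueError(f"family {self.name!r}: dose_coeff requires ma_grid")
        if not has_grid and not has_bounds:
            raise ValueError(
                f"family {self.name!r}: provide either ma_grid+dose_coeff or ctdi_min+ctdi_max"
            )
        if has_bounds and self.ctdi_min > self.ctdi_max:
            raise ValueError(f"family {self.name!r}: ctdi_min > ctdi_max")
        if has_grid and has_bounds:
            lo = ctdi_for_ma(self, self.ma_grid[0])
            hi = ctdi_for_ma(self, self.ma_grid[-1])
            if (
                abs(lo - self.ctdi_min) > DOSE_TABLE_TOLERANCE_MGY
                or abs(hi - self.ctdi_max) > DOSE_TABLE_TOLERANCE_MGY
            ):
                raise ValueError(
                    f"family {self.name!r}: mA grid endpoints ({lo:.2f}, {hi:.2f}) mGy "
                    f"disagree with declared bounds ({self.ctdi_min}, {self.ctdi_max})"
                )
        return self

    # -- derived range endpoints -------------------------------------------

    @property
    def dose_min(self) -> float:
        """Lowest achievable CTDIvol (mGy)."""
        if self.ctdi_min is not None:
            return self.ctdi_min
        return ctdi_for_ma(self, self.ma_grid[0])

    @property
    def dose_max(self) -> float:
        """Highest achievable CTDIvol (mGy)."""
        if self.ctdi_max is not None:
            return self.ctdi_max
        return ctdi_for_ma(self, self.ma_grid[-1])

    def settings_label(self) -> str:
        """Scanner-style settings string, e.g. 'Large Body/80 mm/L/0.8 s/0.992:1'."""
        fs = "XL" if self.focal_spot is FocalSpot.XLARGE else "L"
        return (
            f"{self.sfov}/{self.collimation_mm:g} mm/{fs}/"
            f"{self.rotation_time_s:g} s/{self.pitch:g}:1"
        )


class AchievableDoseSet(BaseModel):
    """The discrete CTDIvol values one family (or a whole profile) can produce."""

    model_config = ConfigDict(frozen=True)

    values: tuple[float, ...]
    source: str = ""

    @field_validator("values", mode="before")
    @classmethod
    def _coerce(cls, v):
        return tuple(float(x) for x in v)

    @model_validator(mode="after")
    def _check_sorted(self) -> "AchievableDoseSet":
        arr = np.asarray(self.values)
        if arr.size == 0:
            raise ValueError("achievable dose set is empty")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("achievable dose values must be strictly increasing")
        return self

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def dose_min(self) -> float:
        return self.values[0]

    @property
    def dose_max(self) -> float:
        return self.values[-1]


def ctdi_for_ma(family: PresetFamily, ma: float) -> float:
    """CTDIvol (mGy) produced by ``family`` at tube current ``ma``.

    Standard helical scaling: dose is proportional to the tube
    current–time product and inversely proportional to pitch,

        CTDIvol = k · mA · T_rot / pitch,

    with the per-family coefficient ``k`` (``dose_coeff``) absorbing
    kV-pair, focal-spot and bowtie differences.
    """
    if family.dose_coeff is None:
        raise ValueError(f"family {family.name!r} has no dose_coeff; bounds-only")
    if ma <= 0:
        raise ValueError(f"tube current must be positive, got {ma}")
    return family.dose_coeff * ma * family.rotation_time_s / family.pitch


def calibrate_dose_coeff(
    rotation_time_s: float, pitch: float, ma: float, ctdi: float
) -> float:
    """Dose coefficient k such that k·ma·T/pitch equals ``ctdi``.

    Used to anchor a synthetic mA grid to published range endpoints.
    """
    if min(rotation_time_s, pitch, ma, ctdi) <= 0:
        raise ValueError("all calibration inputs must be positive")
    return ctdi * pitch / (ma * rotation_time_s)


def ctdi_grid(family: PresetFamily, n_grid: int = 20) -> AchievableDoseSet:
    """All CTDIvol values the family can produce, ascending.

    With an explicit mA list, one dose per current.  For a bounds-only
    family a uniform grid of ``n_grid`` points spans [ctdi_min,
    ctdi_max] with exact endpoints — a synthetic stand-in for the
    unpublished current list.
    """
    if family.ma_grid is not None:
        vals = [ctdi_for_ma(family, ma) for ma in family.ma_grid]
    else:
        if n_grid < 1:
            raise ValueError("n_grid must be >= 1")
        if n_grid == 1 or family.ctdi_min == family.ctdi_max:
            vals = [family.ctdi_min]
        else:
            vals = np.linspace(family.ctdi_min, family.ctdi_max, n_grid).tolist()
    return AchievableDoseSet(values=vals, source=family.name)


def family_matches(family: PresetFamily, constraints: "ProfileConstraints") -> bool:
    """True iff the family satisfies the clinical restrictions.

    SFOV and collimation are exact matches; pitch and rotation time must
    fall inside the allowed intervals; an XLarge focal spot is admitted
    only when the constraints allow it.
    """
    return not violated_constraints(family, constraints)


def violated_constraints(
    family: PresetFamily, constraints: "ProfileConstraints"
) -> list[str]:
    """Names of the constraint clauses the family fails (empty = match)."""
    bad: list[str] = []
    if family.sfov != constraints.sfov:
        bad.append(f"sfov != {constraints.sfov!r}")
    if family.collimation_mm != constraints.collimation_mm:
        bad.append(f"collimation_mm != {constraints.collimation_mm:g}")
    if constraints.pitch_max is not None and family.pitch > constraints.pitch_max:
        bad.append(f"pitch > {constraints.pitch_max:g}")
    if constraints.pitch_min is not None and family.pitch < constraints.pitch_min:
        bad.append(f"pitch < {constraints.pitch_min:g}")
    if constraints.rot_min is not None and family.rotation_time_s < constraints.rot_min:
        bad.append(f"rotation_time_s < {constraints.rot_min:g}")
    if constraints.rot_max is not None and family.rotation_time_s > constraints.rot_max:
        bad.append(f"rotation_time_s > {constraints.rot_max:g}")
    if family.focal_spot is FocalSpot.XLARGE and not constraints.allow_xlarge:
        bad.append("XLarge focal spot not allowed")
    return bad


def sorted_doses(values: Sequence[float], source: str = "") -> AchievableDoseSet:
    """Build an AchievableDoseSet from unordered values, deduplicating."""
    uniq = np.unique(np.asarray(list(values), dtype=float))
    return AchievableDoseSet(values=uniq.tolist(), source=source)
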