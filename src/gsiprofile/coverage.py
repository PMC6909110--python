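"""How precisely a discrete dose ladder can match an arbitrary target dose.

A profile can only produce the discrete CTDIvol values of its member
families' current grids.  For a target dose t and the closest
achievable value a, the signed fractional mismatch is

    f(t) = (t - a) / t,

zero exactly when the target is achievable, positive when the ladder
falls short and negative when the nearest rung overshoots.  A profile
"covers" a target at tolerance τ when |f| ≤ τ; the default τ = 0.05
reflects the noise-level error a reader cannot see in the image, and
CLINICALLY_INSIGNIFICANT_DOSE_CHANGE (25%) marks the dose change below
which the noise change is not noticeable at all.

Noise propagates as dose^(-1/2), so to first order a relative error δ
in the noise index corresponds to a 2δ relative error in dose:
:func:`ni_to_ctdi_mismatch`.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .builder import GsiProfile
from .presets import AchievableDoseSet, ctdi_grid, sorted_doses

__all__ = [
    "DoseMatchReport",
    "NiDoseMismatch",
    "nearest_achievable",
    "fractional_match",
    "profile_dose_union",
    "coverage_report",
    "ni_to_ctdi_mismatch",
    "DEFAULT_TOLERANCE",
    "CLINICALLY_INSIGNIFICANT_DOSE_CHANGE",
]

DEFAULT_TOLERANCE = 0.05
#: A dose change below ~25% does not produce a noticeable noise change.
CLINICALLY_INSIGNIFICANT_DOSE_CHANGE = 0.25


class DoseMatchReport(BaseModel):
    """Fractional-mismatch curve of a profile over a target-dose grid."""

    model_config = ConfigDict(frozen=True)

    profile_name: str
    union_min: float
    union_max: float
    targets: tuple[float, ...]
    nearest: tuple[float, ...]
    f_values: tuple[float, ...]
    tolerance: float
    covered_fraction: float

    def covered_mask(self) -> np.ndarray:
        return np.abs(np.asarray(self.f_values)) <= self.tolerance


class NiDoseMismatch(NamedTuple):
    """Noise-index mismatch and the dose mismatch it implies (percent)."""

    ni_percent: float
    ctdi_percent: float
    ni_percent_display: int
    ctdi_percent_display: int


def nearest_achievable(doses: AchievableDoseSet, target: float) -> float:
    """The achievable CTDIvol closest to ``target``; midpoint ties go low."""
    if target <= 0:
        raise ValueError(f"target CTDIvol must be positive, got {target}")
    v = doses.as_array()
    i = int(np.searchsorted(v, target))
    if i == 0:
        return float(v[0])
    if i == len(v):
        return float(v[-1])
    lo, hi = v[i - 1], v[i]
    # <= : an exact midpoint resolves to the lower value
    return float(lo) if target - lo <= hi - target else float(hi)


def fractional_match(doses: AchievableDoseSet, target: float) -> float:
    """Signed fractional mismatch (t - nearest)/t; zero iff t is achievable."""
    return (target - nearest_achievable(doses, target)) / target


def profile_dose_union(profile: GsiProfile, n_grid: int = 20) -> AchievableDoseSet:
    """Union of all member families' achievable dose values."""
    vals: list[float] = []
    for fam in profile.families:
        vals.extend(ctdi_grid(fam, n_grid=n_grid).values)
    return sorted_doses(vals, source=profile.name)


def default_target_grid(union: AchievableDoseSet, n_targets: int = 200) -> np.ndarray:
    """Log-spaced targets from 0.5×union_min to 1.5×union_max."""
    return np.geomspace(0.5 * union.dose_min, 1.5 * union.dose_max, n_targets)


def coverage_report(
    profile: GsiProfile,
    target_grid: Optional[Sequence[float]] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    n_grid: int = 20,
) -> DoseMatchReport:
    """Evaluate the fractional-mismatch curve of a profile.

    ``n_grid`` controls the synthetic per-family grid density for
    bounds-only families; explicit mA lists are used as-is.
    """
    union = profile_dose_union(profile, n_grid=n_grid)
    if target_grid is None:
        targets = default_target_grid(union)
    else:
        targets = np.asarray(list(target_grid), dtype=float)
    nearest = np.array([nearest_achievable(union, t) for t in targets])
    f = (targets - nearest) / targets
    covered = float(np.mean(np.abs(f) <= tolerance)) if targets.size else 0.0
    return DoseMatchReport(
        profile_name=profile.name,
        union_min=union.dose_min,
        union_max=union.dose_max,
        targets=tuple(targets.tolist()),
        nearest=tuple(nearest.tolist()),
        f_values=tuple(f.tolist()),
        tolerance=tolerance,
        covered_fraction=covered,
    )


def ni_to_ctdi_mismatch(ni_target: float, delta_ni: float) -> NiDoseMismatch:
    """Percent noise-index mismatch and the dose mismatch it implies.

    With noise ∝ dose^(-1/2), a relative noise error δ corresponds to a
    2δ relative dose error to first order (the exact factor is
    1-(1+δ)^(-2), which agrees with 2δ to within 3δ²).  Both percents
    are also returned rounded to whole percent for display.
    """
    if ni_target <= 0:
        raise ValueError(f"noise index must be positive, got {ni_target}")
    ni_pct = 100.0 * delta_ni / ni_target
    ctdi_pct = 2.0 * ni_pct
    return NiDoseMismatch(
        ni_percent=ni_pct,
        ctdi_percent=ctdi_pct,
        ni_percent_display=int(round(ni_pct)),
        ctdi_percent_display=int(round(ctdi_pct)),
    )
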