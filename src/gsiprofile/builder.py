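"""Greedy construction of small/medium/large/extra-large dose-ladder profiles.

The goal is a profile of three or four preset families whose CTDIvol
ranges overlap, but with as little overlap as possible: a wide total
dose range with few families, so the operator's choice at scan time
stays simple.  The procedure works on the candidate table sorted by
ascending minimum CTDIvol:

1. *Small* — the first candidate matching the clinical restrictions.
2. *Medium* — the last large-focal-spot candidate whose minimum CTDIvol
   is strictly below the small family's maximum.
3. *Large* — the last large-focal-spot candidate whose minimum CTDIvol
   is strictly below the medium family's maximum.
4. *Extra-large* — the candidate (any allowed focal spot) with the
   highest maximum CTDIvol.

When consecutive searches land on the same family the roles collapse and
the profile simply has fewer members.  The medium family is the primary
(used unless the operator overrides) by default; sites serving mostly
bariatric or pediatric populations may designate large or small instead.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .presets import (
    FocalSpot,
    PresetFamily,
    family_matches,
    violated_constraints,
)

__all__ = [
    "Role",
    "ProfileConstraints",
    "ProfileMember",
    "GsiProfile",
    "Diagnostic",
    "NoMatchingFamilyError",
    "sort_candidates",
    "build_profile",
    "validate_profile",
]


class Role(str, Enum):
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"
    XLARGE = "xlarge"


ROLE_ORDER = (Role.SMALL, Role.MEDIUM, Role.LARGE, Role.XLARGE)


class ProfileConstraints(BaseModel):
    """Clinical restrictions that filter candidate preset families."""

    model_config = ConfigDict(frozen=True)

    sfov: str
    collimation_mm: float = Field(gt=0)
    pitch_max: Optional[float] = Field(default=None, gt=0)
    pitch_min: Optional[float] = Field(default=None, gt=0)
    rot_min: Optional[float] = Field(default=None, gt=0)
    rot_max: Optional[float] = Field(default=None, gt=0)
    allow_xlarge: bool = True

    @model_validator(mode="after")
    def _check_intervals(self) -> "ProfileConstraints":
        if (
            self.pitch_min is not None
            and self.pitch_max is not None
            and self.pitch_min > self.pitch_max
        ):
            raise ValueError("pitch_min > pitch_max")
        if self.rot_min is not None and self.rot_max is not None and self.rot_min > self.rot_max:
            raise ValueError("rot_min > rot_max")
        return self


class ProfileMember(BaseModel):
    model_config = ConfigDict(frozen=True)

    role: Role
    family: PresetFamily


class GsiProfile(BaseModel):
    """An ordered set of role-labelled preset families.

    ``members`` are stored in patient-size order (small → xlarge); the
    primary family is listed first on serialization, which is how the
    scanner identifies it.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    members: tuple[ProfileMember, ...]
    primary_role: Role = Role.MEDIUM

    @model_validator(mode="after")
    def _check_members(self) -> "GsiProfile":
        if not 1 <= len(self.members) <= 4:
            raise ValueError("profile must have 1-4 members")
        roles = [m.role for m in self.members]
        if len(set(roles)) != len(roles):
            raise ValueError("duplicate roles in profile")
        if self.primary_role not in roles:
            raise ValueError(f"primary role {self.primary_role.value!r} not among members")
        return self

    def member(self, role: Role) -> Optional[ProfileMember]:
        for m in self.members:
            if m.role is role:
                return m
        return None

    @property
    def primary(self) -> ProfileMember:
        m = self.member(self.primary_role)
        assert m is not None
        return m

    def members_serialized(self) -> tuple[ProfileMember, ...]:
        """Members with the primary first, then the rest in size order."""
        rest = tuple(m for m in self.members if m.role is not self.primary_role)
        return (self.primary,) + rest

    @property
    def families(self) -> tuple[PresetFamily, ...]:
        return tuple(m.family for m in self.members)


class NoMatchingFamilyError(ValueError):
    """No candidate family satisfies the clinical restrictions."""


def sort_candidates(families: list[PresetFamily]) -> list[PresetFamily]:
    """Canonical candidate ordering: ascending minimum CTDIvol.

    Ties break by ascending maximum CTDIvol, then input order (the sort
    is stable), mirroring the layout of published preset-family tables.
    """
    return sorted(families, key=lambda f: (f.dose_min, f.dose_max))


def build_profile(
    families: list[PresetFamily],
    constraints: ProfileConstraints,
    name: str = "profile",
    primary_role: Role = Role.MEDIUM,
) -> GsiProfile:
    """Run the greedy small/medium/large/xlarge selection.

    Raises :class:`NoMatchingFamilyError` (naming the violated clauses)
    when nothing matches.  Duplicate selections collapse onto the
    earlier role; a requested primary role that collapsed resolves to
    the surviving role.
    """
    cands = [f for f in sort_candidates(families) if family_matches(f, constraints)]
    if not cands:
        detail = _violation_summary(families, constraints)
        raise NoMatchingFamilyError(f"no matching preset family: {detail}")

    large_focal = [f for f in cands if f.focal_spot is FocalSpot.LARGE]

    small = cands[0]
    medium = _last_with_min_below(large_focal, small.dose_max)
    anchor = medium if medium is not None else small
    large = _last_with_min_below(large_focal, anchor.dose_max)
    # highest achievable dose overall; ties -> lower dose_min, then sort order
    xlarge = max(cands, key=lambda f: (f.dose_max, -f.dose_min))

    picks = [
        (Role.SMALL, small),
        (Role.MEDIUM, medium),
        (Role.LARGE, large),
        (Role.XLARGE, xlarge),
    ]

    members: list[ProfileMember] = []
    alias: dict[Role, Role] = {}
    seen: dict[PresetFamily, Role] = {}  # family -> role that kept it
    for role, fam in picks:
        if fam is None:
            # failed search collapses onto the previous surviving role
            alias[role] = members[-1].role
            continue
        if fam in seen:
            alias[role] = seen[fam]
            continue
        seen[fam] = role
        members.append(ProfileMember(role=role, family=fam))

    resolved_primary = alias.get(primary_role, primary_role)
    return GsiProfile(name=name, members=tuple(members), primary_role=resolved_primary)


def _last_with_min_below(
    candidates: list[PresetFamily], dose_ceiling: float
) -> Optional[PresetFamily]:
    """Last candidate (canonical order) with dose_min strictly below the ceiling."""
    hit = None
    for f in candidates:
        if f.dose_min < dose_ceiling:
            hit = f
    return hit


def _violation_summary(
    families: list[PresetFamily], constraints: ProfileConstraints
) -> str:
    if not families:
        return "empty candidate table"
    counts: dict[str, int] = {}
    for f in families:
        for clause in violated_constraints(f, constraints):
            counts[clause] = counts.get(clause, 0) + 1
    parts = [f"{clause} ({n} families)" for clause, n in sorted(counts.items())]
    return "; ".join(parts)


class Diagnostic(BaseModel):
    """One finding from :func:`validate_profile`.

    ``kind`` is ``"gap"`` (consecutive ranges do not overlap — targets in
    the gap cannot be matched closely) or ``"overlap"`` (the summary
    entry whose ``value`` is the total-overlap fraction of the union
    span; the design goal is overlap, but as little as possible).
    """

    model_config = ConfigDict(frozen=True)

    kind: str
    roles: tuple[str, ...] = ()
    value: float
    message: str


def validate_profile(profile: GsiProfile) -> list[Diagnostic]:
    """Check the overlap structure of a profile's dose ladder.

    Emits one ``gap`` diagnostic per consecutive member pair (ascending
    dose_min) whose ranges do not overlap, plus a single ``overlap``
    summary with the total pairwise-overlap fraction of the union span.
    """
    ordered = sorted(profile.members, key=lambda m: (m.family.dose_min, m.family.dose_max))
    diags: list[Diagnostic] = []
    overlap_total = 0.0
    for lo, hi in zip(ordered, ordered[1:]):
        a, b = lo.family, hi.family
        if a.dose_max < b.dose_min:
            gap = b.dose_min - a.dose_max
            diags.append(
                Diagnostic(
                    kind="gap",
                    roles=(lo.role.value, hi.role.value),
                    value=gap,
                    message=(
                        f"gap of {gap:.1f} mGy between {lo.role.value} "
                        f"(max {a.dose_max:.1f}) and {hi.role.value} (min {b.dose_min:.1f})"
                    ),
                )
            )
        else:
            overlap_total += min(a.dose_max, b.dose_max) - b.dose_min
    union_min = min(m.family.dose_min for m in ordered)
    union_max = max(m.family.dose_max for m in ordered)
    span = union_max - union_min
    frac = overlap_total / span if span > 0 else 0.0
    diags.append(
        Diagnostic(
            kind="overlap",
            roles=tuple(m.role.value for m in ordered),
            value=frac,
            message=f"total overlap is {100 * frac:.1f}% of the {span:.1f} mGy union span",
        )
    )
    return diags
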