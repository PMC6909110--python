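"""Embedded published preset tables and synthetic-data generators.

The published material gives, for each profile, only the rotation time,
pitch, focal spot and the CTDIvol range endpoints of each member family
(one-decimal mGy) — never the underlying mA lists.  The six profiles
embedded here (one vendor-style liver profile and five large-body
80 mm-coverage design variants with different pitch/rotation-time
constraints) are reproduced verbatim at that precision; deduplicating
their rows yields the 13-family candidate table that the profile
builder's worked example runs on.

The random generators supply what the printed tables cannot: full-size
candidate tables with explicit mA grids, and synthetic patients
(thickness profiles along z), both reproducible by seed.
"""

from __future__ import annotations

import numpy as np

from .aec import PatientModel
from .builder import GsiProfile, ProfileMember, Role
from .presets import FocalSpot, PresetFamily, calibrate_dose_coeff

__all__ = [
    "published_profile",
    "published_profile_names",
    "published_candidate_table",
    "generate_family_table",
    "generate_patient",
    "generate_cohort",
]

_SFOV = "Large Body"
_COLL = 80.0

# profile key -> (description, rows); row = (role, focal, rot_s, pitch, min, max)
_PUBLISHED_TABLES: dict[str, tuple[str, list[tuple[str, str, float, float, float, float]]]] = {
    "liver": (
        "Liver protocol: three large-focal families, medium primary",
        [
            ("small", "Large", 0.5, 1.375, 3.6, 8.6),
            ("medium", "Large", 0.8, 0.992, 7.3, 18.6),
            ("large", "Large", 1.0, 0.508, 17.4, 44.6),
        ],
    ),
    "lb80": (
        "Large Body SFOV, 80 mm coverage, unconstrained pitch/rotation",
        [
            ("small", "Large", 0.5, 1.531, 3.1, 7.9),
            ("medium", "Large", 1.0, 1.375, 6.3, 16.8),
            ("large", "Large", 0.8, 0.508, 14.0, 36.8),
            ("xlarge", "XLarge", 1.0, 0.508, 49.7, 53.7),
        ],
    ),
    "lb80_pitch1375": (
        "Large Body SFOV, 80 mm coverage, helical pitch <= 1.375",
        [
            ("small", "Large", 0.5, 1.375, 3.4, 8.8),
            ("medium", "Large", 0.8, 0.992, 7.1, 18.9),
            ("large", "Large", 1.0, 0.508, 17.2, 45.5),
            ("xlarge", "XLarge", 1.0, 0.508, 49.7, 53.7),
        ],
    ),
    "lb80_pitch0992": (
        "Large Body SFOV, 80 mm coverage, helical pitch <= 0.992",
        [
            ("small", "Large", 0.5, 0.992, 4.7, 12.2),
            ("medium", "Large", 0.6, 0.508, 10.9, 28.4),
            ("large", "Large", 1.0, 0.508, 17.2, 45.5),
            ("xlarge", "XLarge", 1.0, 0.508, 49.7, 53.7),
        ],
    ),
    "lb80_rot06": (
        "Large Body SFOV, 80 mm coverage, rotation time <= 0.6 s (chest)",
        [
            ("small", "Large", 0.5, 1.531, 3.1, 7.9),
            ("medium", "Large", 0.6, 0.992, 5.6, 14.6),
            ("large", "Large", 0.6, 0.508, 10.9, 28.4),
            ("xlarge", "XLarge", 0.6, 0.508, 31.1, 33.6),
        ],
    ),
    "lb80_rot08": (
        "Large Body SFOV, 80 mm coverage, rotation time >= 0.8 s",
        [
            ("small", "Large", 0.8, 1.531, 4.6, 12.2),
            ("medium", "Large", 1.0, 0.992, 8.8, 23.3),
            ("large", "Large", 1.0, 0.508, 17.2, 45.5),
            ("xlarge", "XLarge", 1.0, 0.508, 49.7, 53.7),
        ],
    ),
}


def published_profile_names() -> list[str]:
    """Keys accepted by :func:`published_profile`."""
    return list(_PUBLISHED_TABLES)


def _row_family(focal: str, rot: float, pitch: float, lo: float, hi: float) -> PresetFamily:
    fs = "XL" if focal == "XLarge" else "L"
    return PresetFamily(
        name=f"{_SFOV}/{_COLL:g}mm/{fs}/{rot:g}s/{pitch:g}",
        sfov=_SFOV,
        focal_spot=FocalSpot(focal),
        collimation_mm=_COLL,
        rotation_time_s=rot,
        pitch=pitch,
        ctdi_min=lo,
        ctdi_max=hi,
    )


def published_profile(key: str) -> GsiProfile:
    """One of the embedded published profiles (bounds-only families)."""
    try:
        _desc, rows = _PUBLISHED_TABLES[key]
    except KeyError:
        raise KeyError(
            f"unknown profile {key!r}; available: {', '.join(_PUBLISHED_TABLES)}"
        ) from None
    members = tuple(
        ProfileMember(role=Role(role), family=_row_family(focal, rot, pitch, lo, hi))
        for role, focal, rot, pitch, lo, hi in rows
    )
    return GsiProfile(name=key, members=members, primary_role=Role.MEDIUM)


def published_candidate_table() -> list[PresetFamily]:
    """The distinct preset families across the embedded design profiles.

    Deduplicated on (rotation time, pitch, focal spot) and sorted by
    ascending minimum CTDIvol — the same layout as the full per-scanner
    candidate tables this stands in for.  13 families.
    """
    seen: dict[tuple[float, float, str], PresetFamily] = {}
    for key, (_desc, rows) in _PUBLISHED_TABLES.items():
        if key == "liver":  # vendor-style profile, not part of the design table
            continue
        for _role, focal, rot, pitch, lo, hi in rows:
            seen.setdefault((rot, pitch, focal), _row_family(focal, rot, pitch, lo, hi))
    return sorted(seen.values(), key=lambda f: (f.dose_min, f.dose_max))


# ---------------------------------------------------------------------------
# Random generators

PITCH_CHOICES = (0.508, 0.992, 1.375, 1.531)
ROTATION_CHOICES = (0.5, 0.6, 0.8, 1.0)


def generate_family_table(
    seed: int,
    n_families: int = 30,
    sfov: str = _SFOV,
    collimation_mm: float = _COLL,
    xlarge_fraction: float = 0.2,
) -> list[PresetFamily]:
    """Reproducible random candidate table with explicit mA grids.

    Pitches and rotation times are drawn from the scanner's actual
    discrete options; each family gets 10-40 evenly spaced currents and
    a dose coefficient calibrated so the resulting CTDIvol ranges fall
    in the realistic few-to-tens of mGy regime.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    fams: list[PresetFamily] = []
    for i in range(n_families):
        pitch = float(rng.choice(PITCH_CHOICES))
        rot = float(rng.choice(ROTATION_CHOICES))
        focal = FocalSpot.XLARGE if rng.random() < xlarge_fraction else FocalSpot.LARGE
        n_ma = int(rng.integers(10, 41))
        ma_start = float(rng.integers(40, 201))
        ma_step = float(rng.integers(5, 26))
        ma_grid = ma_start + ma_step * np.arange(n_ma)
        # anchor the low end of the range to a realistic minimum dose
        lo_dose = float(rng.uniform(2.0, 20.0))
        k = calibrate_dose_coeff(rot, pitch, ma_start, lo_dose)
        fs = "XL" if focal is FocalSpot.XLARGE else "L"
        fams.append(
            PresetFamily(
                name=f"rand{i:03d}/{fs}/{rot:g}s/{pitch:g}",
                sfov=sfov,
                focal_spot=focal,
                collimation_mm=collimation_mm,
                rotation_time_s=rot,
                pitch=pitch,
                ma_grid=tuple(ma_grid.tolist()),
                dose_coeff=k,
            )
        )
    return fams


def generate_patient(
    seed: int,
    length_cm: float = 40.0,
    n_z: int = 20,
    d_mean: float = 30.0,
    d_sd: float = 0.5,
    taper_cm: float = 0.0,
    **patient_kwargs,
) -> PatientModel:
    """Synthetic water-equivalent thickness profile.

    A linear taper of ``taper_cm`` end-to-end (abdominal thickness can
    easily change by 5 cm over one exam) plus bounded smooth noise of
    scale ``d_sd``; thickness is clipped to stay positive.
    """
    if length_cm <= 0 or n_z < 1 or d_mean <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, length_cm, n_z)
    d = d_mean + taper_cm * (z / length_cm - 0.5)
    if d_sd > 0:
        noise = rng.normal(0.0, d_sd, size=n_z)
        if n_z >= 3:  # light smoothing keeps the profile anatomically plausible
            noise = np.convolve(noise, np.ones(3) / 3.0, mode="same")
        d = d + np.clip(noise, -3 * d_sd, 3 * d_sd)
    d = np.maximum(d, 1.0)
    return PatientModel(z=tuple(z.tolist()), d=tuple(d.tolist()), **patient_kwargs)


def generate_cohort(
    seed: int,
    n: int = 50,
    d_mean_range: tuple[float, float] = (18.0, 42.0),
    d_sd: float = 0.5,
    taper_cm: float = 3.0,
    **patient_kwargs,
) -> list[PatientModel]:
    """Cohort of patients with mean thickness spanning ``d_mean_range``.

    Means are evenly spaced (ascending), so the cohort is monotone in
    size — convenient for checking that recommendations grow with
    patient habitus.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    means = np.linspace(*d_mean_range, n)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        generate_patient(
            int(s), d_mean=float(m), d_sd=d_sd, taper_cm=taper_cm, **patient_kwargs
        )
        for s, m in zip(seeds, means)
    ]
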