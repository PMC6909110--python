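"""Reading and writing the package's tabular and JSON formats.

Family tables are CSV (or a JSON mirror) with columns
``name,sfov,focal_spot,collimation_mm,rotation_time_s,pitch,ctdi_min,
ctdi_max[,ma_grid,dose_coeff]``; ``ma_grid`` is semicolon-separated.
Profiles are JSON with members serialized primary-first.  Patients are
two-column CSV (``z_cm,d_cm``); cohort specs are small YAML mappings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml

from .aec import PatientModel
from .builder import GsiProfile, ProfileMember, Role
from .fixtures import generate_cohort
from .presets import FocalSpot, PresetFamily

__all__ = [
    "families_to_frame",
    "families_to_csv",
    "families_from_csv",
    "families_to_json",
    "families_from_json",
    "profile_to_json",
    "profile_from_json",
    "patient_to_csv",
    "patient_from_csv",
    "cohort_from_yaml",
]

_FAMILY_COLUMNS = [
    "name",
    "sfov",
    "focal_spot",
    "collimation_mm",
    "rotation_time_s",
    "pitch",
    "ctdi_min",
    "ctdi_max",
    "ma_grid",
    "dose_coeff",
]


def _family_record(f: PresetFamily) -> dict[str, Any]:
    return {
        "name": f.name,
        "sfov": f.sfov,
        "focal_spot": f.focal_spot.value,
        "collimation_mm": f.collimation_mm,
        "rotation_time_s": f.rotation_time_s,
        "pitch": f.pitch,
        "ctdi_min": f.ctdi_min,
        "ctdi_max": f.ctdi_max,
        "ma_grid": ";".join(f"{m:g}" for m in f.ma_grid) if f.ma_grid else None,
        "dose_coeff": f.dose_coeff,
    }


def _family_from_record(rec: dict[str, Any]) -> PresetFamily:
    def _opt(v):
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return v

    ma_raw = _opt(rec.get("ma_grid"))
    ma_grid = None
    if ma_raw is not None:
        if isinstance(ma_raw, str):
            ma_grid = tuple(float(x) for x in ma_raw.split(";") if x.strip())
        else:
            ma_grid = tuple(float(x) for x in ma_raw)
    return PresetFamily(
        name=str(rec["name"]),
        sfov=str(rec["sfov"]),
        focal_spot=FocalSpot(rec["focal_spot"]),
        collimation_mm=float(rec["collimation_mm"]),
        rotation_time_s=float(rec["rotation_time_s"]),
        pitch=float(rec["pitch"]),
        ctdi_min=_opt(rec.get("ctdi_min")),
        ctdi_max=_opt(rec.get("ctdi_max")),
        ma_grid=ma_grid,
        dose_coeff=_opt(rec.get("dose_coeff")),
    )


def families_to_frame(families: list[PresetFamily]) -> pd.DataFrame:
    return pd.DataFrame([_family_record(f) for f in families], columns=_FAMILY_COLUMNS)


def families_to_csv(families: list[PresetFamily], path: Union[str, Path]) -> None:
    df = families_to_frame(families)
    # repr round-trips float64 exactly; pandas' default float formatting does not
    df["dose_coeff"] = df["dose_coeff"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    df.to_csv(path, index=False)


def families_from_csv(path: Union[str, Path]) -> list[PresetFamily]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"name", "sfov", "focal_spot", "collimation_mm", "rotation_time_s", "pitch"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        try:
            out.append(_family_from_record(rec))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def families_to_json(families: list[PresetFamily], path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps({"families": [_family_record(f) for f in families]}, indent=2) + "\n"
    )


def families_from_json(path: Union[str, Path]) -> list[PresetFamily]:
    data = json.loads(Path(path).read_text())
    return [_family_from_record(rec) for rec in data["families"]]


def profile_to_json(
    profile: GsiProfile, path: Optional[Union[str, Path]] = None, **extra: Any
) -> dict[str, Any]:
    """Serialize a profile (primary member first).  ``extra`` keys (seed,
    provenance) are recorded alongside."""
    doc = {
        "name": profile.name,
        "primary_role": profile.primary_role.value,
        "members": [
            {"role": m.role.value, "family": _family_record(m.family)}
            for m in profile.members_serialized()
        ],
        **extra,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")
    return doc


def profile_from_json(path: Union[str, Path]) -> GsiProfile:
    data = json.loads(Path(path).read_text())
    members = [
        ProfileMember(role=Role(m["role"]), family=_family_from_record(m["family"]))
        for m in data["members"]
    ]
    members.sort(key=lambda m: list(Role).index(m.role))
    return GsiProfile(
        name=data["name"],
        members=tuple(members),
        primary_role=Role(data["primary_role"]),
    )


def patient_to_csv(patient: PatientModel, path: Union[str, Path]) -> None:
    pd.DataFrame({"z_cm": patient.z, "d_cm": patient.d}).to_csv(path, index=False)


def patient_from_csv(path: Union[str, Path], **patient_kwargs: Any) -> PatientModel:
    df = pd.read_csv(path)
    if not {"z_cm", "d_cm"} <= set(df.columns):
        raise ValueError(f"{path}: patient CSV needs columns z_cm,d_cm")
    return PatientModel(
        z=tuple(df["z_cm"].astype(float)), d=tuple(df["d_cm"].astype(float)), **patient_kwargs
    )


def cohort_from_yaml(path: Union[str, Path]) -> list[PatientModel]:
    """Generate a patient cohort from a YAML spec.

    Keys: ``n``, ``seed``, ``d_mean_min``, ``d_mean_max``, ``d_sd``,
    ``taper_cm`` (all optional except n and seed).
    """
    spec = yaml.safe_load(Path(path).read_text())
    if not isinstance(spec, dict) or "n" not in spec or "seed" not in spec:
        raise ValueError(f"{path}: cohort spec needs at least 'n' and 'seed'")
    return generate_cohort(
        seed=int(spec["seed"]),
        n=int(spec["n"]),
        d_mean_range=(
            float(spec.get("d_mean_min", 18.0)),
            float(spec.get("d_mean_max", 42.0)),
        ),
        d_sd=float(spec.get("d_sd", 0.5)),
        taper_cm=float(spec.get("taper_cm", 3.0)),
    )
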