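"""Independent brute-force oracles, deliberately written from scratch.

These re-read the selection procedure clause by clause and share no
code with the library implementation, so agreement between the two is
a meaningful check rather than a tautology.
"""

from __future__ import annotations

from gsiprofile import PresetFamily, ProfileConstraints, ctdi_for_ma


def nearest_by_scan(values, target):
    """Linear scan for the closest value; on a tie keep the lower one."""
    best = values[0]
    for v in values[1:]:
        dv, db = abs(v - target), abs(best - target)
        if dv < db or (dv == db and v < best):
            best = v
    return best


def _rng_min(f: PresetFamily) -> float:
    if f.ctdi_min is not None:
        return f.ctdi_min
    return ctdi_for_ma(f, f.ma_grid[0])


def _rng_max(f: PresetFamily) -> float:
    if f.ctdi_max is not None:
        return f.ctdi_max
    return ctdi_for_ma(f, f.ma_grid[-1])


def _row_ok(f: PresetFamily, c: ProfileConstraints) -> bool:
    if f.sfov != c.sfov or f.collimation_mm != c.collimation_mm:
        return False
    if c.pitch_max is not None and f.pitch > c.pitch_max:
        return False
    if c.pitch_min is not None and f.pitch < c.pitch_min:
        return False
    if c.rot_min is not None and f.rotation_time_s < c.rot_min:
        return False
    if c.rot_max is not None and f.rotation_time_s > c.rot_max:
        return False
    if f.focal_spot.value == "XLarge" and not c.allow_xlarge:
        return False
    return True


def table_order(families):
    """Rows listed in order of increasing minimum CTDIvol (stable; ties by max)."""
    indexed = list(enumerate(families))
    indexed.sort(key=lambda t: (_rng_min(t[1]), _rng_max(t[1]), t[0]))
    return [f for _i, f in indexed]


def greedy_selection(families, c: ProfileConstraints):
    """Literal re-reading of the four selection steps.

    Returns the collapsed ordered list of (role, family):
    - small:  FIRST matching row of the table;
    - medium: LAST matching large-focal row with min < small's max;
    - large:  LAST matching large-focal row with min < medium's max;
    - xlarge: matching row with the HIGHEST max (ties: lower min, table order);
    duplicate picks (or failed searches) merge into the earlier role.
    """
    rows = [f for f in table_order(families) if _row_ok(f, c)]
    if not rows:
        return None

    small = rows[0]

    medium = None
    for f in rows:
        if f.focal_spot.value == "Large" and _rng_min(f) < _rng_max(small):
            medium = f
    med_anchor = medium if medium is not None else small

    large = None
    for f in rows:
        if f.focal_spot.value == "Large" and _rng_min(f) < _rng_max(med_anchor):
            large = f

    xlarge = rows[0]
    for f in rows[1:]:
        if _rng_max(f) > _rng_max(xlarge) or (
            _rng_max(f) == _rng_max(xlarge) and _rng_min(f) < _rng_min(xlarge)
        ):
            xlarge = f

    out = []
    for role, fam in (("small", small), ("medium", medium), ("large", large), ("xlarge", xlarge)):
        if fam is None:
            continue
        if any(fam == kept for _r, kept in out):
            continue
        out.append((role, fam))
    return out
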