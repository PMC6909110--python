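"""Dose-ladder and coverage figures.

The ladder view draws one horizontal bar per preset family on a
logarithmic dose axis (the primary family on top), optionally with the
|f| fractional-mismatch curve in a second panel; the comparison view
places several profiles' total ranges side by side.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; callers only save to file
import matplotlib.pyplot as plt
import numpy as np

from .builder import GsiProfile
from .coverage import DoseMatchReport

__all__ = ["render_ladder", "render_profile_comparison", "ladder_text"]


def render_ladder(
    profile: GsiProfile,
    report: Optional[DoseMatchReport] = None,
    n_grid: int = 20,
) -> plt.Figure:
    """One row per family on a log-dose axis; |f| panel when a report is given."""
    from .presets import ctdi_grid

    n_panels = 2 if report is not None else 1
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(7, 2 + 1.5 * n_panels), sharex=True, squeeze=False
    )
    ax = axes[0][0]
    members = profile.members_serialized()
    for i, m in enumerate(members):
        y = len(members) - 1 - i  # primary on top
        grid = ctdi_grid(m.family, n_grid=n_grid).as_array()
        ax.hlines(y, grid[0], grid[-1], lw=6, alpha=0.4)
        ax.plot(grid, np.full_like(grid, y), "|", ms=10)
        label = f"{m.role.value}" + (" (primary)" if i == 0 else "")
        ax.annotate(
            f"{label}: {m.family.settings_label()}",
            (grid[0], y + 0.18),
            fontsize=8,
        )
    ax.set_xscale("log")
    ax.set_yticks([])
    ax.set_ylim(-0.6, len(members) - 0.2)
    ax.set_title(f"Achievable CTDIvol — profile {profile.name!r}")
    if report is not None:
        ax2 = axes[1][0]
        ax2.plot(report.targets, np.abs(report.f_values), lw=1)
        ax2.axhline(report.tolerance, ls="--", lw=0.8, color="gray")
        ax2.set_ylabel("|f|")
        ax2.set_xlabel("target CTDIvol (mGy)")
    else:
        ax.set_xlabel("CTDIvol (mGy)")
    fig.tight_layout()
    return fig


def render_profile_comparison(profiles: Sequence[GsiProfile]) -> plt.Figure:
    """Total achievable dose ranges of several profiles, side by side."""
    fig, ax = plt.subplots(figsize=(7, 1 + 0.5 * len(profiles)))
    for i, p in enumerate(profiles):
        y = len(profiles) - 1 - i
        lo = min(f.dose_min for f in p.families)
        hi = max(f.dose_max for f in p.families)
        ax.hlines(y, lo, hi, lw=8, alpha=0.5)
        ax.annotate(f"{p.name}  ({lo:.1f}–{hi:.1f} mGy)", (lo, y + 0.25), fontsize=8)
    ax.set_xscale("log")
    ax.set_yticks([])
    ax.set_ylim(-0.6, len(profiles) - 0.1)
    ax.set_xlabel("CTDIvol (mGy)")
    ax.set_title("Achievable dose range by profile")
    fig.tight_layout()
    return fig


def ladder_text(profile: GsiProfile) -> str:
    """Plain-text dose ladder (primary first), one-decimal mGy."""
    lines = [f"profile {profile.name!r} (primary: {profile.primary_role.value})"]
    for i, m in enumerate(profile.members_serialized()):
        tag = "*" if i == 0 else " "
        lines.append(
            f" {tag} {m.role.value:<7s} {m.family.settings_label():<38s} "
            f"{m.family.dose_min:5.1f} – {m.family.dose_max:5.1f} mGy"
        )
    return "\n".join(lines)
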