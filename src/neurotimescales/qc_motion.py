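"""Framewise displacement and head-motion exclusion.

FD follows the Power-style definition: the sum of absolute backward
differences of the three translations (mm) plus the rotation radius (50 mm
by default) times the sum of absolute backward differences of the three
rotations (radians).  The exclusion rule reads "head motion > threshold"
as peak absolute translation over the run exceeding the threshold (10 mm
default); a peak-FD variant is available via ``metric``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "MotionTrace",
    "exclusion_flags",
    "framewise_displacement",
    "read_motion_file",
]


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body motion parameters: T x 3 translations (mm) and T x 3
    rotations (radians), one row per volume."""

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.translations, dtype=float))
        r = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)
        if t.shape != r.shape or t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("translations and rotations must both be T x 3")
        if t.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 frames")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


def framewise_displacement(
    trace: MotionTrace, rotation_radius_mm: float = 50.0
) -> np.ndarray:
    """Per-frame FD (length T - 1, all values >= 0):

        FD_t = sum_axis |d translation_t| + R * sum_axis |d rotation_t|

    where rotations are converted to arc length on a sphere of radius
    ``rotation_radius_mm``.
    """
    dt = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1)
    return dt + rotation_radius_mm * dr


def exclusion_flags(
    trace: MotionTrace,
    threshold_mm: float = 10.0,
    rotation_radius_mm: float = 50.0,
    metric: str = "peak_translation",
) -> tuple:
    """Apply the head-motion exclusion rule and summarize FD.

    Returns ``(excluded, mean_fd)``: the subject is flagged when the chosen
    motion metric exceeds ``threshold_mm``.  ``metric`` is either
    ``"peak_translation"`` (max |translation| over frames and axes, the
    default reading of a "head motion > 10 mm" rule) or ``"peak_fd"``.
    """
    fd = framewise_displacement(trace, rotation_radius_mm)
    if metric == "peak_translation":
        peak = float(np.abs(trace.translations).max())
    elif metric == "peak_fd":
        peak = float(fd.max())
    else:
        raise ValueError(f"unknown exclusion metric {metric!r}")
    return peak > threshold_mm, float(fd.mean())


def read_motion_file(
    path: Union[str, Path],
    translations_first: bool = True,
    rotations_in_degrees: bool = False,
) -> MotionTrace:
    """Read a whitespace/tab-delimited 6-column motion parameter file
    (one row per volume).  Column order and rotation unit are configurable;
    the default is translations in columns 1-3 (mm) then rotations in
    columns 4-6 (radians)."""
    data = np.loadtxt(str(path), ndmin=2)
    if data.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {data.shape[1]}")
    if translations_first:
        t, r = data[:, :3], data[:, 3:]
    else:
        r, t = data[:, :3], data[:, 3:]
    if rotations_in_degrees:
        r = np.deg2rad(r)
    return MotionTrace(translations=t, rotations=r)
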