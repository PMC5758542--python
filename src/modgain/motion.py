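"""Head-motion quality control for resting-state scans.

Framewise displacement (FD) follows the Power convention: the L1 norm of
the backward differences of the six rigid-body realignment parameters,
with the three rotations converted from radians to millimetres of arc on
a sphere of radius 50 mm (the approximate mean distance from cerebral
cortex to the centre of the head). FD of the first frame is 0.

Subjects are excluded — not individual frames — when strictly more than
``pct_thresh`` percent of volumes exceed ``fd_thresh`` mm of FD, or when
any volume's absolute displacement from the reference (first) volume
exceeds ``max_disp_thresh`` mm. Both comparisons are strict, so a scan
sitting exactly on a boundary is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "MotionSummary",
    "framewise_displacement",
    "max_absolute_displacement",
    "apply_exclusion",
    "motion_summary",
    "read_motion",
    "write_motion",
]

FD_SPHERE_RADIUS_MM = 50.0


@dataclass(frozen=True)
class MotionTrace:
    """Six rigid-body parameters per volume: translations (mm), rotations (radians)."""

    translations: np.ndarray  # (n_volumes, 3), mm
    rotations: np.ndarray     # (n_volumes, 3), radians

    def __post_init__(self) -> None:
        t = np.asarray(self.translations, dtype=float)
        r = np.asarray(self.rotations, dtype=float)
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)
        if t.ndim != 2 or t.shape[1] != 3 or r.shape != t.shape:
            raise ValueError("expect (n_volumes, 3) translations and rotations")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass(frozen=True)
class MotionSummary:
    fd_series: np.ndarray
    mean_fd: float
    pct_high_fd: float
    max_abs_disp: float
    excluded: bool
    reason: str


def framewise_displacement(mt: MotionTrace,
                           radius_mm: float = FD_SPHERE_RADIUS_MM) -> np.ndarray:
    """Per-frame FD (mm): sum of |Δtranslation| plus |radius * Δrotation|."""
    if mt.n_volumes < 2:
        raise ValueError("FD needs at least 2 volumes")
    dt = np.abs(np.diff(mt.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(mt.rotations, axis=0)).sum(axis=1) * radius_mm
    return np.concatenate([[0.0], dt + dr])


def max_absolute_displacement(mt: MotionTrace) -> float:
    """Largest absolute translation (mm) relative to the first (reference) volume."""
    rel = mt.translations - mt.translations[0]
    return float(np.max(np.abs(rel)))


def apply_exclusion(fd_series: np.ndarray, max_abs_disp: float, n_volumes: int,
                    fd_thresh: float = 0.5, pct_thresh: float = 10.0,
                    max_disp_thresh: float = 4.0) -> MotionSummary:
    """Decide subject exclusion from an FD series and peak displacement.

    Excluded iff strictly more than ``pct_thresh`` % of volumes have
    FD > ``fd_thresh``, or ``max_abs_disp`` > ``max_disp_thresh``.
    """
    fd_series = np.asarray(fd_series, dtype=float)
    if fd_series.size != n_volumes:
        raise ValueError("FD series length must equal n_volumes")
    n_high = int(np.sum(fd_series > fd_thresh))
    pct_high = 100.0 * n_high / n_volumes
    reasons = []
    if pct_high > pct_thresh:
        reasons.append(
            f"{n_high}/{n_volumes} volumes ({pct_high:.2f}%) with FD > {fd_thresh} mm"
        )
    if max_abs_disp > max_disp_thresh:
        reasons.append(f"max absolute displacement {max_abs_disp:.2f} mm > {max_disp_thresh} mm")
    return MotionSummary(
        fd_series=fd_series,
        mean_fd=float(fd_series.mean()),
        pct_high_fd=pct_high,
        max_abs_disp=float(max_abs_disp),
        excluded=bool(reasons),
        reason="; ".join(reasons) if reasons else "retained",
    )


def motion_summary(mt: MotionTrace, fd_thresh: float = 0.5,
                   pct_thresh: float = 10.0,
                   max_disp_thresh: float = 4.0) -> MotionSummary:
    """FD computation plus exclusion decision for one subject's trace."""
    fd = framewise_displacement(mt)
    return apply_exclusion(fd, max_absolute_displacement(mt), mt.n_volumes,
                           fd_thresh=fd_thresh, pct_thresh=pct_thresh,
                           max_disp_thresh=max_disp_thresh)


def read_motion(path: str | Path, rotation_units: str,
                order: str = "translations_first") -> MotionTrace:
    """Read a 6-column whitespace-delimited realignment file.

    ``rotation_units`` must be declared explicitly (``"radians"`` or
    ``"degrees"``) — realignment packages disagree and a silent guess
    corrupts FD. ``order`` selects the column dialect
    (``translations_first`` or ``rotations_first``).
    """
    if rotation_units not in ("radians", "degrees"):
        raise ValueError("rotation_units must be 'radians' or 'degrees'")
    if order not in ("translations_first", "rotations_first"):
        raise ValueError("order must be 'translations_first' or 'rotations_first'")
    with open(path) as fh:
        first = fh.readline()
    header = 0 if any(ch.isalpha() for ch in first) else None
    arr = pd.read_csv(path, sep=r"\s+", header=header, comment="#").to_numpy(dtype=float)
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, found {arr.shape[1]}")
    if order == "translations_first":
        trans, rot = arr[:, :3], arr[:, 3:]
    else:
        rot, trans = arr[:, :3], arr[:, 3:]
    if rotation_units == "degrees":
        rot = np.deg2rad(rot)
    return MotionTrace(translations=trans, rotations=rot)


def write_motion(mt: MotionTrace, path: str | Path) -> None:
    """Write translations-first, radians, tab-delimited with a header row."""
    df = pd.DataFrame(
        np.hstack([mt.translations, mt.rotations]),
        columns=["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
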