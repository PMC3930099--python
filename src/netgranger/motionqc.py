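"""Head-motion quality control from realignment parameters.

Four per-subject metrics summarise the 6-parameter rigid-body realignment
series: mean motion (mean volume-to-volume displacement), maximum motion,
number of movements (volumes whose displacement exceeds a 0.1 mm
threshold, bounded by n - 1), and rotation (per-step Euler angle, the
single-angle summary of the 3-D rotation between consecutive volumes).
Group differences are assessed with bootstrap T-tests on the mean
difference, Bonferroni-corrected to alpha = .0125 across the four metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RealignmentSeries",
    "MotionSummary",
    "displacement_series",
    "euler_angle",
    "motion_summary",
    "bootstrap_group_ttest",
]

MOVEMENT_THRESHOLD_MM = 0.1
MOTION_ALPHA = 0.0125  # .05 Bonferroni-corrected for the four metrics


@dataclass(frozen=True)
class RealignmentSeries:
    """T x 3 translations (mm) and T x 3 rotations (radians about x, y, z)."""

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.translations, dtype=float)
        r = np.asarray(self.rotations, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3 or r.shape != t.shape:
            raise ValueError("translations and rotations must both be (T, 3)")
        if t.shape[0] < 2:
            raise ValueError("need at least 2 volumes")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("realignment parameters must be finite")
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)

    @classmethod
    def from_array(cls, params: np.ndarray) -> "RealignmentSeries":
        """From a (T, 6) array laid out x, y, z translations then rotations."""
        params = np.asarray(params, dtype=float)
        if params.ndim != 2 or params.shape[1] != 6:
            raise ValueError("expected a (T, 6) realignment array")
        return cls(params[:, :3], params[:, 3:])

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass(frozen=True)
class MotionSummary:
    mean_motion: float  # mm
    max_motion: float  # mm
    n_movements: int  # in [0, n_volumes - 1]
    rotation: float  # radians


def displacement_series(
    series: RealignmentSeries, mode: str = "rms"
) -> np.ndarray:
    """Volume-to-volume displacement, one value per step (length T - 1).

    ``mode="rms"`` (default) takes the root mean square of the three axis
    deltas, i.e. ``sqrt((dx^2 + dy^2 + dz^2) / 3)``; ``mode="euclidean"``
    gives the Euclidean step length ``sqrt(dx^2 + dy^2 + dz^2)``.
    """
    deltas = np.diff(series.translations, axis=0)
    ss = np.sum(deltas**2, axis=1)
    if mode == "rms":
        return np.sqrt(ss / 3.0)
    if mode == "euclidean":
        return np.sqrt(ss)
    raise ValueError(f"unknown displacement mode {mode!r}")


def euler_angle(phi: float, theta: float, psi: float) -> float:
    """Single Euler rotation angle from rotations about x, y and z (radians).

    Computed as arccos((cos(phi)cos(theta) + cos(phi)cos(psi)
    + cos(theta)cos(psi) + sin(phi)sin(psi)sin(theta) - 1) / 2); the
    arccos argument is clipped to [-1, 1] so rounding error near the
    identity rotation cannot raise.  Result lies in [0, pi].
    """
    phi, theta, psi = np.broadcast_arrays(phi, theta, psi)
    arg = (
        np.cos(phi) * np.cos(theta)
        + np.cos(phi) * np.cos(psi)
        + np.cos(theta) * np.cos(psi)
        + np.sin(phi) * np.sin(psi) * np.sin(theta)
        - 1.0
    ) / 2.0
    out = np.arccos(np.clip(arg, -1.0, 1.0))
    return float(out) if out.ndim == 0 else out


def motion_summary(
    series: RealignmentSeries,
    movement_threshold: float = MOVEMENT_THRESHOLD_MM,
    rotation_reduction: str = "mean",
    displacement_mode: str = "rms",
) -> MotionSummary:
    """The four per-subject motion metrics.

    The per-step rotation is the Euler angle of the rotation-parameter
    differences between consecutive volumes; the per-subject "rotation"
    value reduces these with ``rotation_reduction`` ("mean" or "max").
    ``n_movements`` counts steps with displacement strictly above the
    threshold (default 0.1 mm).
    """
    disp = displacement_series(series, mode=displacement_mode)
    rot_deltas = np.diff(series.rotations, axis=0)
    angles = euler_angle(rot_deltas[:, 0], rot_deltas[:, 1], rot_deltas[:, 2])
    if rotation_reduction == "mean":
        rot = float(np.mean(angles))
    elif rotation_reduction == "max":
        rot = float(np.max(angles))
    else:
        raise ValueError(f"unknown rotation reduction {rotation_reduction!r}")
    return MotionSummary(
        mean_motion=float(np.mean(disp)),
        max_motion=float(np.max(disp)),
        n_movements=int(np.sum(disp > movement_threshold)),
        rotation=rot,
    )


def bootstrap_group_ttest(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Two-sided bootstrap p-value for a between-group mean difference.

    Subjects are resampled with replacement within each group ``n_boot``
    times; the p-value is twice the smaller tail of the bootstrap
    mean-difference distribution around zero (its percentile position).
    A degenerate (zero-variance) bootstrap distribution is flagged with a
    warning.  Compare against alpha = .0125 when testing the four motion
    metrics jointly.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    if np.ptp(diffs) == 0.0:
        warnings.warn(
            "degenerate bootstrap distribution (zero variance)", stacklevel=2
        )
    lower = np.mean(diffs <= 0.0)
    upper = np.mean(diffs >= 0.0)
    return float(min(1.0, 2.0 * min(lower, upper)))
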