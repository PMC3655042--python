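"""Dynamic-PET VOI quantification: frame handling, sphere masks, organ TACs.

Small-animal PET reports each frame's mean concentration (Bq/ml) decay
corrected to the frame start.  Residence-time integration needs the physical
(non-decay-corrected) activity, so this module undoes the frame-start
correction and additionally accounts for decay *within* a frame (a counted
frame measures the time-average of a decaying signal):

    true_mean = corrected * exp(-lambda*t_start) * (1 - exp(-lambda*dt)) / (lambda*dt)

timestamped at the frame midpoint.  Mean VOI concentration times organ volume
over injected activity gives whole-organ FIA.  Two VOI strategies are
supported: whole-organ masks, and small spheres centred in the organ (used to
limit partial-volume bias; the organ volume then comes from the standard
animal scaled to the scanned animal's body weight, or a CT-derived override).
No partial-volume or spill-over correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .nuclides import Radionuclide, decay_factor


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-frame timing, in seconds."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.shape != dur.shape or start.ndim != 1:
            raise ValueError("start and duration arrays must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_spec(cls, spec: list[tuple[int, float]]) -> "FrameSchedule":
        """Build from (count, duration_s) blocks, e.g. [(6, 5), (6, 10), ...]."""
        durations = np.concatenate([np.full(n, d, dtype=float) for n, d in spec])
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @property
    def midpoints_h(self) -> np.ndarray:
        return (self.start_s + 0.5 * self.duration_s) / 3600.0

    @property
    def n_frames(self) -> int:
        return self.start_s.size


#: 120-min small-animal acquisition schedule used throughout the examples.
DEFAULT_SCHEDULE = FrameSchedule.from_spec(
    [(6, 5), (6, 10), (3, 20), (5, 30), (5, 60), (8, 150), (6, 300), (6, 600)]
)


@dataclass
class DynamicImageSeries:
    """4-D voxel concentrations (x, y, z, frame) in Bq/ml with frame timing."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    decay_corrected_to_frame_start: bool = True

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4:
            raise ValueError("voxel array must be 4-D (x, y, z, frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis inconsistent with schedule")
        if np.any(self.voxels < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0


@dataclass
class VOIMask:
    """Boolean voxel mask with its quantification strategy."""

    mask: np.ndarray
    label: str
    strategy: Literal["whole_organ", "sphere"] = "whole_organ"
    sphere_center_mm: tuple[float, float, float] | None = None
    sphere_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")
        if not self.mask.any():
            raise ValueError(f"VOI mask {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def make_sphere_mask(
    center_mm: tuple[float, float, float],
    radius_mm: float,
    shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    label: str = "sphere",
) -> VOIMask:
    """Sphere VOI: voxels whose centres lie within ``radius_mm`` of the centre.

    Voxel centres sit at (index + 0.5) * voxel size.  Raises if the sphere
    captures no voxel centre.
    """
    if not radius_mm > 0:
        raise ValueError("radius must be positive")
    coords = [
        (np.arange(n) + 0.5) * d for n, d in zip(shape, voxel_size_mm, strict=True)
    ]
    for c, ax in zip(center_mm, coords, strict=True):
        if not ax[0] - 0.5 <= c <= ax[-1] + 0.5:
            raise ValueError(f"sphere center {center_mm} outside the voxel grid")
    x, y, z = np.meshgrid(*coords, indexing="ij")
    r2 = (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2
    mask = r2 <= radius_mm**2
    if not mask.any():
        raise ValueError("sphere contains no voxel centres; increase the radius")
    return VOIMask(mask, label, "sphere", tuple(center_mm), radius_mm)


def uncorrect_frames(
    frame_values: np.ndarray, schedule: FrameSchedule, nuclide: Radionuclide,
    decay_corrected: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Physical frame-average values at frame midpoints.

    ``frame_values`` are per-frame means decay corrected to each frame start.
    Returns (midpoint times in hours, true mean values).  If the values are
    flagged as not corrected they pass through unchanged, with a warning.
    """
    values = np.asarray(frame_values, dtype=float)
    if values.shape[-1] != schedule.n_frames:
        raise ValueError("frame values inconsistent with schedule")
    times_h = schedule.midpoints_h
    if not decay_corrected:
        warnings.warn("values not decay corrected; passing through", stacklevel=2)
        return times_h, values
    lam = nuclide.decay_constant
    start_h = schedule.start_s / 3600.0
    dt_h = schedule.duration_s / 3600.0
    x = lam * dt_h
    in_frame = np.where(x > 1e-12, -np.expm1(-x) / x, 1.0)
    return times_h, values * decay_factor(nuclide, start_h) * in_frame


def organ_tac_from_voi(
    series: DynamicImageSeries,
    voi: VOIMask,
    injected_bq: float,
    nuclide: Radionuclide,
    organ_volume_ml: float | None = None,
) -> list[tuple[float, float]]:
    """Whole-organ FIA samples from a VOI time series.

    For whole-organ masks the organ volume defaults to the mask volume; for
    sphere VOIs an explicit organ volume is required (standard-animal volume
    scaled to the scanned body weight, or a CT-derived value).
    """
    if not injected_bq > 0:
        raise ValueError("injected activity must be positive")
    if organ_volume_ml is None:
        if voi.strategy == "sphere":
            raise ValueError("sphere VOIs need an explicit organ volume")
        organ_volume_ml = voi.n_voxels * series.voxel_volume_ml
    if not organ_volume_ml > 0:
        raise ValueError("organ volume must be positive")
    means = series.voxels[voi.mask].mean(axis=0)
    times_h, true_means = uncorrect_frames(
        means, series.schedule, nuclide, series.decay_corrected_to_frame_start
    )
    fia = true_means * organ_volume_ml / injected_bq
    return list(zip(times_h.tolist(), fia.tolist()))
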