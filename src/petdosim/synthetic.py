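"""Synthetic mouse-study generator: ground-truth kinetics, noisy
organ-harvesting tables, and blurred dynamic voxel phantoms.

Every pipeline stage is testable offline against this module.  The true
whole-organ activity is a sum of exponentials modulated by physical decay,

    FIA_organ(t) = exp(-lambda_p t) * sum_i A_i exp(-k_i t)

with amplitudes chosen so the organs plus urinary excretion never exceed the
injected activity.  The default kinetics emulate a tracer with liver-dominant
early uptake, renal and hepatobiliary clearance, and an excreted urinary
fraction of 0.5 with a 3 h biological half-life; they are representative
values, not measurements.  Fast vascular components are confined to the first
half hour where the sampling design (2, 5, 10, 30, 60, 120 min) is dense.

Two ground-truth residence-time conventions are provided.
``true_residence_time`` integrates the analytic curve itself (with biological
clearance frozen after the last design time, the study's trapped-activity
assumption).  ``design_residence_time`` integrates, in closed form, the
piecewise-linear curve through the noiseless design samples — what an ideal
analysis of the design can recover; the difference between the two is the
sampling-design interpolation bias, not implementation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .biodist import BiodistributionTable
from .nuclides import F18, Radionuclide, decay_factor
from .petquant import DEFAULT_SCHEDULE, DynamicImageSeries, FrameSchedule, VOIMask
from .scaling import StandardAnimal, default_standard_mouse

#: Default biological kinetics: organ -> (amplitudes, rates per hour).
DEFAULT_KINETICS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "liver": ((0.12, 0.13), (2.5, 0.25)),
    "brain": ((0.035, 0.045), (1.5, 0.08)),
    "kidneys": ((0.05, 0.02), (3.5, 0.45)),
    "heart": ((0.02, 0.006), (4.0, 0.30)),
    "lung": ((0.025, 0.012), (3.5, 0.30)),
    "spleen": ((0.006, 0.004), (2.5, 0.25)),
    "testes": ((0.0015, 0.001), (1.0, 0.15)),
    "blood": ((0.06, 0.02), (5.0, 0.35)),
    "bone": ((0.015, 0.01), (1.0, 0.1)),
    "intestine": ((0.02, 0.015), (1.5, 0.2)),
    "pancreas": ((0.008, 0.004), (2.0, 0.2)),
    "adrenals": ((0.002, 0.001), (2.0, 0.2)),
    "skin": ((0.02, 0.015), (1.0, 0.15)),
    "muscle": ((0.05, 0.03), (1.5, 0.2)),
    "stomach": ((0.01, 0.006), (1.5, 0.2)),
}


@dataclass
class OrganKineticsSpec:
    """Ground-truth study kinetics: per-organ exponentials plus excretion."""

    kinetics: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    standard_animal: StandardAnimal = field(default_factory=default_standard_mouse)
    urinary_fraction: float = 0.5
    urinary_half_life_h: float = 3.0
    body_weight_g: float = 35.0
    nuclide: Radionuclide = F18

    def __post_init__(self) -> None:
        if not 0.0 <= self.urinary_fraction <= 1.0:
            raise ValueError("urinary fraction must be in [0, 1]")
        for organ, (amps, rates) in self.kinetics.items():
            if len(amps) != len(rates):
                raise ValueError(f"amplitude/rate length mismatch for {organ}")
            if any(a < 0 for a in amps) or any(k < 0 for k in rates):
                raise ValueError(f"negative amplitude or rate for {organ}")
        total0 = sum(sum(a) for a, _ in self.kinetics.values())
        if total0 + 0.0 > 1.0:  # urine is empty at t=0
            raise ValueError(f"organ amplitudes sum to {total0:.3f} > 1 at t=0")

    def organ_mass_g(self, organ: str) -> float:
        """Organ mass for this animal (standard fraction times body weight)."""
        return self.standard_animal.organ_fraction(organ) * self.body_weight_g


def true_fia(spec: OrganKineticsSpec, organ: str, t_h):
    """True whole-organ FIA at time ``t_h`` (physical decay included)."""
    amps, rates = spec.kinetics[organ]
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    bio = sum(a * np.exp(-k * t) for a, k in zip(amps, rates))
    out = decay_factor(spec.nuclide, t) * bio
    return float(out) if np.ndim(t_h) == 0 else out


def true_residence_time(
    spec: OrganKineticsSpec,
    organ: str,
    horizon_h: float = 10.0,
    trapped_after_h: float | None = 2.0,
) -> float:
    """Analytic residence time of the true curve, in hours.

    With ``trapped_after_h`` = T the biological state is frozen at T and only
    physical decay continues to the horizon (the trapped-activity assumption
    applied to the truth); ``None`` lets clearance continue analytically.
    """
    amps, rates = spec.kinetics[organ]
    lam = spec.nuclide.decay_constant
    if trapped_after_h is None or trapped_after_h >= horizon_h:
        T = horizon_h
        tail = 0.0
    else:
        T = trapped_after_h
        bio_T = sum(a * math.exp(-k * T) for a, k in zip(amps, rates))
        tail = (
            math.exp(-lam * T) * bio_T * (1.0 - math.exp(-lam * (horizon_h - T))) / lam
        )
    head = sum(
        a * (1.0 - math.exp(-(lam + k) * T)) / (lam + k) for a, k in zip(amps, rates)
    )
    return head + tail


def design_residence_time(
    spec: OrganKineticsSpec,
    organ: str,
    design_times_h,
    horizon_h: float = 10.0,
) -> float:
    """Closed-form residence time of the design-sampled piecewise-linear curve.

    Exact trapezoid over the noiseless samples (first value held constant back
    to t=0) plus the exact physical-decay integral after the last sample up to
    the horizon.  Independent oracle for the end-to-end numerics of the
    ingestion -> TAC -> integration chain.
    """
    t = np.sort(np.asarray(design_times_h, dtype=float))
    v = true_fia(spec, organ, t)
    lam = spec.nuclide.decay_constant
    head = v[0] * t[0] + float(np.trapezoid(v, t))
    tail = v[-1] * (1.0 - math.exp(-lam * (horizon_h - t[-1]))) / lam
    return head + tail


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of an organ-harvesting study."""

    time_points_min: tuple[float, ...] = (2.0, 5.0, 10.0, 30.0, 60.0, 120.0)
    animals_per_point: int = 4
    measurement_cv: float = 0.05
    mass_cv: float = 0.05
    injected_activity_bq: float = 6.96e6
    counting_delay_min: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_point < 1:
            raise ValueError("need at least one animal per time point")
        if self.measurement_cv < 0 or self.mass_cv < 0:
            raise ValueError("CVs must be non-negative")


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def sample_td_study(spec: OrganKineticsSpec, design: StudyDesign) -> BiodistributionTable:
    """Simulate a tissue-distribution study as a validated table.

    Each animal contributes one whole-organ sample per organ with a standard
    animal mass: measured activity is the true organ activity at sacrifice,
    decayed over the counting delay, with multiplicative lognormal counting
    noise; sample masses get independent lognormal scatter.  Organs without a
    standard-animal mass use a nominal 1 g sample (per-gram-only tissues).
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(design.seed)
    delay_h = design.counting_delay_min / 60.0
    delay_decay = decay_factor(spec.nuclide, delay_h)
    rows = []
    animal = 0
    for t_min in design.time_points_min:
        t_h = t_min / 60.0
        for _ in range(design.animals_per_point):
            animal += 1
            for organ in spec.kinetics:
                try:
                    mass = spec.organ_mass_g(organ)
                except KeyError:
                    mass = 1.0
                mass *= float(_lognormal(rng, design.mass_cv))
                true_organ_bq = true_fia(spec, organ, t_h) * design.injected_activity_bq
                measured = (
                    true_organ_bq * delay_decay * float(_lognormal(rng, design.measurement_cv))
                )
                rows.append(
                    {
                        "animal_id": f"m{animal:03d}",
                        "organ": organ,
                        "time_post_injection_min": t_min,
                        "sample_mass_g": mass,
                        "measured_activity_bq": measured,
                        "injected_activity_bq": design.injected_activity_bq,
                        "counting_delay_min": design.counting_delay_min,
                        "body_weight_g": spec.body_weight_g,
                    }
                )
    return BiodistributionTable(
        pd.DataFrame(rows), calibration_factor=1.0, measurement_cv=design.measurement_cv
    )


#: Default digital-phantom geometry: organ -> (centre mm, semi-axes mm).
#: Ellipsoids on a small-animal grid; liver adjacent to heart/lungs so blur
#: produces spill-over, testes isolated and small so it shows partial volume.
DEFAULT_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "liver": ((16.0, 16.0, 14.0), (8.0, 8.0, 6.2)),
    "heart": ((16.0, 16.0, 24.5), (3.3, 3.3, 3.3)),
    "lung": ((16.0, 22.5, 25.0), (3.5, 3.2, 3.5)),
    "kidneys": ((26.0, 8.0, 14.0), (5.0, 4.5, 5.0)),
    "testes": ((16.0, 16.0, 4.0), (2.9, 2.9, 2.9)),
}


def render_dynamic_phantom(
    spec: OrganKineticsSpec,
    geometry: dict | None = None,
    schedule: FrameSchedule | None = None,
    psf_fwhm_mm: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (80, 80, 40),
    voxel_size_mm: tuple[float, float, float] = (0.4, 0.4, 0.8),
    injected_bq: float = 9.19e6,
) -> tuple[DynamicImageSeries, dict[str, VOIMask], dict]:
    """Voxelise the true kinetics into a blurred dynamic image series.

    Each organ is a homogeneous ellipsoid whose concentration at a frame is
    the true FIA at the frame midpoint times the injected activity over the
    voxelised organ volume; frames are then resolution-blurred (Gaussian PSF
    of the stated FWHM), optionally noised, and decay corrected to the frame
    start, mirroring the scanner output convention.

    Returns the image series, whole-organ masks, and a ground-truth dict with
    the voxelised volumes, the true FIA per frame, and analytic residence
    times (10 h horizon, trapped after the last frame).
    """
    geometry = DEFAULT_GEOMETRY if geometry is None else geometry
    schedule = DEFAULT_SCHEDULE if schedule is None else schedule
    if psf_fwhm_mm < 0:
        raise ValueError("PSF FWHM must be non-negative")
    rng = np.random.default_rng(seed)
    coords = [
        (np.arange(n) + 0.5) * d for n, d in zip(shape, voxel_size_mm, strict=True)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    voxel_ml = voxel_size_mm[0] * voxel_size_mm[1] * voxel_size_mm[2] / 1000.0

    masks: dict[str, VOIMask] = {}
    for organ, (center, semi) in geometry.items():
        for c, s, n, d in zip(center, semi, shape, voxel_size_mm, strict=True):
            if c - s < 0 or c + s > n * d:
                raise ValueError(f"organ {organ!r} extends outside the grid")
        m = (
            ((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2
        ) <= 1.0
        for other, voi in masks.items():
            if (m & voi.mask).any():
                raise ValueError(f"organs {organ!r} and {other!r} overlap")
        masks[organ] = VOIMask(m, organ, "whole_organ")

    t_mid = schedule.midpoints_h
    truth_fia = {o: true_fia(spec, o, t_mid) for o in geometry}
    frames = np.zeros(shape + (schedule.n_frames,), dtype=float)
    for organ, voi in masks.items():
        vol_ml = voi.n_voxels * voxel_ml
        conc = truth_fia[organ] * injected_bq / vol_ml  # Bq/ml, physical
        frames[voi.mask, :] = conc[np.newaxis, :]

    if psf_fwhm_mm > 0:
        sigma_vox = [
            psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / d
            for d in voxel_size_mm
        ]
        for j in range(schedule.n_frames):
            frames[..., j] = ndimage.gaussian_filter(
                frames[..., j], sigma_vox, mode="constant"
            )
    if noise_cv > 0:
        frames *= _lognormal(rng, noise_cv, frames.shape)

    # scanner convention: correct each frame to its start (midpoint-equivalent)
    lam = spec.nuclide.decay_constant
    start_h = schedule.start_s / 3600.0
    dt_h = schedule.duration_s / 3600.0
    x = lam * dt_h
    in_frame = np.where(x > 1e-12, -np.expm1(-x) / x, 1.0)
    frames /= decay_factor(spec.nuclide, start_h) * in_frame

    series = DynamicImageSeries(frames, voxel_size_mm, schedule, True)
    last_h = float(t_mid[-1])
    truth = {
        "volumes_ml": {o: masks[o].n_voxels * voxel_ml for o in geometry},
        "fia": truth_fia,
        "times_h": t_mid,
        "residence_h": {
            o: true_residence_time(spec, o, 10.0, trapped_after_h=last_h)
            for o in geometry
        },
    }
    return series, masks, truth


def default_spec() -> OrganKineticsSpec:
    """The shipped study conditions (representative, clearly non-measured)."""
    return OrganKineticsSpec()


def with_noiseless(design: StudyDesign) -> StudyDesign:
    """Copy of a design with all noise switched off (truth pass-through)."""
    return replace(design, measurement_cv=0.0, mass_cv=0.0)
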