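"""Dynamic voiding-bladder compartment model.

Urinary excretion routes a fraction ``f`` of the injected activity through
the bladder: tracer leaves the body compartment with biological rate
lambda_b = ln2/Tb, accumulates in bladder contents, decays physically with
lambda_p, and the bladder empties completely at every multiple of the voiding
interval Tv.  Within a cycle starting at the last void t0,

    A_bladder(t) = f * exp(-lambda_p*t) * (exp(-lambda_b*t0) - exp(-lambda_b*t))

which solves dA/dt = f*lambda_b*exp(-(lambda_p+lambda_b)*t) - lambda_p*A with
A(t0) = 0.  The residence time is the sum of per-cycle closed-form integrals;
by default the series is summed to convergence (the model is theoretical, so
no measurement horizon truncates it), matching how voiding-bladder residence
times are conventionally reported.  A finite horizon can be imposed to mirror
a truncated TAC analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nuclides import F18, Radionuclide, decay_factor


@dataclass(frozen=True)
class BladderParams:
    """Voiding-bladder parameters.

    excreted_fraction : fraction of injected activity leaving via urine, [0, 1]
    biological_half_life_h : urinary-entry biological half-life Tb (h)
    voiding_interval_h : time between complete bladder emptyings Tv (h)
    horizon_h : integration horizon; None integrates the full cycle series
    """

    excreted_fraction: float = 0.5
    biological_half_life_h: float = 3.0
    voiding_interval_h: float = 4.0
    nuclide: Radionuclide = F18
    horizon_h: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.excreted_fraction <= 1.0:
            raise ValueError("excreted fraction must be in [0, 1]")
        if not self.biological_half_life_h > 0:
            raise ValueError("biological half-life must be positive")
        if not self.voiding_interval_h > 0:
            raise ValueError("voiding interval must be positive")
        if self.horizon_h is not None and not self.horizon_h > 0:
            raise ValueError("horizon must be positive")

    @property
    def lambda_b(self) -> float:
        return math.log(2.0) / self.biological_half_life_h


def bladder_content(t_h, p: BladderParams):
    """FIA in bladder contents at time ``t_h`` (zero just after each void)."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    lam_p = p.nuclide.decay_constant
    lam_b = p.lambda_b
    t0 = np.floor(t / p.voiding_interval_h) * p.voiding_interval_h
    out = (
        p.excreted_fraction
        * np.exp(-lam_p * t)
        * (np.exp(-lam_b * t0) - np.exp(-lam_b * t))
    )
    return float(out) if np.ndim(t_h) == 0 else out


def _cycle_integral(p: BladderParams, a: float, b: float) -> float:
    """Closed-form integral of bladder content over [a, b] within one cycle.

    ``a`` must be the cycle's voiding instant (bladder empty at a).
    """
    lam_p = p.nuclide.decay_constant
    lam_pb = lam_p + p.lambda_b
    return p.excreted_fraction * (
        math.exp(-p.lambda_b * a) * (math.exp(-lam_p * a) - math.exp(-lam_p * b)) / lam_p
        - (math.exp(-lam_pb * a) - math.exp(-lam_pb * b)) / lam_pb
    )


def bladder_residence(p: BladderParams) -> float:
    """Bladder-contents residence time (h), closed form per voiding cycle.

    Sums cycle integrals up to ``p.horizon_h`` (final cycle truncated there),
    or to convergence when the horizon is None.  Exactly linear in the
    excreted fraction and bounded by f/lambda_p.
    """
    if p.excreted_fraction == 0.0:
        return 0.0
    tv = p.voiding_interval_h
    tau = 0.0
    k = 0
    while True:
        a = k * tv
        if p.horizon_h is not None and a >= p.horizon_h:
            break
        b = a + tv if p.horizon_h is None else min(a + tv, p.horizon_h)
        term = _cycle_integral(p, a, b)
        tau += term
        if p.horizon_h is None and term < 1e-15 * max(tau, 1.0):
            break
        k += 1
        if k > 100000:  # unreachable for physical parameters
            raise RuntimeError("bladder cycle series failed to converge")
    return tau


def bladder_residence_numeric(p: BladderParams, step_h: float = 1e-4) -> float:
    """Trapezoid-quadrature oracle for :func:`bladder_residence`.

    The grid is snapped to the voiding instants so the discontinuities (the
    bladder empties instantaneously) are never straddled by a trapezoid.
    """
    if not step_h > 0:
        raise ValueError("step must be positive")
    lam_p = p.nuclide.decay_constant
    # beyond ~40 physical half-lives the integrand is numerically zero
    horizon = p.horizon_h if p.horizon_h is not None else 40.0 / lam_p
    tau = 0.0
    k = 0
    while True:
        a = k * p.voiding_interval_h
        if a >= horizon:
            break
        b = min(a + p.voiding_interval_h, horizon)
        n = max(2, int(math.ceil((b - a) / step_h)) + 1)
        grid = np.linspace(a, b, n)
        tau += float(np.trapezoid(bladder_content(grid, p), grid))
        k += 1
    return tau


def no_voiding_residence(p: BladderParams, horizon_h: float) -> float:
    """Single-cycle limit (Tv -> infinity): integral of the fill curve to horizon."""
    lam_p = p.nuclide.decay_constant
    lam_pb = lam_p + p.lambda_b
    f = p.excreted_fraction
    return f * (
        (1.0 - math.exp(-lam_p * horizon_h)) / lam_p
        - (1.0 - math.exp(-lam_pb * horizon_h)) / lam_pb
    )
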