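"""Radionuclide decay physics and unit conventions shared by every pipeline stage.

All internal times are hours and all activities are expressed as fraction of
injected activity (FIA, dimensionless).  Minutes and Bq/MBq are converted at
the ingestion boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Radionuclide:
    """A radionuclide defined by its physical half-life.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"F-18"``.
    half_life_h : float
        Physical half-life in hours.  Must be positive.
    """

    name: str
    half_life_h: float

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_h}")

    @property
    def decay_constant(self) -> float:
        """Physical decay constant lambda_p in 1/h (ln 2 / half-life)."""
        return LN2 / self.half_life_h

    @property
    def total_disintegrations(self) -> float:
        """Time-integral of a trapped unit activity: 1/lambda_p hours."""
        return self.half_life_h / LN2


#: F-18 physical half-life, 109.771 min (standard nuclide datum).
F18 = Radionuclide("F-18", 109.771 / 60.0)

#: Registry of shipped nuclides; users may register others.
REGISTRY: dict[str, Radionuclide] = {"F-18": F18}


def get_nuclide(name: str) -> Radionuclide:
    """Look up a nuclide by name in the registry."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown nuclide {name!r}; known: {sorted(REGISTRY)}"
        ) from None


def decay_factor(nuclide: Radionuclide, t_h):
    """Fraction of activity remaining after ``t_h`` hours of physical decay.

    Returns ``exp(-lambda_p * t)``; strictly decreasing in ``t`` with value in
    (0, 1].  ``t_h`` may be a scalar or array; negative times are a domain
    error (decay correction is not this function's job).
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("decay_factor requires t >= 0")
    out = np.exp(-nuclide.decay_constant * t)
    return float(out) if np.isscalar(t_h) or t.ndim == 0 else out
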