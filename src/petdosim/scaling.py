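"""Standard-animal construction and interspecies organ-uptake extrapolation.

Human dose prediction from rodent data assumes the percent of injected
activity in an organ, multiplied by total body weight, is conserved across
species.  For an organ with animal uptake concentration %/g this gives

    FIA_human(organ) = FIA/g_animal * BW_animal[kg] * m_organ_human[g] / BW_human[kg]

A "standard animal" (per-organ mass and density averaged over a dissection
cohort, rescaled to a reference body weight) supplies the animal organ masses
and the organ/body-weight ratios; a reference adult phantom supplies the
human organ masses.  Organs whose organ/body-weight ratio is unknown cannot
be extrapolated and are routed to the remainder by the downstream stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class StandardAnimal:
    """Species-average organ masses/densities scaled to a reference body weight.

    ``organs`` maps organ -> (mass_g at reference body weight, density g/ml).
    ``organ_fraction`` is organ mass / body mass, invariant to the rescaling.
    """

    reference_body_weight_g: float = 35.0
    organs: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reference_body_weight_g > 0:
            raise ValueError("reference body weight must be positive")
        total = 0.0
        for organ, (mass, density) in self.organs.items():
            if not mass > 0:
                raise ValueError(f"non-positive mass for {organ}")
            if not 0.5 < density < 2.0:
                raise ValueError(f"implausible density {density} for {organ}")
            total += mass
        if total >= self.reference_body_weight_g:
            raise ValueError("organ masses exceed the reference body weight")

    def organ_mass_g(self, organ: str) -> float:
        return self.organs[organ][0]

    def density(self, organ: str) -> float:
        return self.organs[organ][1]

    def organ_fraction(self, organ: str) -> float:
        return self.organs[organ][0] / self.reference_body_weight_g

    def organ_volume_ml(self, organ: str, body_weight_g: float | None = None) -> float:
        """Organ volume, optionally rescaled to another animal's body weight."""
        mass, density = self.organs[organ]
        if body_weight_g is not None:
            mass = self.organ_fraction(organ) * body_weight_g
        return mass / density


@dataclass
class HumanPhantom:
    """Reference adult phantom: total body weight (kg) and organ masses (g)."""

    total_body_weight_kg: float = 70.0
    organ_masses_g: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.total_body_weight_kg > 0:
            raise ValueError("body weight must be positive")
        bad = [o for o, m in self.organ_masses_g.items() if not m > 0]
        if bad:
            raise ValueError(f"non-positive organ masses: {bad}")
        if sum(self.organ_masses_g.values()) >= self.total_body_weight_kg * 1000:
            raise ValueError("organ masses exceed total body mass")


@dataclass(frozen=True)
class ExtrapolationContext:
    """The three scale factors of the interspecies formula for one organ."""

    animal_body_weight_kg: float
    human_body_weight_kg: float
    human_organ_mass_g: float

    def __post_init__(self) -> None:
        if min(self.animal_body_weight_kg, self.human_body_weight_kg) <= 0:
            raise ValueError("body weights must be positive")
        if self.human_organ_mass_g < 0:
            raise ValueError("organ mass must be non-negative")


def build_standard_animal(
    dissections: pd.DataFrame, reference_bw_g: float = 35.0
) -> StandardAnimal:
    """Average a dissection cohort into a standard animal.

    ``dissections`` columns: animal_id, organ, organ_mass_g, organ_volume_ml,
    body_weight_g.  Per organ: density = mean(mass/volume), organ fraction =
    mean(mass/body weight); the standard mass is fraction * reference weight.
    Organs present in only a subset of animals use that subset (logged).
    """
    required = {"animal_id", "organ", "organ_mass_g", "organ_volume_ml", "body_weight_g"}
    missing = required - set(dissections.columns)
    if missing:
        raise ValueError(f"dissection table missing columns {sorted(missing)}")
    if (dissections["organ_volume_ml"] <= 0).any():
        raise ValueError("organ volumes must be positive")

    n_animals = dissections["animal_id"].nunique()
    organs: dict[str, tuple[float, float]] = {}
    for organ, grp in dissections.groupby("organ"):
        if len(grp) < n_animals:
            log.info("organ %s present in %d/%d animals", organ, len(grp), n_animals)
        density = float((grp["organ_mass_g"] / grp["organ_volume_ml"]).mean())
        fraction = float((grp["organ_mass_g"] / grp["body_weight_g"]).mean())
        organs[str(organ)] = (fraction * reference_bw_g, density)
    return StandardAnimal(reference_bw_g, organs)


def extrapolate_to_human(fia_per_gram_animal: float, ctx: ExtrapolationContext) -> float:
    """Whole-organ human FIA from animal FIA/g via the linear scaling formula."""
    if fia_per_gram_animal < 0:
        raise ValueError("FIA per gram must be non-negative")
    out = (
        fia_per_gram_animal
        * ctx.animal_body_weight_kg
        * ctx.human_organ_mass_g
        / ctx.human_body_weight_kg
    )
    if out > 1.0:
        warnings.warn(
            f"extrapolated organ FIA {out:.3g} exceeds 1; not clamped", stacklevel=2
        )
    return out


def no_extrapolation_fia(fia_per_gram_animal: float, animal_organ_mass_g: float) -> float:
    """Animal whole-organ FIA (the 'NE' variant): per-gram value times organ mass."""
    if not animal_organ_mass_g > 0:
        raise ValueError("organ mass must be positive")
    return fia_per_gram_animal * animal_organ_mass_g


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("petdosim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def default_standard_mouse() -> StandardAnimal:
    """Shipped 35-g standard mouse (representative values, not study data)."""
    df = _load_csv("standard_mouse.csv")
    organs = {
        str(r["organ"]): (float(r["mass_g"]), float(r["density_g_per_ml"]))
        for _, r in df.iterrows()
    }
    return StandardAnimal(35.0, organs)


def default_human_phantom() -> HumanPhantom:
    """Shipped 70-kg adult male phantom organ masses (representative values)."""
    df = _load_csv("human_phantom_70kg.csv")
    masses = {str(r["organ"]): float(r["mass_g"]) for _, r in df.iterrows()}
    return HumanPhantom(70.0, masses)
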