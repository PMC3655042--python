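"""Full-pipeline orchestration: study tables in, dose reports out.

The tissue-distribution route: biodistribution table -> per-organ mean/SD FIA
per gram -> interspecies extrapolation (or the no-extrapolation 'NE' bound)
-> time-activity curves -> residence times with mean +/- 1 SD envelopes ->
theoretical bladder residence -> remainder by disintegration conservation ->
MIRD absorbed doses -> ICRP effective doses, bladder-fraction sensitivity and
regulatory injection limits.  The imaging route replaces the first stages
with dynamic-PET VOI time series; organs outside the field of view are
absorbed into the remainder by the conservation rule and flagged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biodist import BiodistributionTable, collapse_time_points, read_biodistribution
from .bladder import BladderParams, bladder_residence
from .dose import (
    SValueTable,
    TissueWeightScheme,
    absorbed_doses,
    bladder_sensitivity,
    compare_methods,
    effective_dose,
    icrp60_scheme,
    icrp103_scheme,
    injection_limits,
)
from .nuclides import Radionuclide, get_nuclide
from .petquant import FrameSchedule, uncorrect_frames
from .scaling import (
    ExtrapolationContext,
    HumanPhantom,
    StandardAnimal,
    default_human_phantom,
    default_standard_mouse,
    extrapolate_to_human,
    no_extrapolation_fia,
)
from .tac import build_tac, remainder_residence, residence_time, uncertainty_window

log = logging.getLogger(__name__)


def toy_svalue_table() -> SValueTable:
    """The shipped self-dose-dominant toy S-value table (test/demo data)."""
    with resources.files("petdosim.data").joinpath("svalues_toy.csv").open() as fh:
        return SValueTable("toy-70kg", pd.read_csv(fh, index_col=0))


@dataclass
class PipelineConfig:
    """Configuration for either pipeline route."""

    biodistribution_path: str | None = None
    voi_series_path: str | None = None
    nuclide: str = "F-18"
    extrapolate: bool = True  # False = 'NE' (no extrapolation) mode
    bladder_fraction: float = 0.5
    bladder_half_life_h: float = 3.0
    voiding_interval_h: float = 4.0
    sensitivity_fractions: tuple[float, ...] = (0.3, 0.4, 0.5)
    sensitivity_intervals_h: tuple[float, ...] = (2.0, 4.0)
    svalue_path: str | None = None
    schemes: tuple[str, ...] = ("icrp103", "icrp60")
    horizon_h: float = 10.0
    tail_policy: str = "truncate_at_horizon"
    injected_bq: float | None = None
    body_weight_g: float | None = None
    voi_strategy: str = "whole_organ"
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sensitivity_fractions", "sensitivity_intervals_h", "schemes"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    def resolve_nuclide(self) -> Radionuclide:
        return get_nuclide(self.nuclide)

    def resolve_svalues(self) -> SValueTable:
        if self.svalue_path:
            return SValueTable.read_csv(self.svalue_path)
        return toy_svalue_table()

    def resolve_schemes(self) -> dict[str, TissueWeightScheme]:
        factory = {"icrp103": icrp103_scheme, "icrp60": icrp60_scheme}
        out = {}
        for name in self.schemes:
            if name not in factory:
                raise ValueError(f"unknown weighting scheme {name!r}")
            out[name] = factory[name]()
        return out

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class DoseReport:
    """Pipeline output bundle, serialisable to JSON and delimited text."""

    method: str
    residence: pd.DataFrame  # organ, tau_h, cv_percent
    tau_bladder_h: float
    tau_remainder_h: float
    doses: dict[str, float]
    effective_doses: dict[str, float]
    limits: pd.DataFrame
    sensitivity: pd.DataFrame
    missing_organs: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def conservation_total_h(self) -> float:
        return float(self.residence["tau_h"].sum()) + self.tau_bladder_h + self.tau_remainder_h

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "residence": self.residence.to_dict(orient="records"),
            "tau_bladder_h": self.tau_bladder_h,
            "tau_remainder_h": self.tau_remainder_h,
            "doses_mgy_per_mbq": self.doses,
            "effective_doses_msv_per_mbq": self.effective_doses,
            "injection_limits": self.limits.to_dict(orient="records"),
            "bladder_sensitivity": self.sensitivity.to_dict(orient="records"),
            "missing_organs": self.missing_organs,
            "meta": self.meta,
        }

    def write(self, out_dir, prefix: str | None = None) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.method
        report_path = out / f"{prefix}_report.json"
        report_path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        self.residence.to_csv(out / f"{prefix}_residence.csv", index=False, float_format="%.4E")
        pd.Series(self.doses, name="dose_mgy_per_mbq").rename_axis("organ").to_csv(
            out / f"{prefix}_doses.csv", float_format="%.4E"
        )
        self.limits.to_csv(out / f"{prefix}_limits.csv", index=False)
        self.sensitivity.to_csv(out / f"{prefix}_sensitivity.csv", index=False, float_format="%.4E")
        return report_path


def _dosimetry_tail(
    method: str,
    organ_taus: dict[str, float],
    organ_cvs: dict[str, float | None],
    config: PipelineConfig,
    nuclide: Radionuclide,
    missing: list[str],
) -> DoseReport:
    """Shared back half: bladder, remainder, doses, EDs, limits, sensitivity."""
    p = BladderParams(
        config.bladder_fraction,
        config.bladder_half_life_h,
        config.voiding_interval_h,
        nuclide,
    )
    tau_b = bladder_residence(p)
    tau_rem = remainder_residence(organ_taus, tau_b, nuclide)
    total = sum(organ_taus.values()) + tau_b + tau_rem
    if abs(total - nuclide.total_disintegrations) > 1e-9:
        raise RuntimeError(
            f"disintegration conservation violated: {total} != "
            f"{nuclide.total_disintegrations}"
        )

    svals = config.resolve_svalues()
    taus = dict(organ_taus)
    taus["bladder"] = tau_b
    taus["remainder"] = tau_rem
    doses = absorbed_doses(taus, svals)
    schemes = config.resolve_schemes()
    eds = {name: effective_dose(doses, sch) for name, sch in schemes.items()}
    primary_ed = eds.get("icrp103", next(iter(eds.values())))
    limits = injection_limits(doses, primary_ed)
    sens = bladder_sensitivity(
        organ_taus,
        config.sensitivity_fractions,
        config.sensitivity_intervals_h,
        svals,
        schemes,
        nuclide,
        biological_half_life_h=config.bladder_half_life_h,
    )
    residence = pd.DataFrame(
        {
            "organ": list(organ_taus),
            "tau_h": [organ_taus[o] for o in organ_taus],
            "cv_percent": [organ_cvs.get(o) for o in organ_taus],
        }
    ).sort_values("organ").reset_index(drop=True)
    return DoseReport(
        method=method,
        residence=residence,
        tau_bladder_h=tau_b,
        tau_remainder_h=tau_rem,
        doses=doses,
        effective_doses=eds,
        limits=limits,
        sensitivity=sens,
        missing_organs=missing,
        meta={
            "version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "nuclide": nuclide.name,
            "extrapolate": config.extrapolate,
        },
    )


def run_td_pipeline(
    config: PipelineConfig,
    table: BiodistributionTable | None = None,
    animal: StandardAnimal | None = None,
    phantom: HumanPhantom | None = None,
) -> DoseReport:
    """Tissue-distribution route.  Deterministic given its inputs.

    Only organs with a known standard-animal organ/body-weight ratio are
    extrapolated; the rest are reported as missing and reach the dose stage
    only through the remainder.
    """
    if table is None:
        if not config.biodistribution_path:
            raise ValueError("biodistribution_path (or a table) is required")
        table = read_biodistribution(config.biodistribution_path)
    animal = animal or default_standard_mouse()
    phantom = phantom or default_human_phantom()
    nuclide = config.resolve_nuclide()

    points = collapse_time_points(table, nuclide)
    body_weight_g = config.body_weight_g
    if body_weight_g is None:
        bw = table.records["body_weight_g"].dropna()
        body_weight_g = float(bw.mean()) if len(bw) else animal.reference_body_weight_g

    organ_taus: dict[str, float] = {}
    organ_cvs: dict[str, float | None] = {}
    missing: list[str] = []
    for organ, grp in points.groupby("organ"):
        if organ not in animal.organs:
            missing.append(str(organ))
            continue
        if config.extrapolate:
            ctx = ExtrapolationContext(
                animal_body_weight_kg=body_weight_g / 1000.0,
                human_body_weight_kg=phantom.total_body_weight_kg,
                human_organ_mass_g=phantom.organ_masses_g[str(organ)],
            )
            to_whole = lambda per_g: extrapolate_to_human(per_g, ctx)  # noqa: E731
        else:
            mass = animal.organ_fraction(str(organ)) * body_weight_g
            to_whole = lambda per_g: no_extrapolation_fia(per_g, mass)  # noqa: E731

        mean_pts = [
            (float(r["time_h"]), to_whole(float(r["mean_fia_per_g"])))
            for _, r in grp.iterrows()
        ]
        sd_pts = [
            (float(r["time_h"]), to_whole(float(r["sd_fia_per_g"])))
            for _, r in grp.iterrows()
        ]

        def integrate(pts):
            tac = build_tac(
                pts, str(organ), nuclide, config.horizon_h, config.tail_policy
            )
            return residence_time(tac)

        tau, _lo, _hi, cv = uncertainty_window(mean_pts, sd_pts, integrate)
        organ_taus[str(organ)] = tau
        organ_cvs[str(organ)] = cv
    if missing:
        log.info("organs without organ/body-weight ratio -> remainder: %s", missing)
    return _dosimetry_tail("td" if config.extrapolate else "td_ne",
                           organ_taus, organ_cvs, config, nuclide, missing)


def read_voi_series(path) -> pd.DataFrame:
    """Read a VOI time-series text file.

    Columns: frame_start_s, duration_s, voi_label, mean_bq_per_ml (decay
    corrected to frame start).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"frame_start_s", "duration_s", "voi_label", "mean_bq_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"VOI series missing columns {sorted(missing)}")
    return df


def run_imaging_pipeline(
    config: PipelineConfig,
    voi_series: pd.DataFrame | None = None,
    animal: StandardAnimal | None = None,
    phantom: HumanPhantom | None = None,
) -> DoseReport:
    """Dynamic-imaging route from per-VOI frame means.

    The VOI label is the organ name; organ volumes come from the standard
    animal scaled to the scanned body weight (required for sphere VOIs, and
    used for whole-organ series as well so both strategies share one volume
    convention).  Organs absent from the series (e.g. outside the field of
    view) contribute only via the remainder and are flagged in the report.
    """
    if voi_series is None:
        if not config.voi_series_path:
            raise ValueError("voi_series_path (or a series frame) is required")
        voi_series = read_voi_series(config.voi_series_path)
    if not config.injected_bq or config.injected_bq <= 0:
        raise ValueError("imaging route requires a positive injected_bq")
    animal = animal or default_standard_mouse()
    phantom = phantom or default_human_phantom()
    nuclide = config.resolve_nuclide()
    body_weight_g = config.body_weight_g or animal.reference_body_weight_g

    organ_taus: dict[str, float] = {}
    organ_cvs: dict[str, float | None] = {}
    seen: list[str] = []
    for organ, grp in voi_series.groupby("voi_label"):
        organ = str(organ)
        if organ not in animal.organs:
            log.info("VOI %r has no organ/body-weight ratio; skipped", organ)
            continue
        seen.append(organ)
        grp = grp.sort_values("frame_start_s")
        schedule = FrameSchedule(
            grp["frame_start_s"].to_numpy(float), grp["duration_s"].to_numpy(float)
        )
        times_h, true_conc = uncorrect_frames(
            grp["mean_bq_per_ml"].to_numpy(float), schedule, nuclide
        )
        volume_ml = animal.organ_volume_ml(organ, body_weight_g)
        fia_animal = true_conc * volume_ml / config.injected_bq
        if config.extrapolate:
            mass_g = animal.organ_fraction(organ) * body_weight_g
            ctx = ExtrapolationContext(
                animal_body_weight_kg=body_weight_g / 1000.0,
                human_body_weight_kg=phantom.total_body_weight_kg,
                human_organ_mass_g=phantom.organ_masses_g[organ],
            )
            fia = [extrapolate_to_human(v / mass_g, ctx) for v in fia_animal]
        else:
            fia = list(fia_animal)
        tac = build_tac(
            list(zip(times_h.tolist(), fia)),
            organ,
            nuclide,
            config.horizon_h,
            config.tail_policy,
        )
        organ_taus[organ] = residence_time(tac)
        organ_cvs[organ] = None  # single series: no across-scan scatter
    missing = sorted(set(animal.organs) - set(seen))
    method = f"imaging_{config.voi_strategy}"
    return _dosimetry_tail(method, organ_taus, organ_cvs, config, nuclide, missing)


def compare_reports(a: DoseReport, b: DoseReport) -> tuple[float, pd.DataFrame]:
    """Pearson r and per-organ percent deviation between two dose reports."""
    return compare_methods(a.doses, b.doses)
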