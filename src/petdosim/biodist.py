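"""Ingest and normalise organ-harvesting (tissue distribution) study tables.

A biodistribution study sacrifices groups of animals at fixed times after a
tracer injection, dissects a panel of organs, and counts each sample in a
calibrated gamma well counter.  This module validates such tables and reduces
them to per-(organ, time) mean fraction-of-injected-activity per gram.

Activity convention: values are NON-decay-corrected, i.e. physically present
activity at the sample's own clock time.  Decay during the delay between
sacrifice and counting is restored (the value refers to sacrifice time); no
correction back to injection time is applied, because residence-time
integration needs the physical activity and the time-activity curves must
decay to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclides import Radionuclide, decay_factor

log = logging.getLogger(__name__)

#: Controlled organ vocabulary for biodistribution records.
ORGAN_VOCABULARY = frozenset(
    {
        "brain", "liver", "kidneys", "heart", "spleen", "lung", "testes",
        "blood", "bone", "intestine", "pancreas", "adrenals", "skin",
        "muscle", "stomach", "bladder",
    }
)

#: Synonyms folded into the controlled vocabulary at ingestion.
_ORGAN_ALIASES = {
    "kidney": "kidneys",
    "lungs": "lung",
    "femur": "bone",
    "testis": "testes",
}

REQUIRED_COLUMNS = (
    "animal_id",
    "organ",
    "time_post_injection_min",
    "sample_mass_g",
    "measured_activity_bq",
    "injected_activity_bq",
)

OPTIONAL_COLUMNS = ("counting_delay_min", "body_weight_g")


def normalize_organ(name: str) -> str:
    """Map an organ label onto the controlled vocabulary (case-insensitive)."""
    key = str(name).strip().lower()
    key = _ORGAN_ALIASES.get(key, key)
    if key not in ORGAN_VOCABULARY:
        raise ValueError(
            f"organ {name!r} not in controlled vocabulary {sorted(ORGAN_VOCABULARY)}"
        )
    return key


class ValidationError(ValueError):
    """Raised when an input table violates the biodistribution contract."""


@dataclass
class BiodistributionTable:
    """Validated per-animal, per-organ activity measurements.

    ``records`` columns (units fixed at ingestion): animal_id, organ,
    time_post_injection_min, sample_mass_g, measured_activity_bq,
    injected_activity_bq, counting_delay_min, body_weight_g.
    """

    records: pd.DataFrame
    calibration_factor: float = 1.0
    measurement_cv: float = 0.05  # well-counter uncertainty, +/-5% default

    def __post_init__(self) -> None:
        self.records = validate_records(self.records)

    @property
    def organs(self) -> list[str]:
        return sorted(self.records["organ"].unique())

    @property
    def times_min(self) -> list[float]:
        return sorted(self.records["time_post_injection_min"].unique())


@dataclass
class OrganTimePoint:
    """Group summary: mean/SD FIA per gram at one sampling time (hours)."""

    organ: str
    time_h: float
    mean_fia_per_g: float
    sd_fia_per_g: float
    n: int = field(default=1)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check mandatory columns, positivity and uniqueness; normalise organs."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {missing}")
    df = df.copy()
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0 if col == "counting_delay_min" else np.nan
    df["organ"] = df["organ"].map(normalize_organ)

    bad = {}
    for col, ok in (
        ("sample_mass_g", df["sample_mass_g"] > 0),
        ("injected_activity_bq", df["injected_activity_bq"] > 0),
        ("time_post_injection_min", df["time_post_injection_min"] > 0),
        ("counting_delay_min", df["counting_delay_min"] >= 0),
        ("measured_activity_bq", df["measured_activity_bq"] >= 0),
    ):
        rows = df.index[~ok].tolist()
        if rows:
            bad[col] = rows
    if bad:
        raise ValidationError(f"invalid values in rows (by column): {bad}")

    dup = df.duplicated(subset=["animal_id", "organ", "time_post_injection_min"])
    if dup.any():
        raise ValidationError(
            f"duplicate (animal, organ, time) rows at index {df.index[dup].tolist()}"
        )
    return df


def read_biodistribution(
    path,
    schema: dict[str, str] | None = None,
    calibration_factor: float = 1.0,
    measurement_cv: float = 0.05,
    delimiter: str | None = None,
) -> BiodistributionTable:
    """Read a delimited-text biodistribution table.

    Parameters
    ----------
    path : path-like
        UTF-8 delimited text with a header row (comma default; tab accepted).
    schema : dict, optional
        Maps file column names onto the canonical names in
        :data:`REQUIRED_COLUMNS` / :data:`OPTIONAL_COLUMNS`.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if schema:
        df = df.rename(columns=schema)
    return BiodistributionTable(df, calibration_factor, measurement_cv)


def write_biodistribution(table: BiodistributionTable, path) -> None:
    """Write a table back to delimited text (lossless round-trip)."""
    table.records.to_csv(path, index=False)


def fia_per_gram(
    record: pd.Series | dict,
    calibration_factor: float,
    nuclide: Radionuclide,
) -> float:
    """Fraction of injected activity per gram at sacrifice time.

    The well-counter reading is scaled by the calibration factor and the decay
    between sacrifice and counting is restored, then normalised by the
    activity injected at injection time and the sample mass:

        (measured * calibration / decay(counting_delay)) / injected / mass
    """
    delay_h = float(record["counting_delay_min"]) / 60.0
    true_at_sacrifice = (
        float(record["measured_activity_bq"])
        * calibration_factor
        / decay_factor(nuclide, delay_h)
    )
    return (
        true_at_sacrifice
        / float(record["injected_activity_bq"])
        / float(record["sample_mass_g"])
    )


def collapse_time_points(
    table: BiodistributionTable, nuclide: Radionuclide
) -> pd.DataFrame:
    """Per-(organ, time) mean and sample SD of FIA per gram across animals.

    Returns a DataFrame with columns organ, time_h, mean_fia_per_g,
    sd_fia_per_g, n (sorted by organ then time).  Groups with a single animal
    get sd = 0 with a warning; empty groups cannot arise after validation.
    """
    df = table.records
    values = df.apply(
        lambda r: fia_per_gram(r, table.calibration_factor, nuclide), axis=1
    )
    work = pd.DataFrame(
        {
            "organ": df["organ"],
            "time_h": df["time_post_injection_min"] / 60.0,
            "fia_per_g": values,
        }
    )
    rows = []
    for (organ, t), grp in work.groupby(["organ", "time_h"], sort=True):
        n = len(grp)
        if n == 1:
            warnings.warn(
                f"single animal for ({organ}, {t:.3g} h); SD set to 0",
                stacklevel=2,
            )
        sd = float(grp["fia_per_g"].std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "organ": organ,
                "time_h": float(t),
                "mean_fia_per_g": float(grp["fia_per_g"].mean()),
                "sd_fia_per_g": sd,
                "n": n,
            }
        )
    return pd.DataFrame(rows).sort_values(["organ", "time_h"]).reset_index(drop=True)
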