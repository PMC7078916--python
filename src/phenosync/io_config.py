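"""Configuration, CSV input/output and logging for the synchrony pipeline.

All tabular interchange is plain CSV with the headers documented on each
reader; every biological constant used downstream (critical chick age,
lay-to-peak lag, energy content of caterpillars, the per-nestling requirement
series) is a configurable field of :class:`PipelineConfig`, never hard-coded
in computation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .food_curves import REQUIREMENT_G, FrassSeries

logger = logging.getLogger("phenosync")

#: valid levels of the beech crop index (three-level ordinal)
BCI_LEVELS = (0, 1, 2)

FRASS_COLUMNS = ["year", "day_of_year", "biomass_g_m2"]
BREEDING_COLUMNS = [
    "brood_id", "mother_id", "year", "lay_date", "clutch_size",
    "hatch_date", "brood_size_d15", "recruits", "density", "bci",
]


class FormatError(ValueError):
    """A file does not match the expected schema."""


class ValidationError(ValueError):
    """A file matches the schema but contains invalid values."""


@dataclass
class PipelineConfig:
    """Constants of the synchrony pipeline, with field defaults.

    season_window
        inclusive day-of-year range on which daily curves are built.
    chick_age_critical
        nestling age (days post-hatching, hatch day = age 0) at which energy
        needs peak; brood-level mismatch is measured at this age.
    lay_to_peak_lag
        days from laying to the peak of offspring needs, used for the
        population-level mismatch (mean laying date + lag − peak date).
    energy_content
        kJ per g dry caterpillar mass.
    wet_fraction
        proportion of wet mass in caterpillars; the dry-to-wet multiplier is
        1/(1 − wet_fraction).
    requirement_series
        per-nestling daily requirement (g wet biomass) for ages 5–15.
    """

    season_window: tuple[int, int] = (100, 180)
    chick_age_critical: int = 10
    lay_to_peak_lag: int = 33
    energy_content: float = 21.4
    wet_fraction: float = 0.80
    requirement_series: tuple[float, ...] = REQUIREMENT_G
    rng_seed: int = 0
    bootstrap_reps: int = 1000

    def __post_init__(self):
        self.season_window = (int(self.season_window[0]), int(self.season_window[1]))
        self.requirement_series = tuple(float(v) for v in self.requirement_series)
        self.validate()

    def validate(self) -> None:
        if not 0 < self.wet_fraction < 1:
            raise ValidationError("wet_fraction must be in (0, 1)")
        if self.energy_content <= 0:
            raise ValidationError("energy_content must be positive")
        if len(self.requirement_series) != 11 or any(v < 0 for v in self.requirement_series):
            raise ValidationError("requirement_series needs exactly 11 nonnegative entries")
        if self.season_window[0] >= self.season_window[1]:
            raise ValidationError("season_window start must precede end")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be positive")

    # -- flat YAML round-trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["season_window"] = list(self.season_window)
        d["requirement_series"] = list(self.requirement_series)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler to the package logger (idempotent)."""
    lg = logging.getLogger("phenosync")
    if not lg.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        lg.addHandler(h)
    lg.setLevel(level)


# ---------------------------------------------------------------------------
# Frass samples
# ---------------------------------------------------------------------------

def read_frass_csv(path: str | Path) -> list[FrassSeries]:
    """Read sparse biomass samples, one :class:`FrassSeries` per year.

    Expects columns ``year, day_of_year, biomass_g_m2``.  Rows duplicating a
    (year, day) pair are averaged; samples are sorted by date within year.
    """
    df = pd.read_csv(path)
    missing = [c for c in FRASS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"frass file {path} lacks columns {missing}")
    neg = df.index[df["biomass_g_m2"] < 0]
    if len(neg):
        raise ValidationError(f"negative biomass in row(s) {list(neg)} of {path}")
    grouped = (
        df.groupby(["year", "day_of_year"], as_index=False)["biomass_g_m2"].mean()
        .sort_values(["year", "day_of_year"])
    )
    out = [
        FrassSeries(int(year), sub["day_of_year"].to_numpy(int), sub["biomass_g_m2"].to_numpy(float))
        for year, sub in grouped.groupby("year")
    ]
    logger.info("read %d frass samples in %d seasons from %s", len(df), len(out), path)
    return out


def write_frass_csv(series_list: list[FrassSeries], path: str | Path) -> None:
    rows = [
        {"year": s.year, "day_of_year": int(d), "biomass_g_m2": float(b)}
        for s in series_list
        for d, b in zip(s.days, s.biomass)
    ]
    pd.DataFrame(rows, columns=FRASS_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Breeding records
# ---------------------------------------------------------------------------

def read_breeding_csv(path: str | Path) -> pd.DataFrame:
    """Read brood-level breeding records with yearly covariates.

    Expects columns ``brood_id, mother_id, year, lay_date, clutch_size,
    hatch_date, brood_size_d15, recruits, density, bci``.  An empty
    ``brood_size_d15`` marks a brood that failed before nestling day 15; the
    returned frame carries a boolean ``failed`` column.  ``bci`` must take
    one of the three ordinal levels (0, 1, 2).
    """
    df = pd.read_csv(path)
    missing = [c for c in BREEDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"breeding file {path} lacks columns {missing}")
    bad = df.index[df["hatch_date"] < df["lay_date"]]
    if len(bad):
        raise ValidationError(f"hatch before lay in row(s) {list(bad)} of {path}")
    if not df["bci"].isin(BCI_LEVELS).all():
        bad = sorted(set(df["bci"]) - set(BCI_LEVELS))
        raise ValidationError(f"bci outside its 3 ordinal levels {BCI_LEVELS}: {bad}")
    df = df.copy()
    df["bci"] = df["bci"].astype(int)
    df["brood_size_d15"] = pd.to_numeric(df["brood_size_d15"], errors="raise").astype("Float64")
    df["failed"] = df["brood_size_d15"].isna()
    for col in ("year", "lay_date", "clutch_size", "hatch_date", "recruits"):
        df[col] = df[col].astype(int)
    logger.info(
        "read %d broods (%d failed) across %d years from %s",
        len(df), int(df["failed"].sum()), df["year"].nunique(), path,
    )
    return df


def write_breeding_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df[BREEDING_COLUMNS].copy()
    pd.DataFrame(out).to_csv(path, index=False)
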