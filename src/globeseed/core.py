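"""Domain types, validation and tabular I/O for soil seed bank survey records.

A *record* is one survey observation of either seed bank **diversity**
(species richness per soil sample) or **density** (seeds per unit soil
surface), located on the globe, attributed to one of the 14 TEOW biomes,
and annotated with the sampling conventions (season or month, quadrat
area, soil depth slice) that the standardization stage later harmonizes.

Coordinates are decimal degrees, WGS84 implied, southern latitudes
negative.  Missing values are empty cells on disk and ``None`` in memory;
no numeric sentinels are used anywhere.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTOR_NAMES",
    "PERCENTAGE_PREDICTORS",
    "BIOMES",
    "TROPICAL_BIOMES",
    "MEASURES",
    "SEASONS",
    "RECORD_COLUMNS",
    "SeedBankRecord",
    "ReadReport",
    "ValidationReport",
    "read_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
    "validate_dataset",
    "read_predictor_table",
    "write_predictor_table",
    "is_tropical",
]

# The 31 environmental covariates: 19 climatic indices, 8 topsoil variables,
# human footprint, two plant indices and absolute latitude.  Spellings are the
# standard abbreviations used throughout the outputs of this package.
PREDICTOR_NAMES: tuple[str, ...] = (
    "abs.latit",  # absolute latitude, degrees
    "AMT",        # annual mean temperature, degC
    "AP",         # annual precipitation, mm
    "ATR",        # annual temperature range, degC
    "AVWAC",      # available water capacity, %
    "BULK",       # bulk density, kg dm-3
    "CEC",        # cation exchange capacity, cmol kg-1
    "CLAYC",      # clay, mass %
    "diversity",  # plant diversity index
    "HFP",        # human footprint index
    "Isoth",      # isothermality
    "npp",        # net primary productivity
    "ORGNC",      # organic carbon content, g kg-1
    "PCQ",        # precipitation of coldest quarter, mm
    "PDM",        # precipitation of driest month, mm
    "PDQ",        # precipitation of driest quarter, mm
    "pH",         # pH measured in water
    "Pseason",    # precipitation seasonality (CV)
    "PWeQ",       # precipitation of wettest quarter, mm
    "PWM",        # precipitation of wettest month, mm
    "PWQ",        # precipitation of warmest quarter, mm
    "SANDC",      # sand, mass %
    "SILTC",      # silt, mass %
    "TCM",        # min temperature of coldest month, degC
    "TCQ",        # mean temperature of coldest quarter, degC
    "TDQ",        # mean temperature of driest quarter, degC
    "TDR",        # mean diurnal range, degC
    "Tseason",    # temperature seasonality (sd * 100)
    "TWeQ",       # mean temperature of wettest quarter, degC
    "TWM",        # max temperature of warmest month, degC
    "TWQ",        # mean temperature of warmest quarter, degC
)

PERCENTAGE_PREDICTORS = frozenset({"AVWAC", "CLAYC", "SANDC", "SILTC"})

# The 14 TEOW major biome types, short code -> full name.
BIOMES: dict[str, str] = {
    "TSMF": "Tropical & Subtropical Moist Broadleaf Forests",
    "TSDF": "Tropical & Subtropical Dry Broadleaf Forests",
    "TSCF": "Tropical & Subtropical Coniferous Forests",
    "TBMF": "Temperate Broadleaf & Mixed Forests",
    "TCF": "Temperate Conifer Forests",
    "BFT": "Boreal Forests/Taiga",
    "TSGS": "Tropical & Subtropical Grasslands, Savannas & Shrublands",
    "TGSS": "Temperate Grasslands, Savannas & Shrublands",
    "FGS": "Flooded Grasslands & Savannas",
    "MGS": "Montane Grasslands & Shrublands",
    "TUN": "Tundra",
    "MFWS": "Mediterranean Forests, Woodlands & Scrub",
    "DXS": "Deserts & Xeric Shrublands",
    "MAN": "Mangroves",
}

# (Sub)tropical classification: biome name contains "tropical"/"subtropical",
# plus mangroves.  Low-seasonality biomes exempt from winter standardization.
TROPICAL_BIOMES = frozenset(
    code
    for code, name in BIOMES.items()
    if "tropical" in name.lower() or code == "MAN"
)

MEASURES = ("diversity", "density")
SEASONS = ("spring", "summer", "autumn", "winter")

RECORD_COLUMNS = (
    "record_id",
    "latitude",
    "longitude",
    "biome",
    "measure",
    "value",
    "sample_area_m2",
    "depth_upper_cm",
    "depth_lower_cm",
    "sampling_month",
    "season",
)

VALID_FLAGS = frozenset({"season", "area", "depth", "density_unit"})


def is_tropical(biome: str) -> bool:
    """Whether a biome code is (sub)tropical (incl. mangroves)."""
    return biome in TROPICAL_BIOMES


@dataclass
class SeedBankRecord:
    """One survey observation of seed bank diversity or density.

    ``value`` is a species count per sample for diversity records and a seed
    count for density records; after unit standardization density values are
    seeds per m2 (tracked by the ``density_unit`` flag).
    """

    record_id: str
    latitude: float
    longitude: float
    biome: str
    measure: str
    value: float
    sample_area_m2: float
    depth_upper_cm: float
    depth_lower_cm: float
    sampling_month: int | None = None
    season: str | None = None
    standardized_flags: set[str] = field(default_factory=set)

    def violations(self) -> list[str]:
        """Invariant violations as human-readable tags (empty if valid)."""
        v = []
        if not (isinstance(self.latitude, (int, float)) and -90 <= self.latitude <= 90):
            v.append("latitude in [-90, 90]")
        if not (isinstance(self.longitude, (int, float)) and -180 <= self.longitude <= 180):
            v.append("longitude in [-180, 180]")
        if self.biome not in BIOMES:
            v.append("biome in TEOW vocabulary")
        if self.measure not in MEASURES:
            v.append("measure in {diversity, density}")
        if not (math.isfinite(self.value) and self.value >= 0):
            v.append("value >= 0")
        if not (math.isfinite(self.sample_area_m2) and self.sample_area_m2 > 0):
            v.append("sample_area_m2 > 0")
        if not (
            math.isfinite(self.depth_upper_cm)
            and math.isfinite(self.depth_lower_cm)
            and self.depth_lower_cm > self.depth_upper_cm >= 0
        ):
            v.append("depth_lower_cm > depth_upper_cm >= 0")
        if self.sampling_month is not None and self.sampling_month not in range(1, 13):
            v.append("sampling_month in 1..12")
        if self.season is not None and self.season not in SEASONS:
            v.append("season in vocabulary")
        if not set(self.standardized_flags) <= VALID_FLAGS:
            v.append("flags in vocabulary")
        return v

    def is_valid(self) -> bool:
        return not self.violations()

    def replace(self, **changes) -> "SeedBankRecord":
        """Copy with fields changed; flags are copied, never shared."""
        if "standardized_flags" not in changes:
            changes["standardized_flags"] = set(self.standardized_flags)
        return dataclasses.replace(self, **changes)


@dataclass
class ReadReport:
    """Outcome of parsing a records file: parsed records plus row rejections."""

    records: list[SeedBankRecord]
    rejections: list[dict]  # {"row": int, "record_id": str | None, "reason": str}

    @property
    def n_parsed(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


@dataclass
class ValidationReport:
    """Per-invariant violation counts and per-biome/measure record counts."""

    n_records: int
    violation_counts: dict[str, int]
    biome_counts: dict[str, dict[str, int]]  # measure -> biome -> count
    invalid_record_ids: list[str]

    @property
    def n_violations(self) -> int:
        return sum(self.violation_counts.values())


def _parse_row(row: pd.Series) -> SeedBankRecord:
    month = row["sampling_month"]
    if pd.isna(month):
        month = None
    else:
        month = int(month)
    season = row["season"]
    if pd.isna(season) or season == "":
        season = None
    return SeedBankRecord(
        record_id=str(row["record_id"]),
        latitude=float(row["latitude"]),
        longitude=float(row["longitude"]),
        biome=str(row["biome"]),
        measure=str(row["measure"]),
        value=float(row["value"]),
        sample_area_m2=float(row["sample_area_m2"]),
        depth_upper_cm=float(row["depth_upper_cm"]),
        depth_lower_cm=float(row["depth_lower_cm"]),
        sampling_month=month,
        season=season,
    )


def read_records(path: str | Path) -> ReadReport:
    """Parse a records CSV; every row is either parsed or rejected with a reason.

    Raises ``ValueError`` if a mandatory column is missing from the header.
    """
    df = pd.read_csv(path, dtype={"record_id": str, "season": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing mandatory columns: {missing}")
    records: list[SeedBankRecord] = []
    rejections: list[dict] = []
    for i, (_, row) in enumerate(df.iterrows()):
        rid = None if pd.isna(row["record_id"]) else str(row["record_id"])
        try:
            rec = _parse_row(row)
        except (ValueError, TypeError) as exc:
            rejections.append({"row": i, "record_id": rid, "reason": f"unparseable: {exc}"})
            continue
        bad = rec.violations()
        if bad:
            rejections.append({"row": i, "record_id": rid, "reason": "; ".join(bad)})
        else:
            records.append(rec)
    return ReadReport(records=records, rejections=rejections)


def records_to_frame(records: Iterable[SeedBankRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "biome": r.biome,
                "measure": r.measure,
                "value": r.value,
                "sample_area_m2": r.sample_area_m2,
                "depth_upper_cm": r.depth_upper_cm,
                "depth_lower_cm": r.depth_lower_cm,
                "sampling_month": r.sampling_month,
                "season": r.season,
            }
        )
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    if not df.empty:
        df["sampling_month"] = df["sampling_month"].astype("Int64")
    return df


def frame_to_records(df: pd.DataFrame) -> list[SeedBankRecord]:
    return [_parse_row(row) for _, row in df.iterrows()]


def write_records(records: Iterable[SeedBankRecord], path: str | Path) -> None:
    """Write records as CSV with the canonical column order.

    Missing month/season become empty cells.  Round trips losslessly through
    :func:`read_records` for valid records.
    """
    df = records_to_frame(records)
    df.to_csv(path, index=False, na_rep="")


def validate_dataset(records: Sequence[SeedBankRecord]) -> ValidationReport:
    """Count invariant violations and tabulate records per biome and measure."""
    violation_counts: dict[str, int] = {}
    invalid_ids: list[str] = []
    biome_counts: dict[str, dict[str, int]] = {m: {} for m in MEASURES}
    for rec in records:
        bad = rec.violations()
        if bad:
            invalid_ids.append(rec.record_id)
            for tag in bad:
                violation_counts[tag] = violation_counts.get(tag, 0) + 1
        if rec.measure in biome_counts:
            bc = biome_counts[rec.measure]
            bc[rec.biome] = bc.get(rec.biome, 0) + 1
    return ValidationReport(
        n_records=len(records),
        violation_counts=violation_counts,
        biome_counts=biome_counts,
        invalid_record_ids=invalid_ids,
    )


def read_predictor_table(path: str | Path) -> pd.DataFrame:
    """Read the per-record table of the 31 environmental covariates.

    Keyed by ``record_id``.  A row with any missing covariate is kept (the
    modeling stage drops incomplete rows and counts them) but basic range
    invariants are enforced: absolute latitude in [0, 90], percentages in
    [0, 100], pH in [0, 14].
    """
    df = pd.read_csv(path, dtype={"record_id": str})
    if "record_id" not in df.columns:
        raise ValueError("predictor table must have a record_id column")
    missing = [c for c in PREDICTOR_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"predictor table missing covariates: {missing}")
    df = df.set_index("record_id")[list(PREDICTOR_NAMES)]
    _check_predictor_ranges(df)
    return df


def _check_predictor_ranges(df: pd.DataFrame) -> None:
    def bad(col, lo, hi):
        s = df[col].dropna()
        return ((s < lo) | (s > hi)).any()

    if bad("abs.latit", 0, 90):
        raise ValueError("abs.latit outside [0, 90]")
    if bad("pH", 0, 14):
        raise ValueError("pH outside [0, 14]")
    for col in PERCENTAGE_PREDICTORS:
        if bad(col, 0, 100):
            raise ValueError(f"{col} outside [0, 100]")


def write_predictor_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index() if df.index.name == "record_id" else df
    out.to_csv(path, index=False, na_rep="")
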