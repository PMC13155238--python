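"""Ingest, quality-flag, harmonise and aggregate occurrence archives.

The analysis frame is a country x substrate x species record-count table
restricted to observed combinations (y > 0; absences are never imputed).  For
each country x substrate cell the total record count supplies the sampling
effort context; each species row carries a leave-one-out exposure (cell total
minus the focal species' own records) whose logarithm is the model offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .vocab import SUBSTRATE_CODES, SubstrateVocabulary

#: Default small constant added to the leave-one-out exposure before the log,
#: guaranteeing a finite offset for single-record cells (exposure 0).
OFFSET_CONSTANT = 1.0

#: Exposure below which a cell is flagged as descriptive-only.
LOW_EXPOSURE_THRESHOLD = 5

#: Substrate record total below which the pre-declared rarity rule applies.
RARE_SUBSTRATE_THRESHOLD = 100

#: Observation window of archives in the study's style (configurable).
DEFAULT_YEAR_BOUNDS = (1857, 2025)

OPTIONAL_FIELDS = (
    "species",
    "substrateCategory",
    "decimalLatitude",
    "decimalLongitude",
    "minimumElevationInMeters",
    "maximumElevationInMeters",
    "pH",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for all displayed percentages/scores."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def read_archive(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a CSV/TSV occurrence table, optionally renaming columns.

    ``column_map`` maps source column names to the Darwin-Core-style names
    used throughout (country, year, species, genus, family, order,
    microhabitat, substrateCategory, decimalLatitude, decimalLongitude,
    minimumElevationInMeters, maximumElevationInMeters, pH).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    return df


@dataclass
class CompletenessSummary:
    """Per-field missingness of an occurrence table."""

    n_records: int
    n_species: int
    missing_counts: dict[str, int] = field(default_factory=dict)
    missing_percent: dict[str, float] = field(default_factory=dict)
    range_violations: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "field": f,
                "missing": self.missing_counts[f],
                "missing_percent": self.missing_percent[f],
                "range_violations": self.range_violations.get(f, 0),
            }
            for f in self.missing_counts
        ]
        return pd.DataFrame(rows)


def quality_flags(
    records: pd.DataFrame,
    year_bounds: tuple[int, int] = DEFAULT_YEAR_BOUNDS,
) -> tuple[pd.DataFrame, CompletenessSummary]:
    """Range-check and missingness-profile an occurrence table.

    Records with missing species or substrate are flagged but retained; range
    violations (year outside the window, coordinates off the globe, pH outside
    [0, 14], min elevation above max) set boolean flag columns.
    """
    df = records.copy()
    n = len(df)

    missing_counts: dict[str, int] = {}
    missing_percent: dict[str, float] = {}
    violations: dict[str, int] = {}

    for fieldname in OPTIONAL_FIELDS:
        if fieldname in df.columns:
            miss = int(df[fieldname].isna().sum())
            if df[fieldname].dtype == object:
                miss = int((df[fieldname].isna() | (df[fieldname] == "")).sum())
        else:
            miss = n
        missing_counts[fieldname] = miss
        missing_percent[fieldname] = round_half_up(100.0 * miss / n) if n else np.nan

    def _viol(col, ok):
        present = df[col].notna()
        bad = present & ~ok
        violations[col] = int(bad.sum())
        return bad

    df["flag_missing_species"] = (
        df["species"].isna() if "species" in df else pd.Series(True, index=df.index)
    )
    df["flag_missing_substrate"] = (
        df["substrateCategory"].isna()
        if "substrateCategory" in df
        else pd.Series(True, index=df.index)
    )

    if "year" in df.columns:
        y = pd.to_numeric(df["year"], errors="coerce")
        df["flag_year_range"] = _viol("year", (y >= year_bounds[0]) & (y <= year_bounds[1]))
    if "decimalLatitude" in df.columns:
        lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")
        df["flag_lat_range"] = _viol("decimalLatitude", lat.abs() <= 90)
    if "decimalLongitude" in df.columns:
        lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
        df["flag_lon_range"] = _viol("decimalLongitude", lon.abs() <= 180)
    if "pH" in df.columns:
        ph = pd.to_numeric(df["pH"], errors="coerce")
        df["flag_ph_range"] = _viol("pH", (ph >= 0) & (ph <= 14))
    if {"minimumElevationInMeters", "maximumElevationInMeters"} <= set(df.columns):
        lo = pd.to_numeric(df["minimumElevationInMeters"], errors="coerce")
        hi = pd.to_numeric(df["maximumElevationInMeters"], errors="coerce")
        both = lo.notna() & hi.notna()
        bad = both & (lo > hi)
        violations["elevation"] = int(bad.sum())
        df["flag_elevation_order"] = bad

    n_species = int(df["species"].dropna().nunique()) if "species" in df else 0
    summary = CompletenessSummary(
        n_records=n,
        n_species=n_species,
        missing_counts=missing_counts,
        missing_percent=missing_percent,
        range_violations=violations,
    )
    return df, summary


def elevation_mid(minimum, maximum):
    """Midpoint elevation: (min + max) / 2 where both bounds are available.

    Returns NaN when either bound is missing or min > max (flagged upstream).
    Accepts scalars or aligned Series.
    """
    scalar_in = not isinstance(minimum, (pd.Series, np.ndarray, list))
    lo = pd.to_numeric(pd.Series([minimum]) if scalar_in else pd.Series(minimum), errors="coerce")
    hi = pd.to_numeric(pd.Series([maximum]) if scalar_in else pd.Series(maximum), errors="coerce")
    hi.index = lo.index
    mid = (lo + hi) / 2.0
    mid = mid.where(lo <= hi)
    if scalar_in:
        return float(mid.iloc[0]) if mid.notna().iloc[0] else np.nan
    return mid


def add_elevation_mid(records: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``elevationMid`` column to a copy of the table."""
    df = records.copy()
    df["elevationMid"] = elevation_mid(
        df.get("minimumElevationInMeters"), df.get("maximumElevationInMeters")
    )
    return df


#: pH band labels and display names; the bands are <=5.00, (5.00, 7.00], >=7.01.
PH_BANDS = ("acid", "mid", "alkaline")
PH_BAND_DISPLAY = {"acid": "<=5.00", "mid": "5.01-7.00", "alkaline": ">=7.01"}


def band_ph(ph):
    """Discretise pH into acid (<=5.00), mid (5.01-7.00), alkaline (>=7.01)."""
    if np.isscalar(ph) or ph is None:
        val = pd.to_numeric(pd.Series([ph]), errors="coerce").iloc[0]
        if pd.isna(val):
            return None
        return "acid" if val <= 5.00 else ("mid" if val <= 7.00 else "alkaline")
    vals = pd.to_numeric(ph, errors="coerce")
    out = pd.Series(pd.NA, index=vals.index, dtype="object")
    out[vals <= 5.00] = "acid"
    out[(vals > 5.00) & (vals <= 7.00)] = "mid"
    out[vals > 7.00] = "alkaline"
    return out


def harmonise_table(
    records: pd.DataFrame, vocab: SubstrateVocabulary | None = None
) -> pd.DataFrame:
    """Fill missing substrateCategory from verbatim microhabitat descriptors.

    Existing codes are kept; unmapped or ambiguous descriptors stay missing.
    The verbatim text is always preserved.
    """
    vocab = vocab or SubstrateVocabulary()
    df = records.copy()
    if "substrateCategory" not in df.columns:
        df["substrateCategory"] = pd.NA
    if "microhabitat" in df.columns:
        need = df["substrateCategory"].isna() & df["microhabitat"].notna()
        mapped = df.loc[need, "microhabitat"].map(vocab.harmonise)
        df.loc[need, "substrateCategory"] = mapped
    bad = df["substrateCategory"].notna() & ~df["substrateCategory"].isin(SUBSTRATE_CODES)
    df.loc[bad, "substrateCategory"] = pd.NA
    return df


def aggregate_counts(
    records: pd.DataFrame,
    taxon_col: str = "species",
    offset_constant: float = OFFSET_CONSTANT,
    low_exposure_threshold: int = LOW_EXPOSURE_THRESHOLD,
    rare_substrate_threshold: int = RARE_SUBSTRATE_THRESHOLD,
) -> pd.DataFrame:
    """Aggregate records to a country x substrate x taxon count frame.

    Only rows with non-missing taxon and substrateCategory contribute; only
    observed combinations appear (y >= 1).  Columns:

    country, substrateCategory, <taxon_col>, y, cell_total, exposure
    (leave-one-out: cell_total - y), log_offset (log(exposure + c)),
    low_exposure, rare_substrate.
    """
    cols = ["country", "substrateCategory", taxon_col]
    df = records.dropna(subset=[c for c in cols if c in records.columns])
    if df.empty:
        return pd.DataFrame(
            columns=cols
            + ["y", "cell_total", "exposure", "log_offset", "low_exposure", "rare_substrate"]
        )
    frame = (
        df.groupby(cols, observed=True).size().rename("y").reset_index()
    )
    cell = frame.groupby(["country", "substrateCategory"], observed=True)["y"].transform("sum")
    frame["cell_total"] = cell
    frame["exposure"] = frame["cell_total"] - frame["y"]
    frame["log_offset"] = np.log(frame["exposure"] + offset_constant)
    frame["low_exposure"] = frame["exposure"] < low_exposure_threshold
    substrate_total = frame.groupby("substrateCategory", observed=True)["y"].transform("sum")
    frame["rare_substrate"] = substrate_total < rare_substrate_threshold
    return frame.sort_values(cols).reset_index(drop=True)
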