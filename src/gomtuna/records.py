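"""Logbook record I/O: schemas, validation and the study's inclusion filters.

Three comma-delimited, UTF-8 schemas are used throughout:

* schools:  ``date,latitude,longitude,n_fish`` — one predator-school sighting
  or catch per row; retained rows must fall inside the Jun 1-Oct 31 window,
  the study box, and carry more than two fish.
* herring:  ``date,latitude,longitude,tonnage_mt,gear,zone`` — one prey-catch
  position weighted by metric tons; purse-seine/trawl gear in zones 1A/1B/3.
* survey:   ``year,season,mean_per_tow`` — the bottom-trawl abundance index.

Readers drop (and log, with a reason) records violating the filters; rows
that cannot be parsed at all raise with their file line number.
"""
from __future__ import annotations

import datetime as dt
import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calendar import day_of_year, season_window
from .domain import SpatialDomain

__all__ = [
    "GEAR_TYPES",
    "ZONES",
    "SEASONS",
    "read_schools",
    "write_schools",
    "filter_schools",
    "read_herring",
    "write_herring",
    "filter_herring",
    "read_survey",
    "write_survey",
]

logger = logging.getLogger(__name__)

GEAR_TYPES = ("purse_seine", "trawl")
ZONES = ("1A", "1B", "3")
SEASONS = ("spring", "autumn")

SCHOOL_COLUMNS = ["date", "latitude", "longitude", "n_fish"]
HERRING_COLUMNS = ["date", "latitude", "longitude", "tonnage_mt", "gear", "zone"]
SURVEY_COLUMNS = ["year", "season", "mean_per_tow"]

MIN_FISH = 3  # "more than two fish" per school


def _parse_date(value: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(f"line {line}: unparseable date {value!r}") from exc


def _parse_number(value, line: int, kind, name: str):
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"line {line}: malformed {name} {value!r}") from exc


def _read_raw(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match schema {columns}"
        )
    return df


def filter_schools(df: pd.DataFrame, domain: SpatialDomain | None = None):
    """Apply the inclusion filters; return (kept, dropped-with-reason)."""
    domain = domain or SpatialDomain()
    reasons = pd.Series("", index=df.index, dtype=object)
    in_window = df["date"].map(lambda d: season_window(d.year)[0] <= d <= season_window(d.year)[1])
    reasons[~in_window] = "outside Jun 1-Oct 31 window"
    in_domain = domain.contains(df["latitude"].to_numpy(), df["longitude"].to_numpy())
    reasons[(reasons == "") & ~in_domain] = "outside study domain"
    too_few = df["n_fish"] < MIN_FISH
    reasons[(reasons == "") & too_few] = "fewer than three fish"
    dropped = df[reasons != ""].assign(reason=reasons[reasons != ""])
    kept = df[reasons == ""].reset_index(drop=True)
    for _, row in dropped.iterrows():
        logger.info("dropped school record %s: %s", row["date"], row["reason"])
    return kept, dropped.reset_index(drop=True)


def read_schools(path, domain: SpatialDomain | None = None, return_dropped: bool = False):
    """Read, validate and filter a schools CSV.

    Adds derived ``year`` and ``day_of_year`` columns used by the GLM.
    """
    raw = _read_raw(path, SCHOOL_COLUMNS)
    rows = []
    for idx, row in raw.iterrows():
        line = idx + 2  # header is line 1
        rows.append(
            {
                "date": _parse_date(row["date"], line),
                "latitude": _parse_number(row["latitude"], line, float, "latitude"),
                "longitude": _parse_number(row["longitude"], line, float, "longitude"),
                "n_fish": _parse_number(row["n_fish"], line, int, "n_fish"),
            }
        )
    df = pd.DataFrame(rows, columns=SCHOOL_COLUMNS)
    kept, dropped = filter_schools(df, domain)
    kept["year"] = kept["date"].map(lambda d: d.year)
    kept["day_of_year"] = kept["date"].map(day_of_year)
    return (kept, dropped) if return_dropped else kept


def write_schools(df: pd.DataFrame, path) -> None:
    """ISO-8601 dates, 4-decimal coordinates."""
    out = pd.DataFrame(
        {
            "date": df["date"].map(lambda d: d.isoformat()),
            "latitude": df["latitude"].map(lambda v: f"{v:.4f}"),
            "longitude": df["longitude"].map(lambda v: f"{v:.4f}"),
            "n_fish": df["n_fish"].astype(int),
        }
    )
    out.to_csv(path, index=False)


def filter_herring(df: pd.DataFrame, domain: SpatialDomain | None = None):
    domain = domain or SpatialDomain()
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[~(df["tonnage_mt"] > 0)] = "non-positive tonnage"
    reasons[(reasons == "") & ~df["gear"].isin(GEAR_TYPES)] = "gear outside purse_seine/trawl"
    reasons[(reasons == "") & ~df["zone"].isin(ZONES)] = "zone outside 1A/1B/3"
    in_domain = domain.contains(df["latitude"].to_numpy(), df["longitude"].to_numpy())
    reasons[(reasons == "") & ~in_domain] = "outside study domain"
    dropped = df[reasons != ""].assign(reason=reasons[reasons != ""])
    kept = df[reasons == ""].reset_index(drop=True)
    for _, row in dropped.iterrows():
        logger.info("dropped herring record %s: %s", row["date"], row["reason"])
    return kept, dropped.reset_index(drop=True)


def read_herring(path, domain: SpatialDomain | None = None, return_dropped: bool = False):
    raw = _read_raw(path, HERRING_COLUMNS)
    rows = []
    for idx, row in raw.iterrows():
        line = idx + 2
        rows.append(
            {
                "date": _parse_date(row["date"], line),
                "latitude": _parse_number(row["latitude"], line, float, "latitude"),
                "longitude": _parse_number(row["longitude"], line, float, "longitude"),
                "tonnage_mt": _parse_number(row["tonnage_mt"], line, float, "tonnage_mt"),
                "gear": str(row["gear"]).strip(),
                "zone": str(row["zone"]).strip(),
            }
        )
    df = pd.DataFrame(rows, columns=HERRING_COLUMNS)
    kept, dropped = filter_herring(df, domain)
    return (kept, dropped) if return_dropped else kept


def write_herring(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "date": df["date"].map(lambda d: d.isoformat()),
            "latitude": df["latitude"].map(lambda v: f"{v:.4f}"),
            "longitude": df["longitude"].map(lambda v: f"{v:.4f}"),
            "tonnage_mt": df["tonnage_mt"].map(lambda v: f"{v:.4f}"),
            "gear": df["gear"],
            "zone": df["zone"],
        }
    )
    out.to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    raw = _read_raw(path, SURVEY_COLUMNS)
    rows = []
    for idx, row in raw.iterrows():
        line = idx + 2
        season = str(row["season"]).strip()
        if season not in SEASONS:
            raise ValueError(f"line {line}: unknown season {season!r}")
        mean = _parse_number(row["mean_per_tow"], line, float, "mean_per_tow")
        if mean < 0:
            raise ValueError(f"line {line}: negative mean_per_tow")
        rows.append(
            {
                "year": _parse_number(row["year"], line, int, "year"),
                "season": season,
                "mean_per_tow": mean,
            }
        )
    df = pd.DataFrame(rows, columns=SURVEY_COLUMNS)
    if df.duplicated(["year", "season"]).any():
        raise ValueError("duplicate (year, season) rows in survey series")
    return df


def write_survey(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "year": df["year"].astype(int),
            "season": df["season"],
            "mean_per_tow": df["mean_per_tow"].map(lambda v: f"{v:.4f}"),
        }
    )
    out.to_csv(path, index=False)
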