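"""Annual size-weighted school centroids and their link to prey abundance.

The yearly centroid weights each school's position by its fish count;
variability is reported as the unweighted sample variance of the school
coordinates (a frequency-weighted variant is available).  Centroid
longitude is then correlated (Pearson) with the biannual mean-herring-per-
tow survey index over the common years.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnnualCentroid", "CorrelationResult", "annual_centroid",
           "annual_centroids", "correlate_index"]


@dataclass(frozen=True)
class AnnualCentroid:
    year: int
    lat: float
    lon: float
    var_lat: float   # NaN when fewer than two schools
    var_lon: float
    n_schools: int
    n_fish: int


@dataclass(frozen=True)
class CorrelationResult:
    season: str
    coordinate: str
    n: int
    r: float
    r2: float
    p_value: float


def annual_centroid(schools: pd.DataFrame, year: int,
                    weighted_variance: bool = False) -> AnnualCentroid | None:
    """Fish-count-weighted mean position for one year; None if no schools.

    Variance is the unweighted sample variance of school coordinates by
    default; ``weighted_variance`` switches to the frequency-weighted form
    (weights treated as replicate counts).
    """
    sel = schools[schools["year"] == year]
    n = len(sel)
    if n == 0:
        return None
    w = sel["n_fish"].to_numpy(float)
    lat = sel["latitude"].to_numpy(float)
    lon = sel["longitude"].to_numpy(float)
    clat = float(np.average(lat, weights=w))
    clon = float(np.average(lon, weights=w))
    if n < 2:
        vlat = vlon = float("nan")
    elif weighted_variance:
        vlat = float(np.sum(w * (lat - clat) ** 2) / (w.sum() - 1.0))
        vlon = float(np.sum(w * (lon - clon) ** 2) / (w.sum() - 1.0))
    else:
        vlat = float(np.var(lat, ddof=1))
        vlon = float(np.var(lon, ddof=1))
    return AnnualCentroid(year, clat, clon, vlat, vlon, n, int(w.sum()))


def annual_centroids(schools: pd.DataFrame,
                     weighted_variance: bool = False) -> pd.DataFrame:
    """Centroid table ``year,lat,lon,var_lat,var_lon,n_schools,n_fish``."""
    rows = []
    for year in sorted(schools["year"].unique()):
        c = annual_centroid(schools, int(year), weighted_variance=weighted_variance)
        if c is not None:
            rows.append(c.__dict__)
    return pd.DataFrame(rows, columns=["year", "lat", "lon", "var_lat", "var_lon",
                                       "n_schools", "n_fish"])


def correlate_index(centroids: pd.DataFrame, survey: pd.DataFrame, season: str,
                    coordinate: str = "lon") -> CorrelationResult:
    """Pearson correlation of centroid position with the survey index.

    Longitude is the default coordinate (the documented distribution shift
    is longitudinal); latitude is available for completeness.  Requires at
    least three common years; constant series are an error (undefined r).
    """
    if coordinate not in ("lon", "lat"):
        raise ValueError("coordinate must be 'lon' or 'lat'")
    idx = survey[survey["season"] == season]
    merged = centroids.merge(idx, on="year", how="inner")
    n = len(merged)
    if n < 3:
        raise ValueError(f"need at least 3 common years, got {n}")
    x = merged[coordinate].to_numpy(float)
    y = merged["mean_per_tow"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(season, coordinate, n, float(r), float(r * r), float(p))
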