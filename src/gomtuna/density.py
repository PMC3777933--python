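"""Weighted 2-D kernel density surfaces and percentile-mass utilization regions.

The estimator is an axis-aligned bivariate-normal kernel sum on the study
grid, with kernel standard deviation = bandwidth / 4 — the convention of the
classic quartile (normal-reference) bandwidth rule this module implements,
whose output is sized for exactly that divisor.  Other KDE conventions use
the bandwidth as the standard deviation directly and differ by a factor of
four; surfaces here always follow the /4 convention.

An alpha "percentile contour" is read as the alpha-mass highest-density
region of the normalized surface (standard utilization-distribution usage):
grid cells are accumulated in decreasing density order until their summed
probability mass reaches alpha.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calendar import SemimonthlyPeriod
from .domain import SpatialDomain

__all__ = [
    "DensitySurface",
    "UtilizationRegion",
    "SkipMarker",
    "bandwidth_quartile_rule",
    "weighted_kde",
    "utilization_region",
    "periodic_density",
    "epoch_density",
    "DEFAULT_EPOCHS",
    "MIN_RECORDS_PER_PERIOD",
]

MIN_RECORDS_PER_PERIOD = 10
DEFAULT_EPOCHS = ((1979, 1985), (1986, 1992), (1993, 1999), (2000, 2005))


@dataclass
class DensitySurface:
    """Unit-mass density on the grid: values[i_lat, i_lon] in degree^-2."""

    domain: SpatialDomain
    values: np.ndarray
    bandwidth_lon: float
    bandwidth_lat: float

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.domain.cell_area)

    def to_frame(self) -> pd.DataFrame:
        """Long-format lon,lat,density table."""
        lon, lat = np.meshgrid(self.domain.lon_nodes, self.domain.lat_nodes)
        return pd.DataFrame(
            {"lon": lon.ravel(), "lat": lat.ravel(), "density": self.values.ravel()}
        )


@dataclass
class UtilizationRegion:
    """Smallest highest-density cell set holding at least ``level`` mass."""

    level: float
    member: np.ndarray  # bool, grid-shaped
    achieved_mass: float
    domain: SpatialDomain

    @property
    def n_cells(self) -> int:
        return int(self.member.sum())


@dataclass
class SkipMarker:
    """A period/epoch that could not support a surface, with the reason."""

    label: str
    n_records: int
    reason: str


def bandwidth_quartile_rule(values) -> float:
    """Normal-reference bandwidth from the 25th/75th quantiles.

    b = 4 * 1.06 * min(sd, IQR/1.34) * n^(-1/5), with quantiles by linear
    interpolation at position 1 + (n-1)p and sd the n-1 estimator.  The
    factor 4 is consumed downstream by the sigma = b/4 kernel convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values for the quartile bandwidth rule")
    sd = float(np.std(x, ddof=1))
    q25, q75 = np.quantile(x, [0.25, 0.75])  # linear interpolation, R type 7
    iqr = float(q75 - q25)
    if sd == 0.0 and iqr == 0.0:
        raise ValueError("zero spread: supply a manual bandwidth")
    b = 4.0 * 1.06 * min(sd, iqr / 1.34) * x.size ** (-0.2)
    if b <= 0.0:
        raise ValueError("degenerate quartile spread (IQR = 0): supply a manual bandwidth")
    return b


def weighted_kde(lats, lons, weights, domain: SpatialDomain,
                 bandwidth_lat: float, bandwidth_lon: float) -> DensitySurface:
    """Weighted axis-aligned Gaussian KDE evaluated on the domain grid.

    Weights are normalized to sum to one, and the evaluated surface is then
    renormalized to unit probability mass on the (truncating) grid.
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if lats.size == 0:
        raise ValueError("empty point set")
    if np.any(weights <= 0) or weights.sum() == 0:
        raise ValueError("weights must be positive")
    if bandwidth_lat <= 0 or bandwidth_lon <= 0:
        raise ValueError("bandwidths must be positive")
    sig_lat = bandwidth_lat / 4.0
    sig_lon = bandwidth_lon / 4.0
    w = weights / weights.sum()
    norm = 1.0 / np.sqrt(2.0 * np.pi)
    a_lon = np.exp(-0.5 * ((domain.lon_nodes[None, :] - lons[:, None]) / sig_lon) ** 2) * (norm / sig_lon)
    a_lat = np.exp(-0.5 * ((domain.lat_nodes[None, :] - lats[:, None]) / sig_lat) ** 2) * (norm / sig_lat)
    values = a_lat.T @ (w[:, None] * a_lon)
    total = values.sum() * domain.cell_area
    if total <= 0:
        raise ValueError("density mass vanished on the grid (points far outside domain?)")
    return DensitySurface(domain, values / total, bandwidth_lon, bandwidth_lat)


def utilization_region(surface: DensitySurface, level: float) -> UtilizationRegion:
    """Highest-density region holding at least ``level`` of the mass.

    Cells accumulate in decreasing density order (ties broken by row-major
    node index) until the cumulative mass reaches the level, so removing the
    last-added cell would drop the region below it.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    flat = surface.values.ravel()
    order = np.argsort(-flat, kind="stable")  # stable keeps row-major order among ties
    masses = flat[order] * surface.domain.cell_area
    cum = np.cumsum(masses)
    total = cum[-1]
    target = level * total
    k = int(np.searchsorted(cum, target * (1.0 - 1e-12), side="left"))
    k = min(k, flat.size - 1)
    member = np.zeros(flat.size, dtype=bool)
    member[order[: k + 1]] = True
    return UtilizationRegion(
        level=level,
        member=member.reshape(surface.values.shape),
        achieved_mass=float(cum[k] / total),
        domain=surface.domain,
    )


def periodic_density(herring: pd.DataFrame, period: SemimonthlyPeriod,
                     domain: SpatialDomain,
                     min_records: int = MIN_RECORDS_PER_PERIOD):
    """Tonnage-weighted prey density for one semimonthly period.

    Returns a :class:`DensitySurface`, or a :class:`SkipMarker` when the
    period has too few records or degenerate coordinate spread.
    """
    sel = herring[herring["date"].map(period.contains)]
    n = len(sel)
    if n < min_records:
        return SkipMarker(period.key, n, "too few records")
    try:
        b_lon = bandwidth_quartile_rule(sel["longitude"].to_numpy())
        b_lat = bandwidth_quartile_rule(sel["latitude"].to_numpy())
    except ValueError as exc:
        return SkipMarker(period.key, n, f"degenerate spread: {exc}")
    return weighted_kde(
        sel["latitude"].to_numpy(), sel["longitude"].to_numpy(),
        sel["tonnage_mt"].to_numpy(), domain, b_lat, b_lon,
    )


def epoch_density(schools: pd.DataFrame, domain: SpatialDomain,
                  epochs=DEFAULT_EPOCHS):
    """Fish-count-weighted predator density per multi-year epoch.

    Returns an ordered dict epoch -> DensitySurface (or SkipMarker for
    empty/degenerate epochs).
    """
    out = {}
    for y0, y1 in epochs:
        label = f"{y0}-{y1}"
        sel = schools[(schools["year"] >= y0) & (schools["year"] <= y1)]
        n = len(sel)
        if n == 0:
            out[(y0, y1)] = SkipMarker(label, 0, "no schools in epoch")
            continue
        if n == 1:
            # single point: no data-driven bandwidth; use one grid-cell scale
            b_lat = b_lon = 4.0 * max(domain.dlat, domain.dlon)
        else:
            try:
                b_lon = bandwidth_quartile_rule(sel["longitude"].to_numpy())
                b_lat = bandwidth_quartile_rule(sel["latitude"].to_numpy())
            except ValueError as exc:
                out[(y0, y1)] = SkipMarker(label, n, f"degenerate spread: {exc}")
                continue
        out[(y0, y1)] = weighted_kde(
            sel["latitude"].to_numpy(), sel["longitude"].to_numpy(),
            sel["n_fish"].to_numpy(float), domain, b_lat, b_lon,
        )
    return out
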