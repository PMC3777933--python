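"""Study-area grid and land/bathymetry masking.

The analysis domain is the Gulf of Maine box 39-45 deg N, 71-65 deg W,
discretized on a regular lat/lon node grid (default 500 x 500).  Grid nodes
double as cell centres: every node owns a rectangular cell of size
``dlat x dlon`` and probability mass on a density surface is
``value * cell_area`` (degree^2).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpatialDomain", "LandMask", "generate_land_mask", "DEFAULT_COAST_POLYLINE"]


@dataclass(frozen=True)
class SpatialDomain:
    """Regular lat/lon grid over the study box.

    Coordinates are decimal degrees, west negative.  Nodes are generated with
    ``linspace`` so the bounds are themselves nodes; cell size is
    ``span / (n - 1)`` per axis.
    """

    lat_min: float = 39.0
    lat_max: float = 45.0
    lon_min: float = -71.0
    lon_max: float = -65.0
    n_lat: int = 500
    n_lon: int = 500

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("domain bounds must be strictly ordered")
        if self.n_lat < 2 or self.n_lon < 2:
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def lat_nodes(self) -> np.ndarray:
        return np.linspace(self.lat_min, self.lat_max, self.n_lat)

    @property
    def lon_nodes(self) -> np.ndarray:
        return np.linspace(self.lon_min, self.lon_max, self.n_lon)

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / (self.n_lat - 1)

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / (self.n_lon - 1)

    @property
    def cell_area(self) -> float:
        """Cell area in degree^2 (planar; used only for grid-mass bookkeeping)."""
        return self.dlat * self.dlon

    def contains(self, lat, lon):
        lat = np.asarray(lat)
        lon = np.asarray(lon)
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )

    def node_index(self, lat, lon):
        """Indices (i_lat, i_lon) of the node whose cell contains the point."""
        i = np.clip(np.rint((np.asarray(lat) - self.lat_min) / self.dlat).astype(int), 0, self.n_lat - 1)
        j = np.clip(np.rint((np.asarray(lon) - self.lon_min) / self.dlon).astype(int), 0, self.n_lon - 1)
        return i, j

    def with_resolution(self, n_lat: int, n_lon: int | None = None) -> "SpatialDomain":
        return SpatialDomain(
            self.lat_min, self.lat_max, self.lon_min, self.lon_max,
            n_lat, n_lon if n_lon is not None else n_lat,
        )


@dataclass
class LandMask:
    """Boolean exclusion field on the analysis grid.

    ``excluded[i_lat, i_lon]`` is True where points must not be placed
    (land, estuaries, shallow water).  Rows run south to north, columns west
    to east, matching :class:`SpatialDomain` node order.
    """

    domain: SpatialDomain
    excluded: np.ndarray

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.excluded.shape != (self.domain.n_lat, self.domain.n_lon):
            raise ValueError("mask shape must match the domain grid")
        if self.excluded.all():
            raise ValueError("mask excludes the whole domain")

    @property
    def fraction_excluded(self) -> float:
        return float(self.excluded.mean())

    def is_excluded(self, lat, lon):
        i, j = self.domain.node_index(lat, lon)
        return self.excluded[i, j]

    def write(self, path) -> None:
        """Plain-text 0/1 grid with a 4-line header (bounds, grid size, legend)."""
        d = self.domain
        lines = [
            f"{d.lon_min:.6f} {d.lon_max:.6f}",
            f"{d.lat_min:.6f} {d.lat_max:.6f}",
            f"{d.n_lon} {d.n_lat}",
            "# 0=water 1=excluded; rows south->north, columns west->east",
        ]
        body = "\n".join("".join("1" if v else "0" for v in row) for row in self.excluded)
        Path(path).write_text("\n".join(lines) + "\n" + body + "\n")

    @classmethod
    def read(cls, path) -> "LandMask":
        lines = Path(path).read_text().splitlines()
        lon_min, lon_max = map(float, lines[0].split())
        lat_min, lat_max = map(float, lines[1].split())
        n_lon, n_lat = map(int, lines[2].split())
        grid = np.array([[c == "1" for c in row] for row in lines[4 : 4 + n_lat]])
        domain = SpatialDomain(lat_min, lat_max, lon_min, lon_max, n_lat, n_lon)
        return cls(domain, grid)


#: Synthetic "coastline": everything north-west of this polyline is excluded.
#: Chosen so roughly 15% of the default grid is masked, mimicking the
#: land/estuary band along the western Gulf of Maine.
DEFAULT_COAST_POLYLINE = ((-71.0, 41.8), (-68.0, 45.0))


def generate_land_mask(domain: SpatialDomain, polyline=DEFAULT_COAST_POLYLINE) -> LandMask:
    """Deterministic synthetic land/bathymetry mask.

    A grid cell is excluded when it lies north of the piecewise-linear
    threshold ``lat = f(lon)`` defined by ``polyline`` (lon ascending).  A
    polyline entirely above the domain yields an all-water mask.
    """
    polyline = sorted(polyline)
    xs = np.array([p[0] for p in polyline], dtype=float)
    ys = np.array([p[1] for p in polyline], dtype=float)
    threshold = np.interp(domain.lon_nodes, xs, ys)
    excluded = domain.lat_nodes[:, None] > threshold[None, :]
    return LandMask(domain, excluded)
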