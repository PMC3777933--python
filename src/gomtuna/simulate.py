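"""Synthetic logbook, prey-catch, survey-index and mask generators.

The generators emulate the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without the (proprietary) source
data:

* herring catches cluster in a handful of Gaussian hotspots that drift
  eastward at a fixed rate (degrees longitude per year);
* predator schools are attracted to the same hotspots with probability
  ``attraction`` (otherwise uniform over open water), with overdispersed
  negative-binomial school sizes floored at three fish;
* the biannual survey index is affine in the yearly mean hotspot longitude
  plus Gaussian noise, so its squared correlation with position has a
  closed form used in tests.

Each generator draws from its own RNG stream derived from ``(seed, op
name)``, so adding an operation never perturbs the draws of another.
"""
from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calendar import SemimonthlyPeriod, semimonthly_periods
from .domain import LandMask, SpatialDomain, generate_land_mask
from .records import GEAR_TYPES, SEASONS, ZONES

__all__ = ["SimConfig", "hotspot_centers", "generate_herring", "generate_schools",
           "generate_survey_index", "generate_land_mask", "simulate_all"]

_REJECTION_CAP = 10**6  # max draws for one record's position


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic decade.

    Defaults mirror the scale of the source fishery: a 1996-2005 decade,
    three herring hotspots spanning the western Gulf of Maine to Georges
    Bank, ~30 prey-catch positions per semimonthly period, ~3 predator
    schools per period averaging 69 fish with strong overdispersion, and a
    slow eastward hotspot drift of 0.1 deg longitude per year.
    """

    first_year: int = 1996
    last_year: int = 2005
    #: (lat deg, lon deg, spread deg) per hotspot
    hotspots: tuple = ((42.2, -70.4, 0.25), (43.5, -69.3, 0.30), (41.5, -68.4, 0.35))
    drift_rate: float = 0.1  # deg lon / year, eastward positive
    n_herring_per_period: int = 30
    tonnage_logmean: float = 3.0
    tonnage_logsd: float = 1.0
    n_schools_per_period: int = 3
    attraction: float = 0.9
    jitter: float = 0.15  # deg, isotropic school displacement from hotspot
    school_mean: float = 69.0
    school_dispersion: float = 1.5  # NB size; variance = mean + mean^2/dispersion
    survey_intercept: float = 3600.0
    survey_slope: float = 50.0  # index units per deg lon, > 0 links index to drift
    survey_noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.first_year > self.last_year:
            raise ValueError("first_year must not exceed last_year")
        if not self.hotspots:
            raise ValueError("at least one hotspot is required")
        dom = SpatialDomain()
        for lat, lon, spread in self.hotspots:
            if spread < 0:
                raise ValueError("hotspot spread must be >= 0")
            if not dom.contains(lat, lon):
                raise ValueError(f"hotspot ({lat}, {lon}) outside the study domain")
        if not 0.0 <= self.attraction <= 1.0:
            raise ValueError("attraction must lie in [0, 1]")
        for name in ("n_herring_per_period", "n_schools_per_period"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tonnage_logsd", "jitter", "survey_noise_sd", "school_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)


def _stream(config: SimConfig, op: str) -> np.random.Generator:
    """Independent RNG stream for one generator operation."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(op.encode())])
    )


def hotspot_centers(config: SimConfig, year: int) -> list[tuple[float, float, float]]:
    """Hotspot (lat, lon, spread) after eastward drift to ``year``."""
    shift = config.drift_rate * (year - config.first_year)
    return [(lat, lon + shift, spread) for lat, lon, spread in config.hotspots]


def mean_hotspot_longitude(config: SimConfig, year: int) -> float:
    return float(np.mean([lon for _, lon, _ in hotspot_centers(config, year)]))


def _rejection_position(rng, draw, domain: SpatialDomain, mask: LandMask | None):
    """Draw positions until one lands in-domain and off-mask (capped)."""
    for _ in range(_REJECTION_CAP):
        lat, lon = draw(rng)
        if not domain.contains(lat, lon):
            continue
        if mask is not None and mask.is_excluded(lat, lon):
            continue
        return float(lat), float(lon)
    raise RuntimeError("rejection sampling exceeded the draw cap; mask too restrictive?")


def _uniform_dates(rng, period: SemimonthlyPeriod, n: int) -> list[dt.date]:
    span = (period.end - period.start).days + 1
    offs = rng.integers(0, span, size=n)
    return [period.start + dt.timedelta(days=int(o)) for o in offs]


def generate_herring(config: SimConfig, domain: SpatialDomain | None = None,
                     mask: LandMask | None = None) -> pd.DataFrame:
    """Prey-catch records clustered in drifting hotspots.

    Per semimonthly period, ``n_herring_per_period`` positions are drawn from
    an equal-weight mixture of isotropic Gaussians at the drifted hotspot
    centres, truncated to the domain and off-mask by rejection.  Tonnage is
    lognormal; gear and zone are drawn uniformly from the allowed sets.
    """
    domain = domain or SpatialDomain()
    if mask is not None and mask.excluded.all():
        raise ValueError("mask covers the whole domain")
    rng = _stream(config, "herring")
    rows = []
    for period in semimonthly_periods(config.first_year, config.last_year):
        centers = hotspot_centers(config, period.year)
        dates = _uniform_dates(rng, period, config.n_herring_per_period)
        for date in dates:
            k = int(rng.integers(len(centers)))
            clat, clon, spread = centers[k]

            def draw(r, clat=clat, clon=clon, spread=spread):
                return clat + r.normal(0.0, spread), clon + r.normal(0.0, spread)

            lat, lon = _rejection_position(rng, draw, domain, mask)
            rows.append(
                {
                    "date": date,
                    "latitude": round(lat, 4),
                    "longitude": round(lon, 4),
                    "tonnage_mt": round(float(rng.lognormal(config.tonnage_logmean, config.tonnage_logsd)), 4),
                    "gear": GEAR_TYPES[int(rng.integers(len(GEAR_TYPES)))],
                    "zone": ZONES[int(rng.integers(len(ZONES)))],
                }
            )
    return pd.DataFrame(rows, columns=["date", "latitude", "longitude", "tonnage_mt", "gear", "zone"])


def _school_size(rng, mean: float, dispersion: float) -> int:
    """Negative-binomial (or Poisson in the infinite-dispersion limit) draw, floored at 3."""
    for _ in range(_REJECTION_CAP):
        if np.isinf(dispersion):
            n = int(rng.poisson(mean))
        else:
            p = dispersion / (dispersion + mean)
            n = int(rng.negative_binomial(dispersion, p))
        if n >= 3:
            return n
    raise RuntimeError("school-size resampling exceeded the draw cap")


def generate_schools(config: SimConfig, domain: SpatialDomain | None = None,
                     mask: LandMask | None = None) -> pd.DataFrame:
    """Predator-school records attracted to the drifting prey hotspots.

    With probability ``attraction`` a school sits at a hotspot centre plus
    isotropic Gaussian jitter; otherwise it is uniform over unmasked water.
    School sizes are overdispersed counts of at least three fish.
    """
    domain = domain or SpatialDomain()
    if config.school_mean <= 0:
        raise ValueError("school_mean must be positive")
    rng = _stream(config, "schools")
    rows = []
    for period in semimonthly_periods(config.first_year, config.last_year):
        centers = hotspot_centers(config, period.year)
        dates = _uniform_dates(rng, period, config.n_schools_per_period)
        for date in dates:
            if rng.random() < config.attraction:
                k = int(rng.integers(len(centers)))
                clat, clon, _ = centers[k]

                def draw(r, clat=clat, clon=clon):
                    return clat + r.normal(0.0, config.jitter), clon + r.normal(0.0, config.jitter)

            else:

                def draw(r):
                    return (
                        r.uniform(domain.lat_min, domain.lat_max),
                        r.uniform(domain.lon_min, domain.lon_max),
                    )

            lat, lon = _rejection_position(rng, draw, domain, mask)
            rows.append(
                {
                    "date": date,
                    "latitude": round(lat, 4),
                    "longitude": round(lon, 4),
                    "n_fish": _school_size(rng, config.school_mean, config.school_dispersion),
                }
            )
    df = pd.DataFrame(rows, columns=["date", "latitude", "longitude", "n_fish"])
    df["year"] = df["date"].map(lambda d: d.year)
    df["day_of_year"] = df["date"].map(lambda d: d.timetuple().tm_yday)
    return df


def generate_survey_index(config: SimConfig) -> pd.DataFrame:
    """Spring and autumn mean-herring-per-tow series.

    index(year, season) = a + b * mean hotspot longitude(year) + N(0, sd),
    clamped at zero, so positive ``b`` ties the index to the eastward drift.
    """
    rng = _stream(config, "survey")
    rows = []
    for season in SEASONS:
        for year in config.years:
            value = (
                config.survey_intercept
                + config.survey_slope * mean_hotspot_longitude(config, year)
                + rng.normal(0.0, config.survey_noise_sd)
            )
            rows.append({"year": year, "season": season, "mean_per_tow": max(0.0, round(value, 4))})
    return pd.DataFrame(rows, columns=["year", "season", "mean_per_tow"])


def simulate_all(config: SimConfig, domain: SpatialDomain | None = None):
    """Generate mask, herring, schools and survey index in one call."""
    domain = domain or SpatialDomain()
    mask = generate_land_mask(domain)
    herring = generate_herring(config, domain, mask)
    schools = generate_schools(config, domain, mask)
    survey = generate_survey_index(config)
    return {"mask": mask, "herring": herring, "schools": schools, "survey": survey}
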