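"""Spatial null-model test of predator-prey association.

Per semimonthly period, the prey utilization distribution is estimated and
its 95%-mass region extracted; geodesic distances to that region are
computed for the observed predator schools and for twice as many random
points drawn uniformly over unmasked water (the null).  Pooled over all
usable periods, a linear model ``distance ~ group`` asks whether observed
schools sit significantly closer to prey concentrations than random points
would ("observed closer": positive random-minus-observed effect at the
chosen level).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from .calendar import semimonthly_periods
from .density import SkipMarker, periodic_density, utilization_region
from .domain import LandMask, SpatialDomain
from .geo import haversine_km

__all__ = [
    "AssociationResult",
    "distance_to_region",
    "region_distances",
    "sample_random_points",
    "association_test",
    "run_association",
]

_RANDOM_CAP = 10**6


@dataclass
class AssociationResult:
    """Pooled distance samples and the group-effect test."""

    samples: pd.DataFrame            # period,group,lat,lon,distance_km,inside
    effect_km: float                 # random minus observed mean distance
    t_stat: float
    p_value: float
    observed_closer: bool            # effect > 0 and p < alpha
    alpha: float
    n_observed: int
    n_random: int
    periods_evaluated: int
    periods_skipped: list = field(default_factory=list)   # (period key, reason)
    periods_with_school_inside: int = 0
    schools_inside: int = 0

    def to_dict(self) -> dict:
        return {
            "effect_km": self.effect_km,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "observed_closer": bool(self.observed_closer),
            "alpha": self.alpha,
            "n_observed": self.n_observed,
            "n_random": self.n_random,
            "periods_evaluated": self.periods_evaluated,
            "periods_skipped": [list(s) for s in self.periods_skipped],
            "periods_with_school_inside": self.periods_with_school_inside,
            "schools_inside": self.schools_inside,
        }


def _boundary_nodes(region) -> tuple[np.ndarray, np.ndarray]:
    """Lat/lon of member cells adjacent to a non-member (or the grid edge).

    The nearest member node to any exterior point lies on this boundary, so
    distances can be minimized over it instead of the full member set.
    """
    member = region.member
    interior = ndimage.binary_erosion(member, border_value=0)
    boundary = member & ~interior
    if not boundary.any():
        boundary = member
    ii, jj = np.nonzero(boundary)
    return region.domain.lat_nodes[ii], region.domain.lon_nodes[jj]


def distance_to_region(lat: float, lon: float, region) -> float:
    """Geodesic km from a point to the region (0 if its cell is a member)."""
    return float(region_distances(np.atleast_1d(lat), np.atleast_1d(lon), region)[0])


def region_distances(lats, lons, region) -> np.ndarray:
    """Vectorized distance-to-region for many points."""
    if not region.member.any():
        raise ValueError("empty utilization region")
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    i, j = region.domain.node_index(lats, lons)
    inside = region.member[i, j]
    out = np.zeros(lats.shape, dtype=float)
    if (~inside).any():
        blat, blon = _boundary_nodes(region)
        d = haversine_km(
            lats[~inside][:, None], lons[~inside][:, None], blat[None, :], blon[None, :]
        )
        out[~inside] = d.min(axis=1)
    return out


def sample_random_points(n_observed: int, domain: SpatialDomain,
                         mask: LandMask | None, rng: np.random.Generator,
                         ratio: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """``ratio`` x n_observed points uniform over the unmasked domain."""
    if mask is not None and mask.excluded.all():
        raise ValueError("mask covers the whole domain")
    need = ratio * n_observed
    lats = np.empty(need)
    lons = np.empty(need)
    got = 0
    attempts = 0
    while got < need:
        batch = max(64, 2 * (need - got))
        attempts += batch
        if attempts > _RANDOM_CAP:
            raise RuntimeError("random-point rejection sampling exceeded the draw cap")
        la = rng.uniform(domain.lat_min, domain.lat_max, batch)
        lo = rng.uniform(domain.lon_min, domain.lon_max, batch)
        if mask is not None:
            keep = ~mask.is_excluded(la, lo)
            la, lo = la[keep], lo[keep]
        take = min(need - got, la.size)
        lats[got : got + take] = la[:take]
        lons[got : got + take] = lo[:take]
        got += take
    return lats, lons


def association_test(samples: pd.DataFrame, alpha: float = 0.05,
                     per_period_effects: bool = False) -> AssociationResult:
    """Linear model ``distance ~ group`` on pooled samples.

    The group coefficient is the random-minus-observed mean distance; its t
    statistic on n-2 df equals the pooled two-sample t statistic.  With
    ``per_period_effects``, period fixed effects are added.
    """
    for g in ("observed", "random"):
        if (samples["group"] == g).sum() == 0:
            raise ValueError(f"no '{g}' samples")
    x = (samples["group"] == "random").astype(float).to_numpy()
    X = pd.DataFrame({"const": 1.0, "random": x})
    if per_period_effects:
        dummies = pd.get_dummies(samples["period"], prefix="p", drop_first=True, dtype=float)
        X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    fit = sm.OLS(samples["distance_km"].to_numpy(), X.to_numpy()).fit()
    effect = float(fit.params[1])
    t_stat = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    obs = samples[samples["group"] == "observed"]
    return AssociationResult(
        samples=samples,
        effect_km=effect,
        t_stat=t_stat,
        p_value=p,
        observed_closer=bool(effect > 0 and p < alpha),
        alpha=alpha,
        n_observed=int((samples["group"] == "observed").sum()),
        n_random=int((samples["group"] == "random").sum()),
        periods_evaluated=int(samples["period"].nunique()),
        periods_with_school_inside=int(obs.groupby("period")["inside"].any().sum()),
        schools_inside=int(obs["inside"].sum()),
    )


def run_association(schools: pd.DataFrame, herring: pd.DataFrame,
                    first_year: int, last_year: int,
                    domain: SpatialDomain, mask: LandMask | None,
                    alpha_mass: float = 0.95, alpha_test: float = 0.05,
                    ratio: int = 2, min_records: int = 10, seed: int = 0,
                    per_period_effects: bool = False) -> AssociationResult:
    """The full per-period procedure, pooled into one test.

    For every semimonthly period with enough prey records and at least one
    observed school: estimate the tonnage-weighted prey density, take its
    ``alpha_mass`` highest-density region, measure observed-school and
    2:1 random-point distances to it.  Random points come from a per-period
    substream of ``seed`` so periods are independently reproducible.
    """
    rows = []
    skipped = []
    for period in semimonthly_periods(first_year, last_year):
        surf = periodic_density(herring, period, domain, min_records=min_records)
        if isinstance(surf, SkipMarker):
            skipped.append((period.key, surf.reason))
            continue
        obs = schools[schools["date"].map(period.contains)]
        if len(obs) == 0:
            skipped.append((period.key, "no observed schools"))
            continue
        region = utilization_region(surf, alpha_mass)
        olat = obs["latitude"].to_numpy()
        olon = obs["longitude"].to_numpy()
        od = region_distances(olat, olon, region)
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(b"association"), period.year, period.index])
        )
        rlat, rlon = sample_random_points(len(obs), domain, mask, rng, ratio=ratio)
        rd = region_distances(rlat, rlon, region)
        for la, lo, d in zip(olat, olon, od):
            rows.append((period.key, "observed", la, lo, d, d == 0.0))
        for la, lo, d in zip(rlat, rlon, rd):
            rows.append((period.key, "random", la, lo, d, d == 0.0))
    if not rows:
        raise ValueError("no usable periods: every period was skipped")
    samples = pd.DataFrame(
        rows, columns=["period", "group", "lat", "lon", "distance_km", "inside"]
    )
    result = association_test(samples, alpha=alpha_test, per_period_effects=per_period_effects)
    result.periods_skipped = skipped
    return result
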