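import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from gomtuna.calendar import semimonthly_periods
from gomtuna.density import (
    DEFAULT_EPOCHS,
    DensitySurface,
    SkipMarker,
    bandwidth_quartile_rule,
    epoch_density,
    periodic_density,
    utilization_region,
    weighted_kde,
)
from gomtuna.domain import SpatialDomain
from gomtuna.simulate import SimConfig, generate_herring


def nrd_oracle(x):
    """Literal quartile-rule formula, written independently of the implementation."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)

    def quantile(p):  # linear interpolation at position 1 + (n-1)p
        h = (n - 1) * p
        lo = int(math.floor(h))
        return x[lo] + (h - lo) * (x[min(lo + 1, n - 1)] - x[lo])

    sd = np.std(x, ddof=1)
    iqr = quantile(0.75) - quantile(0.25)
    return 4.0 * 1.06 * min(sd, iqr / 1.34) * n ** (-0.2)


def brute_force_kde(lats, lons, weights, domain, b_lat, b_lon):
    """Doubly-looped reference estimator (normalized the same way)."""
    s_lat, s_lon = b_lat / 4.0, b_lon / 4.0
    w = np.asarray(weights, float) / np.sum(weights)
    vals = np.zeros((domain.n_lat, domain.n_lon))
    for i, gla in enumerate(domain.lat_nodes):
        for j, glo in enumerate(domain.lon_nodes):
            acc = 0.0
            for la, lo, wi in zip(lats, lons, w):
                acc += (
                    wi
                    * math.exp(-0.5 * ((gla - la) / s_lat) ** 2) / (s_lat * math.sqrt(2 * math.pi))
                    * math.exp(-0.5 * ((glo - lo) / s_lon) ** 2) / (s_lon * math.sqrt(2 * math.pi))
                )
            vals[i, j] = acc
    return vals / (vals.sum() * domain.cell_area)


def test_bandwidth_rule_matches_formula_oracle(rng):
    assert bandwidth_quartile_rule(np.arange(1.0, 101.0)) == pytest.approx(
        nrd_oracle(np.arange(1.0, 101.0)), abs=1e-12
    )
    for _ in range(100):
        x = rng.normal(size=rng.integers(5, 200)) * rng.uniform(0.1, 50)
        assert bandwidth_quartile_rule(x) == pytest.approx(nrd_oracle(x), abs=1e-12)


def test_bandwidth_scale_equivariance(rng):
    x = rng.normal(size=60)
    for c in (0.5, 3.0, 111.2):
        assert bandwidth_quartile_rule(c * x) == pytest.approx(
            c * bandwidth_quartile_rule(x), rel=1e-12
        )


def test_bandwidth_degenerate_inputs():
    assert bandwidth_quartile_rule([1.0, 2.0]) > 0
    with pytest.raises(ValueError, match="bandwidth"):
        bandwidth_quartile_rule([3.0, 3.0, 3.0])
    with pytest.raises(ValueError):
        bandwidth_quartile_rule([5.0])


def test_single_point_surface_peaks_at_nearest_node(small_domain):
    surf = weighted_kde([42.1], [-68.3], [1.0], small_domain, 0.5, 0.5)
    assert surf.mass == pytest.approx(1.0, abs=1e-6)
    i, j = np.unravel_index(np.argmax(surf.values), surf.values.shape)
    ii, jj = small_domain.node_index(42.1, -68.3)
    assert (i, j) == (ii, jj)


def test_weight_linearity_duplicated_point(small_domain):
    a = weighted_kde([42.0, 42.0, 43.0], [-68.0, -68.0, -69.0], [2.0, 1.0, 5.0],
                     small_domain, 0.6, 0.6)
    b = weighted_kde([42.0, 43.0], [-68.0, -69.0], [3.0, 5.0], small_domain, 0.6, 0.6)
    assert np.allclose(a.values, b.values, atol=1e-12)


def test_kde_matches_brute_force_loop(rng, small_domain):
    n = rng.integers(50, 200)
    lats = rng.uniform(39.5, 44.5, n)
    lons = rng.uniform(-70.5, -65.5, n)
    w = rng.uniform(0.1, 30.0, n)
    b_lat, b_lon = 0.8, 0.6
    surf = weighted_kde(lats, lons, w, small_domain, b_lat, b_lon)
    ref = brute_force_kde(lats, lons, w, small_domain, b_lat, b_lon)
    assert np.abs(surf.values - ref).max() < 1e-9


def test_kde_input_validation(small_domain):
    with pytest.raises(ValueError):
        weighted_kde([], [], [], small_domain, 0.5, 0.5)
    with pytest.raises(ValueError, match="weights"):
        weighted_kde([42.0], [-68.0], [0.0], small_domain, 0.5, 0.5)
    with pytest.raises(ValueError, match="bandwidth"):
        weighted_kde([42.0], [-68.0], [1.0], small_domain, 0.0, 0.5)


def make_surface(masses):
    """2x2 surface whose four cells carry the given probability masses."""
    dom = SpatialDomain(n_lat=2, n_lon=2)
    values = np.asarray(masses, float).reshape(2, 2) / dom.cell_area
    return DensitySurface(dom, values, 1.0, 1.0)


def test_region_with_equal_masses_needs_all_cells():
    surf = make_surface([0.25, 0.25, 0.25, 0.25])
    region = utilization_region(surf, 0.95)
    assert region.member.all()
    assert region.achieved_mass == pytest.approx(1.0)


def test_region_top_node_only():
    surf = make_surface([0.5, 0.3, 0.2, 0.0])
    region = utilization_region(surf, 0.5)
    assert region.n_cells == 1
    assert region.member[0, 0]
    assert region.achieved_mass == pytest.approx(0.5)


def test_region_coverage_minimality_nestedness(rng):
    dom = SpatialDomain(n_lat=20, n_lon=20)
    for _ in range(20):
        values = rng.uniform(0.0, 1.0, (20, 20))
        surf = DensitySurface(dom, values / (values.sum() * dom.cell_area), 1.0, 1.0)
        r50 = utilization_region(surf, 0.5)
        r95 = utilization_region(surf, 0.95)
        assert r50.achieved_mass >= 0.5 and r95.achieved_mass >= 0.95
        assert (r95.member | r50.member).sum() == r95.member.sum()  # nested
        for region, level in ((r50, 0.5), (r95, 0.95)):
            member_vals = surf.values[region.member]
            least = member_vals.min() * dom.cell_area
            assert region.achieved_mass - least < level


def test_periodic_density_threshold_and_degenerate_spread(coarse_domain):
    period = semimonthly_periods(1997, 1997)[0]
    base = dict(tonnage_mt=5.0, gear="trawl", zone="1A")
    few = pd.DataFrame(
        [{"date": dt.date(1997, 6, 2), "latitude": 42 + 0.1 * k, "longitude": -69 + 0.1 * k, **base}
         for k in range(9)]
    )
    out = periodic_density(few, period, coarse_domain)
    assert isinstance(out, SkipMarker) and "few" in out.reason and out.n_records == 9
    same_spot = pd.DataFrame(
        [{"date": dt.date(1997, 6, 2), "latitude": 42.0, "longitude": -69.0, **base}] * 12
    )
    out = periodic_density(same_spot, period, coarse_domain)
    assert isinstance(out, SkipMarker) and "degenerate" in out.reason


def test_single_hotspot_period_region_contains_center(coarse_domain):
    cfg = SimConfig(first_year=1997, last_year=1997, hotspots=((42.5, -69.0, 0.2),),
                    drift_rate=0.0, n_herring_per_period=40, seed=21)
    herring = generate_herring(cfg, coarse_domain)
    period = semimonthly_periods(1997, 1997)[0]
    surf = periodic_density(herring, period, coarse_domain)
    region = utilization_region(surf, 0.95)
    i, j = coarse_domain.node_index(42.5, -69.0)
    assert region.member[i, j]


def test_epoch_density_reduction_and_monotone_weighting():
    from conftest import make_schools

    dom = SpatialDomain(n_lat=60, n_lon=60)
    one = make_schools([("1997-07-04", 42.0, -69.0, 20)])
    surfaces = epoch_density(one, dom, ((1996, 1999),))
    surf = surfaces[(1996, 1999)]
    single = weighted_kde([42.0], [-69.0], [20.0], dom, surf.bandwidth_lat, surf.bandwidth_lon)
    assert np.allclose(surf.values, single.values)

    two = make_schools([("1997-07-04", 42.0, -69.0, 20), ("1997-08-04", 43.5, -66.5, 20)])
    boosted = make_schools([("1997-07-04", 42.0, -69.0, 40), ("1997-08-04", 43.5, -66.5, 20)])
    s_a = epoch_density(two, dom, ((1996, 1999),))[(1996, 1999)]
    s_b = weighted_kde(boosted["latitude"], boosted["longitude"], boosted["n_fish"].astype(float),
                       dom, s_a.bandwidth_lat, s_a.bandwidth_lon)
    i, j = dom.node_index(42.0, -69.0)
    k, l = dom.node_index(43.5, -66.5)
    assert s_b.values[i, j] / s_b.values[k, l] > s_a.values[i, j] / s_a.values[k, l]


def test_default_epochs_cover_study_years_in_four_surfaces(rng):
    from conftest import make_schools

    rows = []
    for year in range(1979, 2006):
        for k in range(3):
            rows.append((f"{year}-07-{10 + k:02d}",
                         float(rng.uniform(40, 44)), float(rng.uniform(-70.5, -65.5)),
                         int(rng.integers(3, 100))))
    schools = make_schools(rows)
    dom = SpatialDomain(n_lat=60, n_lon=60)
    surfaces = epoch_density(schools, dom, DEFAULT_EPOCHS)
    assert len(surfaces) == 4
    assert all(not isinstance(s, SkipMarker) for s in surfaces.values())
    assert all(s.mass == pytest.approx(1.0, abs=1e-6) for s in surfaces.values())
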