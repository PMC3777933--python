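import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gomtuna.association import (
    association_test,
    distance_to_region,
    region_distances,
    run_association,
    sample_random_points,
)
from gomtuna.density import DensitySurface, utilization_region
from gomtuna.domain import SpatialDomain, generate_land_mask
from gomtuna.geo import haversine_km
from gomtuna.simulate import SimConfig, generate_herring, generate_schools


def random_region(rng, dom, level=0.5):
    values = rng.uniform(0, 1, (dom.n_lat, dom.n_lon))
    surf = DensitySurface(dom, values / (values.sum() * dom.cell_area), 1.0, 1.0)
    return utilization_region(surf, level)


def test_inside_point_is_zero_and_single_node_reduces_to_haversine(small_domain):
    dom = small_domain
    values = np.zeros((dom.n_lat, dom.n_lon))
    values[10, 20] = 1.0
    surf = DensitySurface(dom, values / dom.cell_area, 1.0, 1.0)
    region = utilization_region(surf, 0.95)
    assert region.n_cells == 1
    nlat, nlon = dom.lat_nodes[10], dom.lon_nodes[20]
    assert distance_to_region(nlat, nlon, region) == 0.0
    d = distance_to_region(44.0, -66.0, region)
    assert d == pytest.approx(haversine_km(44.0, -66.0, nlat, nlon), abs=1e-9)


def test_boundary_shortcut_equals_full_member_minimum(rng):
    dom = SpatialDomain(n_lat=30, n_lon=30)
    for _ in range(10):
        region = random_region(rng, dom, level=rng.uniform(0.2, 0.8))
        lat = rng.uniform(39, 45)
        lon = rng.uniform(-71, -65)
        got = distance_to_region(lat, lon, region)
        ii, jj = np.nonzero(region.member)
        full = haversine_km(lat, lon, dom.lat_nodes[ii], dom.lon_nodes[jj]).min()
        i, j = dom.node_index(lat, lon)
        expected = 0.0 if region.member[i, j] else full
        assert got == pytest.approx(expected, abs=1e-9)


def test_region_monotonicity_subset_distances(rng):
    dom = SpatialDomain(n_lat=30, n_lon=30)
    values = rng.uniform(0, 1, (30, 30))
    surf = DensitySurface(dom, values / (values.sum() * dom.cell_area), 1.0, 1.0)
    small = utilization_region(surf, 0.3)
    big = utilization_region(surf, 0.9)
    pts_lat = rng.uniform(39, 45, 50)
    pts_lon = rng.uniform(-71, -65, 50)
    d_small = region_distances(pts_lat, pts_lon, small)
    d_big = region_distances(pts_lat, pts_lon, big)
    assert np.all(d_small >= d_big - 1e-12)  # A subset of B => farther from A


def test_random_points_ratio_mask_and_uniform_mean(coarse_domain, rng):
    mask = generate_land_mask(coarse_domain)
    lats, lons = sample_random_points(25, coarse_domain, mask, rng)
    assert len(lats) == len(lons) == 50
    assert not mask.is_excluded(lats, lons).any()
    full = generate_land_mask(coarse_domain)
    full.excluded[:] = True
    with pytest.raises(ValueError):
        sample_random_points(5, coarse_domain, full, rng)
    # unmasked uniform mean longitude ~ domain centre
    lats, lons = sample_random_points(5000, coarse_domain, None, rng)
    se = 6.0 / np.sqrt(12.0) / np.sqrt(10000)
    assert abs(lons.mean() + 68.0) < 3 * se


def test_association_test_equals_pooled_two_sample_t(rng):
    obs = rng.normal(5.0, 2.0, 40)
    ran = rng.normal(9.0, 2.0, 80)
    samples = pd.DataFrame(
        {
            "period": "1997-01",
            "group": ["observed"] * 40 + ["random"] * 80,
            "lat": 42.0, "lon": -69.0,
            "distance_km": np.concatenate([obs, ran]),
            "inside": False,
        }
    )
    res = association_test(samples)
    ref = stats.ttest_ind(ran, obs, equal_var=True)
    assert res.t_stat == pytest.approx(ref.statistic, rel=1e-10)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
    assert res.effect_km == pytest.approx(ran.mean() - obs.mean(), rel=1e-12)
    # exchanging labels flips the sign of the statistic
    flipped = samples.assign(group=samples["group"].map(
        {"observed": "random", "random": "observed"}))
    res2 = association_test(flipped)
    assert res2.t_stat == pytest.approx(-res.t_stat, rel=1e-10)


def test_clear_separation_detected():
    rng = np.random.default_rng(44)
    samples = pd.DataFrame(
        {
            "period": "1997-01",
            "group": ["observed"] * 50 + ["random"] * 100,
            "lat": 42.0, "lon": -69.0,
            "distance_km": np.concatenate(
                [rng.normal(1.0, 0.1, 50), rng.normal(10.0, 0.1, 100)]
            ),
            "inside": False,
        }
    )
    res = association_test(samples)
    assert res.p_value < 1e-6
    assert res.observed_closer


def test_association_test_requires_both_groups():
    samples = pd.DataFrame(
        {"period": "p", "group": ["observed"] * 5, "lat": 42.0, "lon": -69.0,
         "distance_km": 1.0, "inside": False}
    )
    with pytest.raises(ValueError, match="random"):
        association_test(samples)


def test_schools_at_hotspot_centers_are_all_inside(coarse_domain):
    cfg = SimConfig(
        first_year=1997, last_year=1997, hotspots=((42.5, -69.0, 0.2),),
        drift_rate=0.0, n_herring_per_period=40, n_schools_per_period=3,
        attraction=1.0, jitter=0.0, seed=17,
    )
    herring = generate_herring(cfg, coarse_domain)
    schools = generate_schools(cfg, coarse_domain)
    res = run_association(schools, herring, 1997, 1997, coarse_domain, None, seed=17)
    obs = res.samples[res.samples["group"] == "observed"]
    assert (obs["distance_km"] == 0.0).all()
    assert obs["inside"].all()
    assert res.periods_with_school_inside == res.periods_evaluated


def test_run_association_is_reproducible_and_ratio_holds(coarse_domain, mask):
    cfg = SimConfig(first_year=1997, last_year=1998, seed=23)
    herring = generate_herring(cfg, coarse_domain, mask)
    schools = generate_schools(cfg, coarse_domain, mask)
    r1 = run_association(schools, herring, 1997, 1998, coarse_domain, mask, seed=23)
    r2 = run_association(schools, herring, 1997, 1998, coarse_domain, mask, seed=23)
    pd.testing.assert_frame_equal(r1.samples, r2.samples)
    assert (r1.effect_km, r1.t_stat, r1.p_value) == (r2.effect_km, r2.t_stat, r2.p_value)
    counts = r1.samples.groupby(["period", "group"]).size().unstack("group")
    assert (counts["random"] == 2 * counts["observed"]).all()
    r3 = run_association(schools, herring, 1997, 1998, coarse_domain, mask, seed=24)
    assert not r3.samples["distance_km"].equals(r1.samples["distance_km"])


def test_run_association_errors_without_usable_periods(coarse_domain):
    cfg = SimConfig(first_year=1997, last_year=1997, n_herring_per_period=2, seed=3)
    herring = generate_herring(cfg, coarse_domain)
    schools = generate_schools(cfg, coarse_domain)
    with pytest.raises(ValueError, match="usable"):
        run_association(schools, herring, 1997, 1997, coarse_domain, None, seed=3)
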