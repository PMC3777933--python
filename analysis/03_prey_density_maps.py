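#!/usr/bin/env python
"""Semimonthly prey utilization distributions.

For each half-month period, estimate the tonnage-weighted herring density on
the 500x500 study grid and extract the 95%-mass utilization region.  Writes
per-period bandwidths and region sizes to results/03_density_summary.json.
"""
import json
from pathlib import Path

from gomtuna.calendar import semimonthly_periods
from gomtuna.density import SkipMarker, periodic_density, utilization_region
from gomtuna.domain import SpatialDomain
from gomtuna.pipeline import round_sig
from gomtuna.records import read_herring

ROOT = Path(__file__).resolve().parent.parent


def main():
    herring_path = ROOT / "scratch" / "data" / "herring.csv"
    if not herring_path.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    domain = SpatialDomain()
    herring = read_herring(herring_path, domain)
    years = sorted({d.year for d in herring["date"]})

    per_period = {}
    skipped = 0
    for period in semimonthly_periods(min(years), max(years)):
        surf = periodic_density(herring, period, domain)
        if isinstance(surf, SkipMarker):
            per_period[period.key] = {"skipped": surf.reason, "n_records": surf.n_records}
            skipped += 1
            continue
        region = utilization_region(surf, 0.95)
        per_period[period.key] = {
            "bandwidth_lon_deg": surf.bandwidth_lon,
            "bandwidth_lat_deg": surf.bandwidth_lat,
            "region95_cells": region.n_cells,
            "region95_area_fraction": region.n_cells / surf.values.size,
        }

    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "03_density_summary.json").write_text(
        json.dumps(round_sig(per_period), indent=2, sort_keys=True) + "\n"
    )
    usable = len(per_period) - skipped
    fracs = [v["region95_area_fraction"] for v in per_period.values() if "skipped" not in v]
    print(f"{usable}/{len(per_period)} periods had enough records for a surface; "
          f"median 95% region covers {sorted(fracs)[len(fracs)//2]:.1%} of the grid")


if __name__ == "__main__":
    main()
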