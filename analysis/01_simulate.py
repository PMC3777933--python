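#!/usr/bin/env python
"""Generate the synthetic study decade.

Writes the four analysis inputs (school logbook, herring catches, survey
index, land mask) to scratch/data/ and a small summary of what was generated
to results/01_simulation_summary.json.
"""
import argparse
import json
from pathlib import Path

from gomtuna.domain import SpatialDomain, generate_land_mask
from gomtuna.records import write_herring, write_schools, write_survey
from gomtuna.simulate import SimConfig, generate_herring, generate_schools, generate_survey_index

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = SimConfig(seed=args.seed)
    domain = SpatialDomain()
    mask = generate_land_mask(domain)
    herring = generate_herring(cfg, domain, mask)
    schools = generate_schools(cfg, domain, mask)
    survey = generate_survey_index(cfg)

    data = ROOT / "scratch" / "data"
    data.mkdir(parents=True, exist_ok=True)
    write_schools(schools, data / "schools.csv")
    write_herring(herring, data / "herring.csv")
    write_survey(survey, data / "survey.csv")
    mask.write(data / "mask.txt")

    summary = {
        "seed": args.seed,
        "years": [cfg.first_year, cfg.last_year],
        "n_schools": len(schools),
        "n_fish_total": int(schools["n_fish"].sum()),
        "n_herring_records": len(herring),
        "mask_fraction_excluded": round(mask.fraction_excluded, 4),
    }
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "01_simulation_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"simulated decade {cfg.first_year}-{cfg.last_year}: "
          f"{len(schools)} schools ({summary['n_fish_total']} fish), "
          f"{len(herring)} herring records; inputs in {data}")


if __name__ == "__main__":
    main()
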