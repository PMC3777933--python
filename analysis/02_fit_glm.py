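#!/usr/bin/env python
"""Fit the school-count model.

Full quasi-Poisson GLM (four mains, six pairwise interactions) on the
simulated logbook, overdispersion diagnosis, then backward stepwise
elimination at alpha = 0.05.  Writes results/02_glm_fit.json.
"""
import json
from pathlib import Path

from gomtuna.glm import GlmSpec, backward_select, check_overdispersion, fit_quasipoisson
from gomtuna.pipeline import round_sig
from gomtuna.records import read_schools

ROOT = Path(__file__).resolve().parent.parent


def main():
    schools_path = ROOT / "scratch" / "data" / "schools.csv"
    if not schools_path.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    schools = read_schools(schools_path)

    full = fit_quasipoisson(schools, GlmSpec())
    overdispersed = check_overdispersion(full)
    final = backward_select(schools, GlmSpec(), alpha=0.05)

    report = round_sig({
        "full_model": full.to_dict(),
        "overdispersed": overdispersed,
        "final_model": final.to_dict(),
    })
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "02_glm_fit.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    print(f"full model: deviance/df = {full.deviance / full.df_resid:.2f} "
          f"(overdispersed: {overdispersed}), Pearson dispersion = {full.dispersion:.2f}")
    print(f"backward selection removed {len(final.elimination_log)} terms; "
          f"final model: {', '.join(final.terms) or 'intercept only'}")


if __name__ == "__main__":
    main()
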