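"""End-to-end orchestration: simulate -> filter -> glm -> density -> association -> trends.

A run is driven by one YAML config and one seed; every stage derives its own
substream, writes text outputs rounded to 10 significant digits, and the run
manifest records the config hash plus a checksum per output so identical
configurations produce identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import records
from .association import run_association
from .density import DEFAULT_EPOCHS, SkipMarker, epoch_density, utilization_region
from .domain import LandMask, SpatialDomain, generate_land_mask
from .glm import GlmSpec, backward_select, check_overdispersion, fit_quasipoisson
from .simulate import SimConfig, generate_herring, generate_schools, generate_survey_index
from .trends import annual_centroids, correlate_index

__all__ = ["RunConfig", "run_all", "round_sig"]

logger = logging.getLogger(__name__)


def round_sig(x, digits: int = 10):
    """Round floats (recursively through dicts/lists) to ``digits`` significant digits."""
    if isinstance(x, dict):
        return {k: round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [round_sig(v, digits) for v in x]
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (float, np.floating)):
        if x == 0 or not np.isfinite(x):
            return float(x)
        return float(f"{x:.{digits}g}")
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


@dataclass
class RunConfig:
    """Full-run parameters; see docs/methods.md for the analysis defaults."""

    sim: SimConfig = field(default_factory=SimConfig)
    domain: SpatialDomain = field(default_factory=SpatialDomain)
    alpha_mass: float = 0.95
    alpha_test: float = 0.05
    ratio: int = 2
    min_records_per_period: int = 10
    epochs: tuple = DEFAULT_EPOCHS
    outdir: str = "run_output"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_mass <= 1.0:
            raise ValueError("alpha_mass must lie in (0, 1]")
        if not 0.0 < self.alpha_test < 1.0:
            raise ValueError("alpha_test must lie in (0, 1)")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.min_records_per_period < 2:
            raise ValueError("min_records_per_period must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{k: tuple(map(tuple, v)) if k == "hotspots" else v
                           for k, v in raw.get("sim", {}).items()})
        domain = SpatialDomain(**raw.get("domain", {}))
        kwargs = {k: v for k, v in raw.items() if k not in ("sim", "domain")}
        if "epochs" in kwargs:
            kwargs["epochs"] = tuple(tuple(e) for e in kwargs["epochs"])
        return cls(sim=sim, domain=domain, **kwargs)

    def to_yaml(self) -> str:
        payload = {
            "sim": dataclasses.asdict(self.sim),
            "domain": dataclasses.asdict(self.domain),
            "alpha_mass": self.alpha_mass,
            "alpha_test": self.alpha_test,
            "ratio": self.ratio,
            "min_records_per_period": self.min_records_per_period,
            "epochs": [list(e) for e in self.epochs],
            "outdir": self.outdir,
        }
        payload["sim"]["hotspots"] = [list(h) for h in self.sim.hotspots]
        return yaml.safe_dump(payload, sort_keys=True)

    def canonical_yaml(self) -> str:
        """Config serialization used for hashing; the output path is not part
        of the scientific configuration, so it is excluded."""
        payload = yaml.safe_load(self.to_yaml())
        payload.pop("outdir", None)
        return yaml.safe_dump(payload, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(round_sig(obj), indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig) -> dict:
    """Execute every stage; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest: dict = {
        "config_sha256": hashlib.sha256(config.canonical_yaml().encode()).hexdigest(),
        "seed": config.sim.seed,
        "stages": {},
    }

    # --- simulate -----------------------------------------------------------
    logger.info("stage simulate")
    mask = generate_land_mask(config.domain)
    herring = generate_herring(config.sim, config.domain, mask)
    schools = generate_schools(config.sim, config.domain, mask)
    survey = generate_survey_index(config.sim)
    records.write_schools(schools, outdir / "schools.csv")
    records.write_herring(herring, outdir / "herring.csv")
    records.write_survey(survey, outdir / "survey.csv")
    mask.write(outdir / "mask.txt")
    for name in ("schools.csv", "herring.csv", "survey.csv", "mask.txt"):
        outputs[name] = _sha256(outdir / name)
    manifest["stages"]["simulate"] = {
        "n_schools": len(schools),
        "n_herring": len(herring),
        "mask_fraction_excluded": round_sig(mask.fraction_excluded),
    }

    # --- filter (round-trip through the record readers) ---------------------
    logger.info("stage filter")
    schools_f, dropped_s = records.read_schools(outdir / "schools.csv", config.domain, return_dropped=True)
    herring_f, dropped_h = records.read_herring(outdir / "herring.csv", config.domain, return_dropped=True)
    survey_f = records.read_survey(outdir / "survey.csv")
    manifest["stages"]["filter"] = {
        "schools_kept": len(schools_f),
        "schools_dropped": len(dropped_s),
        "herring_kept": len(herring_f),
        "herring_dropped": len(dropped_h),
    }

    # --- glm ----------------------------------------------------------------
    logger.info("stage glm")
    poisson_fit = fit_quasipoisson(schools_f, GlmSpec())
    overdispersed = check_overdispersion(poisson_fit)
    final_fit = backward_select(schools_f, GlmSpec(), alpha=config.alpha_test)
    glm_report = {
        "full_model": poisson_fit.to_dict(),
        "overdispersed": overdispersed,
        "final_model": final_fit.to_dict(),
    }
    _write_json(outdir / "glm.json", glm_report)
    outputs["glm.json"] = _sha256(outdir / "glm.json")
    manifest["stages"]["glm"] = {
        "overdispersed": overdispersed,
        "dispersion": round_sig(poisson_fit.dispersion),
        "final_terms": list(final_fit.terms),
    }

    # --- density (epoch utilization maps) -----------------------------------
    logger.info("stage density")
    sim_epochs = tuple(
        (max(y0, config.sim.first_year), min(y1, config.sim.last_year))
        for y0, y1 in config.epochs
        if y1 >= config.sim.first_year and y0 <= config.sim.last_year
    ) or ((config.sim.first_year, config.sim.last_year),)
    surfaces = epoch_density(schools_f, config.domain, sim_epochs)
    density_summary = {}
    for (y0, y1), surf in surfaces.items():
        label = f"{y0}-{y1}"
        if isinstance(surf, SkipMarker):
            density_summary[label] = {"skipped": surf.reason, "n_records": surf.n_records}
        else:
            region = utilization_region(surf, config.alpha_mass)
            density_summary[label] = {
                "bandwidth_lon": surf.bandwidth_lon,
                "bandwidth_lat": surf.bandwidth_lat,
                "mass": surf.mass,
                "region_cells": region.n_cells,
                "region_fraction": region.n_cells / surf.values.size,
            }
    _write_json(outdir / "density.json", density_summary)
    outputs["density.json"] = _sha256(outdir / "density.json")
    manifest["stages"]["density"] = {"epochs": list(density_summary)}

    # --- association --------------------------------------------------------
    logger.info("stage association")
    assoc = run_association(
        schools_f, herring_f, config.sim.first_year, config.sim.last_year,
        config.domain, mask,
        alpha_mass=config.alpha_mass, alpha_test=config.alpha_test,
        ratio=config.ratio, min_records=config.min_records_per_period,
        seed=config.sim.seed,
    )
    samples = assoc.samples.copy()
    samples["lat"] = samples["lat"].map(lambda v: f"{v:.4f}")
    samples["lon"] = samples["lon"].map(lambda v: f"{v:.4f}")
    samples["distance_km"] = samples["distance_km"].map(lambda v: f"{v:.6g}")
    samples.to_csv(outdir / "distance_samples.csv", index=False)
    _write_json(outdir / "association.json", assoc.to_dict())
    outputs["distance_samples.csv"] = _sha256(outdir / "distance_samples.csv")
    outputs["association.json"] = _sha256(outdir / "association.json")
    manifest["stages"]["association"] = {
        "direction_observed_closer": bool(assoc.observed_closer),
        "p_value": round_sig(assoc.p_value),
        "effect_km": round_sig(assoc.effect_km),
        "periods_evaluated": assoc.periods_evaluated,
        "periods_skipped": len(assoc.periods_skipped),
        "periods_with_school_inside": assoc.periods_with_school_inside,
    }

    # --- trends -------------------------------------------------------------
    logger.info("stage trends")
    cents = annual_centroids(schools_f)
    cents_out = cents.copy()
    for col in ("lat", "lon", "var_lat", "var_lon"):
        cents_out[col] = cents_out[col].map(lambda v: f"{v:.10g}")
    cents_out.to_csv(outdir / "centroids.csv", index=False)
    trends_report = {}
    for season in ("spring", "autumn"):
        c = correlate_index(cents, survey_f, season)
        trends_report[season] = {"n": c.n, "r": c.r, "r2": c.r2, "p_value": c.p_value}
    _write_json(outdir / "trends.json", trends_report)
    outputs["centroids.csv"] = _sha256(outdir / "centroids.csv")
    outputs["trends.json"] = _sha256(outdir / "trends.json")
    manifest["stages"]["trends"] = round_sig(
        {s: trends_report[s]["r2"] for s in trends_report} | {"n_years": int(len(cents))}
    )

    manifest["outputs"] = outputs
    _write_json(outdir / "manifest.json", manifest)
    return manifest
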