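# gomtuna

Spatial analysis of predator-prey association between Atlantic bluefin tuna
(*Thunnus thynnus*) schools and Atlantic herring (*Clupea harengus*) density
in the Gulf of Maine (39-45° N, 71-65° W), built for fisheries ecologists who
want the whole chain — from logbook-style records to the association test —
as tested, reusable code.

Because the original captains'-logbook, dealer and survey extracts are
proprietary, the package ships a first-class synthetic-data generator that
reproduces their statistical structure (hotspot-clustered prey catches with
slow eastward drift, overdispersed school sizes, an abundance index tied to
hotspot longitude), so every stage of the analysis runs and is testable from
a single seed.

## The analysis

1. **School-count model.** A log-link GLM of fish per school,
   `numbersoffish ~ year + dayofyear + latitude + longitude` plus all six
   pairwise interactions, fit by IRLS. If residual deviance per degree of
   freedom exceeds 1.5, inference switches to quasi-Poisson: Var(y) = φμ with
   φ the Pearson dispersion, standard errors inflated by √φ, p-values from a
   t distribution. Backward stepwise elimination removes terms with p > 0.05,
   interactions before main effects, under marginality.
2. **Prey utilization distributions.** For each semimonthly period
   (1st-15th / 16th-month-end, June-October — 100 periods per decade), a
   catch-tonnage-weighted 2-D Gaussian KDE on a 500×500 grid. Bandwidths per
   axis from the quartile rule `b = 4·1.06·min(sd, IQR/1.34)·n^(-1/5)`, with
   kernel σ = b/4. The "95th percentile contour" is the 95%-mass
   highest-density cell set of the normalized surface.
3. **Association test.** Great-circle (haversine, R = 6371.0088 km) distances
   from observed schools — and from twice as many random points placed
   uniformly over unmasked water (a bathymetry/land filter) — to the nearest
   95% contour, pooled over all periods, compared by the linear model
   `distance ~ group` at α = 0.05. "Observed closer" means a positive
   random-minus-observed effect that is significant.
4. **Distribution trend.** Yearly school centroids weighted by fish count
   (error bars: sample variance), and Pearson correlation of centroid
   longitude with the spring/autumn mean-herring-per-tow survey index.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
decade (inputs land in `scratch/data/`, tables in `results/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_fit_glm.py
python analysis/03_prey_density_maps.py
python analysis/04_association_test.py --seed 1
python analysis/05_centroid_trends.py
```

which prints (seed 1):

```
simulated decade 1996-2005: 300 schools (21274 fish), 3000 herring records; ...
full model: deviance/df = 40.84 (overdispersed: True), Pearson dispersion = 44.96
backward selection removed 7 terms; final model: dayofyear, longitude, longitude:dayofyear
100/100 periods had enough records for a surface; median 95% region covers 31.0% of the grid
observed schools are closer to the 95% prey contour than random points: random-observed effect = 67.5 km, p = 7.59e-49
100 of 100 evaluated periods had at least one school inside the 95% contour
centroid longitude shifted +0.81 deg over 10 years
spring: r2 = 0.06, p = 0.51 (n = 10 years)
autumn: r2 = 0.07, p = 0.464 (n = 10 years)
```

Reading this: school sizes are strongly overdispersed (deviance/df ≈ 41 ≫
1.5), so the quasi-Poisson refit is triggered; with schools generated at
attraction 0.9 the association test finds them ~67 km closer to prey
concentrations than random points; the centroid tracks the prescribed
0.1°/yr eastward hotspot drift (+0.81° over ten years). At the default
survey noise the 10-year index correlation is weak for any single seed — its
calibration across many seeds is what the test suite checks.

The same stages are available as a CLI (`gomtuna simulate|glm|kde|assoc|trends|all`)
and as one reproducible pipeline call (`gomtuna.pipeline.run_all`), which
writes a manifest with a config hash and per-output checksums — two runs
with the same config and seed are byte-identical.

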