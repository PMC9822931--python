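# windcape

Convective storms are the dominant cause of large windthrows — patches of
uprooted or snapped trees bigger than 25,000 m² — across the Amazon basin.
`windcape` is a Python package for the analysis chain that links the
atmosphere's convective available potential energy (CAPE) to the spatial
density of those windthrows and projects how both change under future
climate forcing:

1. **Parcel CAPE** — a nondilute, near-surface-based, adiabatic parcel is
   lifted over discrete pressure levels (100 kPa → 10 kPa in 10 kPa steps)
   and its buoyancy summed:

   CAPE = Σᵢ dp · H(bᵢ) · bᵢ,  with  bᵢ = 1/ρᵢ − 1/ρ_{e,i},

   where ρᵢ is the parcel density at level *i*, ρ_{e,i} the environmental
   density, and H the Heaviside step function. Daily ESM fields (tas, huss,
   ps, ta) feed this directly; reanalysis CAPE enters as data and is
   averaged over the 17:00–23:00 UTC afternoon window.
2. **Density model** — CAPE values at the windthrow locations are sorted
   and split into equal-count bins; each bin's windthrow density is its
   event count divided by the regional area with that CAPE (per
   10,000 km²). The outer bin edges extend to 0 and +∞, bootstrap
   resampling of the events gives per-bin SDs, and the interior edge with
   maximal density contrast defines the storm-favorable CAPE threshold.
3. **Projection** — each Earth-system model's fractional CAPE change,
   delta = (future − current)/current, scales the observational baseline
   grid-wise; the scaled fields yield the percent increase in
   storm-favorable area (CAPE above threshold) and in the expected
   windthrow total Σ density(CAPE)·area/10⁴, summarised over the ensemble
   as mean ± sample SD.

A synthetic-data module generates correlated CAPE fields spanning the
observed range (42–1549 J kg⁻¹), inhomogeneous-Poisson windthrow sets
from known step intensities, and ESM ensembles with planted deltas, so
every stage is testable end to end with measurable parameter recovery.

## Worked example

```python
import numpy as np
import windcape as wc

# 1. Synthetic study region: correlated mean-afternoon CAPE field
scenario = wc.SyntheticScenario(seed=42)
cape = wc.make_cape_field(scenario)

# 2. Windthrows from a step intensity rising 8-fold above 1023 J/kg
intensity = wc.step_intensity([1023.0], [1.0, 8.0])
events = wc.simulate_windthrows(cape, intensity, seed=43)

# 3. Fit the equal-count density model and its uncertainty
capes_at_events = wc.sample_cape_at_points(cape, events)
model = wc.fit_density_model(capes_at_events, cape, n_bins=6)
wc.bootstrap_density_sd(capes_at_events, model, n_boot=10_000, seed=44)
threshold = wc.favorable_threshold(model)
print(f"events: {events.n}")
print(f"bin edges (J/kg): {np.round(model.bin_edges, 0)}")
print(f"densities (per 10^4 km^2): {np.round(model.bin_density, 2)}")
print(f"bootstrap SD: {np.round(model.bootstrap_sd, 2)}")
print(f"threshold: {threshold:.0f} J/kg, "
      f"fold ratio: {wc.density_ratio(model, threshold):.1f}")

# 4. Project a 10-member synthetic ESM ensemble (planted 26 +/- 9% CAPE rise)
members = wc.make_esm_ensemble(cape, wc.EsmParams(), seed=45)
results = [wc.project_model(m["name"], m["current"], m["future"],
                            cape, model, threshold) for m in members]
summary = wc.ensemble_summary(results)
print(f"favorable-area increase: {summary.mean_area_increase:.0f}% "
      f"+/- {summary.sd_area_increase:.0f}%")
print(f"windthrow-density increase: {summary.mean_density_increase:.0f}% "
      f"+/- {summary.sd_density_increase:.0f}%")
```

Output:

```
events: 602
bin edges (J/kg): [   0.  853. 1119. 1222. 1304. 1363.   inf]
densities (per 10^4 km^2): [0.97 3.84 8.96 9.21 9.44 6.98]
bootstrap SD: [0.09 0.35 0.82 0.86 0.86 0.64]
threshold: 853 J/kg, fold ratio: 7.0
favorable-area increase: 35% +/- 14%
windthrow-density increase: 19% +/- 8%
```

The fitted step function recovers the planted contrast: density is low in
the bins below the intensity jump and roughly 8 events per 10,000 km²
above it, the maximal-contrast threshold falls in the bin containing the
planted change point, and windthrows are about 7 times more frequent on
the favorable side. The projection numbers are the ensemble mean ± SD of
the per-model percent increases driven by the planted ~26% CAPE rise on
this particular synthetic geography.

The same workflow is scriptable from a shell via the `windcape` CLI
(`simulate`, `cape`, `aggregate`, `fit`, `bootstrap`, `project`,
`densitymap`); every subcommand writes a log with its parameters and seed
so runs are reconstructible.

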