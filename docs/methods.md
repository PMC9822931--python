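# Methods

## Parcel CAPE

CAPE is computed for a nondilute (non-entraining) parcel launched from
the surface state (ps, tas, huss) and lifted over fixed pressure levels,
by default 100 kPa down to 10 kPa in 10 kPa increments:

CAPE = Σᵢ dp · H(bᵢ) · bᵢ,  bᵢ = 1/ρᵢ − 1/ρ_{e,i}  (J kg⁻¹ with dp in Pa).

H(0) contributes zero: strictly positive buoyancy is required, so a
parcel exactly neutral at every level gives CAPE = 0 exactly.

Ascent is dry-adiabatic (T = Ts·(p/ps)^{R_d/c_p}, vapour conserved) up to
the lifting condensation level and pseudo-adiabatic above it, with
condensate removed on formation. The pseudo-adiabatic lapse

dT/dp = (R_d·T + L_v·r_s) / [p·(c_pd + L_v²·r_s·ε/(R_d·T²))]

uses a constant latent heat L_v = 2.501×10⁶ J kg⁻¹ and is integrated
with fixed-step RK4 (internal step ≤ 1 hPa, configurable). Saturation
vapour pressure follows Bolton's empirical formula by default, with
Tetens selectable through `CapeConfig` for sensitivity checks; the LCL
temperature uses Bolton's closed form. Parcel and environmental
densities come from the ideal-gas law with virtual temperature
Tv = T·(1 + r/ε)/(1 + r); condensate loading is ignored, consistent with
pseudo-adiabatic removal. Environmental temperature (and specific
humidity, when supplied) is interpolated linearly in log-pressure to the
summation levels; without environmental humidity the environment is
treated as dry air. These scheme choices are this package's own — the
lookup of density from CAPE downstream does not depend on them, but
absolute CAPE values do, which is one reason reanalysis CAPE (computed
with a different, maximum-unstable algorithm) is only ever consumed as
data and never recomputed here.

Levels below ground (pressure above surface pressure) and levels outside
the environmental profile's range are excluded from the sum rather than
extrapolated; fewer than two usable levels is an error. The 10-level sum
carries a discretisation error of a few percent relative to a 0.1 kPa
sum with identical thermodynamics; refining dp shrinks it monotonically
(the acceptance script prints both values and the refinement error).

Hourly CAPE rasters are averaged over the 17:00–23:00 UTC window
(13:00–19:00 Amazon local time) and a year range to form mean-afternoon
climatologies; cells missing in every selected field stay missing.

## Density model

The windthrow-density model is a non-parametric look-up table. CAPE is
sampled at each event location by nearest cell center. The n event CAPE
values are sorted and split into `n_bins` groups (default 6) whose sizes
differ by at most one, larger groups first: 1012 events give four groups
of 169 and two of 168. Interior bin edges sit at the midpoint between
the last event of one group and the first of the next, so membership is
unambiguous for the fitted events; the first edge is extended down to 0
and the last up to +∞ under the assumption that density is similar for
neighbouring CAPE values (in particular, it does not keep rising beyond
the largest observed CAPE). Bins are left-closed, right-open; an event
exactly on an interior edge belongs to the upper bin. Tied CAPE values
straddling a group boundary — common when several events share a grid
cell — can make the exact equal split impossible; the realised counts
are then reported through a warning, and conservation (counts summing to
n, areas partitioning the region) always holds.

Bin density is events per 10,000 km²: the bin's event count divided by
the summed area of in-region cells whose CAPE falls in the bin. Cell
areas are exact spherical band areas R²·Δλ·(sin φ₂ − sin φ₁), so no
cosine-latitude approximation enters.

Bootstrap uncertainty resamples the n events with replacement (default
10,000 replicates) and recounts against the edges of the full-data fit.
Edges are deliberately held fixed: the published error bars are per-bin
quantities, and refitting edges per replicate would change what each bin
means. With fixed edges the replicate counts are exactly multinomial
(n, p̂) draws, which is how the implementation generates them —
vectorised, statistically identical to per-event resampling, and
checkable against the closed form √(n·p(1−p))/area·10⁴.

The storm-favorable threshold is operationalised as the interior edge
maximising the contrast (events above / area above) ÷ (events below /
area below); a user-supplied constant (e.g. the published 1023 J kg⁻¹)
can override it. The fold ratio at an arbitrary threshold aggregates
counts and areas from the bins on each side; a threshold strictly inside
a finite bin splits that bin proportionally under a uniform-within-bin
assumption, and a threshold inside the unbounded last bin is rejected.

## Projection

Absolute CAPE from different products is not comparable, so futures are
delta-change scaled: delta = (future − current)/current per cell on the
ESM's own fields (cells with current CAPE below a 1 J kg⁻¹ floor are
masked rather than divided), then scaled_future = (1 + delta)·baseline
on the observational grid. Storm-favorable area uses a strict inequality
(CAPE > threshold); the expected windthrow total is
Σ_cells density(CAPE)·area/10⁴ under the fitted model, computed
identically for current and scaled-future fields so the percent increase
isolates the CAPE shift. Ensemble summaries are mean and sample SD
(ddof = 1) across models; percentages are carried at full precision and
rounded to integers only in the report CSV. An absolute-delta variant is
not implemented; relative scaling is known to be more sensitive to the
ESM's historical baseline, which the synthetic ensemble's multiplicative
bias factors exercise directly.

## Synthetic data

Fields are Gaussian-smoothed white noise mapped affinely so the realised
extremes hit the configured range exactly (default 42–1549 J kg⁻¹, the
observed range of mean-afternoon reanalysis CAPE over the Amazon);
correlation length 0 recovers white noise. The default study region is a
12° × 12° box at 0.25° resolution (≈1.8 M km², roughly a quarter of the
Amazon) — large enough for several hundred events per draw at realistic
intensities while keeping full test runs in seconds. Windthrows are an
inhomogeneous Poisson process resolved at cell level: count ~
Poisson(intensity(CAPE)·area/10⁴) per cell, uniform placement within the
cell. Cell-level thinning (rather than continuous-space simulation) is
adequate because the analysis itself is cell-resolved. Synthetic ESM
members multiply the baseline by a smooth log-normal bias field
(emulating inter-product offsets) and plant a per-model delta field:
model mean drawn from N(0.26, 0.09²) by default, matching the published
ensemble's CAPE increase, plus smooth spatial noise floored at −0.99.
Planted truths are returned so recovery is measurable. All generators
are reproducible from an integer seed; the CLI derives per-stage seeds
from one run seed by fixed offsets.

What the generator does not emulate: the real spatial distribution of
Amazon CAPE (its anisotropy, river effects, coastal gradients), event
size and dating, observational detection bias, or any specific ESM's
physics. Passing recovery tests therefore demonstrates the estimators
are correct and calibrated under the model's own assumptions — step
intensity driven by CAPE alone — not that real windthrows obey them.

## Numerical choices and edge cases

- Percentile coarsening (e.g. 90th percentile onto a 2.5° grid) uses
  linear interpolation between order statistics; empty coarse cells are
  missing-flagged.
- Point-in-cell membership is half-open [west, east) × [south, north);
  a point on a shared edge belongs to its east/north neighbour.
- Missing raster cells are NaN in memory and an explicit fill value in
  NetCDF, never an ambiguous mix.
- Equal-count fitting with more tied values than a group width raises a
  degenerate-edges error rather than producing non-increasing edges.
- A flat (zero-contrast) density profile yields a no-threshold warning
  and falls back to the lowest interior edge.

## Known limitations

- The quantile bin edges of the equal-count fit generally do not
  coincide with a true intensity change point, so the fold ratio at the
  fitted threshold is biased slightly toward 1 (mixture bins dilute the
  contrast); across 100 replicate fits at default conditions the
  recovered 8-fold contrast averages within 10% of the truth, and the
  bias shrinks with domain size and event count.
- The pseudo-adiabat uses constant latent heat and ignores the ice
  phase; differences from more elaborate schemes are small below the
  10 kPa summation ceiling but not zero.
- `daily_cape_from_esm` loops per cell and day in Python; it is intended
  for the daily-resolution profile counts typical of this analysis, not
  for hourly global grids.
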