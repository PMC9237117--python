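# Methods

## The question and the approach

Late-summer cyanobacteria blooms (predominantly *Nodularia spumigena*) in
the Baltic Proper are detectable from space as surface accumulations, but
the environmental conditions that *precede* a bloom are hard to observe
directly: by the time a bloom is visible, the water that hosts it has been
drifting for weeks. bloomtrace implements the back-tracing strategy for this
problem: treat the bloom as a set of Lagrangian water parcels, reconstruct
where each parcel was during the previous two months from archived Eulerian
surface velocities, and compare the abiotic history of parcels that ended in
a bloom with the history of parcels that did not.

The pipeline has five stages:

1. **Seeding and attribution.** Virtual drifters (default 4000) are drawn
   uniformly at random inside the study box (13–24°E, 54–60°N). Each drifter
   inherits the state of its seed pixel in a three-state satellite bloom
   raster: bloom, no-bloom, or inconclusive (clouds, uncertain or
   sub-surface signals). Inconclusive drifters are discarded from every
   contrast. Cell membership is nearest-node assignment; land-seeded draws
   are rejected and redrawn so the requested count is exact.
2. **Backward advection.** Explicit Euler steps backward in time, default
   dt = 3 h (the cadence of the archived velocity output) over a 60-day
   window, with velocities interpolated bilinearly in space and linearly in
   time to the moving positions.
3. **Environmental sampling.** SST, mixed-layer depth, and mixed-layer
   averaged PAR are interpolated the same way onto every active trajectory
   point; distance to coast comes from a precomputed static field.
4. **Ensemble contrast.** Per-offset group means and population standard
   deviations (bloom vs. no-bloom), and the offshore-exposure statistic:
   the distance D such that a fraction `coverage` (default 90%) of bloom
   parcels never came closer than D to the coast in the final `window`
   (default 21 days).
5. **Nutrient climatology.** An independent observational contrast: surface
   bottle data zoned into coastal (< 40 nm from the coast) and offshore
   (> 60 nm) records, binned by climatological month May–September, and
   summarised as box-whisker statistics for nitrate, phosphate and excess
   phosphate P* = PO₄ − NO₃/16. The 40–60 nm gap keeps offshore bins clear
   of recently upwelled coastal water.

## Models and formulas

**Euler step.** With position (λ, φ) in degrees, velocity (u, v) in m s⁻¹
and a spherical Earth of radius R = 6 371 000 m,

    Δλ = −u·Δt / (R cos φ) · 180/π,   Δφ = −v·Δt / R · 180/π

for a backward step (signs flipped forward). The scheme is first order; for
smooth analytic flows the endpoint error scales ~O(Δt), which the tests
verify against a solid-body-rotation orbit. No diffusion or random-walk
component is added, so trajectories are bit-reproducible.

**Beaching.** The velocity archive is undefined on land, so a drifter whose
interpolation stencil becomes all-land has left the resolved ocean. Policy:
freeze in place with status `beached` (`out_of_domain` if it crossed the
grid bounding box). Frozen drifters keep their position for all earlier
offsets and stay countable — active + beached + out-of-domain always equals
the seeded count — but contribute no further environmental samples.

**Masked bilinear interpolation.** The four surrounding nodes are weighted
bilinearly; land nodes are dropped and the remaining weights renormalised
to sum to one. A value is missing only when all four nodes are land. This
avoids the alternative of treating land as zero velocity, which would
artificially drag parcels ashore. No extrapolation in space or time: out-of
range queries raise, and the tracker layer decides what that means.

**Mixed-layer PAR.** A cell mixed homogeneously through a layer of depth H
experiences the depth average of exponentially attenuated surface light:

    PAR(I0, H) = (1/H) ∫₀ᴴ f·I0·e^(−kz) dz = f·I0·(1 − e^(−kH))/(kH)

with f = 0.42 (PAR fraction of incoming shortwave) and k = 0.2 m⁻¹
(constant attenuation). The implementation uses `expm1`, so the H → 0 limit
(42% of I0) is exact to machine precision even at H = 10⁻⁹ m. Self-shading
by the bloom itself is deliberately excluded: bloom-induced shading would
correlate the light history with the outcome being explained. MLD enters
instantaneously at each sample time, not time-averaged.

**Distance to coast.** Per wet node, the minimum great-circle (haversine)
distance to any land node, in nautical miles (1852 m). Node-to-node
distance rather than distance to a vector shoreline: at ~1 nm grid
resolution the difference is below the grid scale. Land nodes carry 0.

**Offshore exposure.** Per-drifter minima over the window, then the
(1 − coverage) *nearest-rank* quantile (the ⌈q·n⌉-th smallest minimum). The
nearest-rank rule is chosen because the statistic is reported as a plain
percentage of parcels; it is monotone in coverage and exactly reproducible
by order-statistic enumeration, which the tests exploit.

**Whisker statistics.** Quartiles by linear interpolation between order
statistics (numpy's default); median and quartiles are computed on the full
bin, the 1.5·IQR fence removes outliers only for the whisker extent — the
standard box-whisker semantics. Counts of retained and discarded points are
reported per bin, and empty bins appear explicitly with n_used = 0.

## Synthetic scenarios: what they emulate and what they do not

The generator stands in for three external data sources: an ocean-model
velocity/forcing archive, a satellite bloom-classification product, and a
bottle-data nutrient extract. It produces a rectangular basin enclosed by a
one-node land rim (solid walls, as in a regional model domain; optional
peninsula for a nontrivial distance field), analytic velocity regimes
(uniform, solid-body rotation, steady or time-periodic double gyre with
no-flow walls), smooth forcing fields (baseline + meridional gradient +
Gaussian noise), bloom masks confined beyond a designed offshore distance
D* with a uniformly sprinkled inconclusive fraction as a cloud proxy, and
nutrient tables with lognormal noise around zone medians that step up by a
designed coastal offset.

Design choices worth recording:

* **Lognormal nutrient noise** (σ of log-concentration, default 0.3):
  bottle concentrations are positive and right-skewed, and the median of a
  lognormal is its scale parameter, so the designed coastal−offshore median
  difference is exactly the configured offset — the recovery tests have an
  unbiased truth. Concentrations are rounded to instrument precision
  (0.1 µmol L⁻¹ nitrate, 0.01 µmol L⁻¹ phosphate), which quantises sample
  medians but does not bias the difference.
* **The median step sits at 50 nm**, inside the excluded 40–60 nm band, so
  both zoned bins see a clean single-median population.
* **Default scenario** (the conditions the recovery tests run under):
  120×100 nodes over the study box, 3-h cadence over 61 days, a weak steady
  double gyre (peak 0.005 m s⁻¹), bloom placement beyond D* = 15 nm with
  50% coverage and 10% inconclusive, PO₄ coastal offset 0.1 µmol L⁻¹,
  2000 records per month. The gyre is deliberately weak: its closed,
  wall-parallel streamlines displace parcels by only ~5 nm over the 21-day
  exposure window, so the designed offshore confinement remains recoverable
  from the *traced* histories, not just from the seed positions.
* **Convergence tests run on a low-latitude basin** (0–4°E, ±2°N). The
  rotation regime is built in a local tangent plane, while the tracker
  converts metres to degrees with cos(latitude) at the moving position; at
  Baltic latitudes that metric mismatch is the same order as the Euler
  error being measured, at |φ| < 2° it is ~10⁻⁴ and the constant-radius
  orbit is a clean oracle.

What the scenarios do **not** emulate: realistic Baltic circulation
(mesoscale eddies, coastal jets, wind events), correlated cloud fields,
seasonal trends inside a month, spatial autocorrelation of nutrient
sampling effort, or any feedback of biology on physics. Passing tests
demonstrate that the machinery recovers designed structure under known
conditions; they say nothing about retrieval skill on real satellite or
hydrographic data.

## Numerical choices and degenerate inputs

* Grids are node-registered, regular rectilinear lon/lat; longitudes in
  [−180, 360) are normalised to one increasing branch at load. Curvilinear
  and staggered grids are out of scope; archived velocities are assumed
  collocated.
* Missing values are NaN everywhere in memory and declared via CF-style
  fill attributes on disk; 0 is always a legal field value.
* A query exactly on a snapshot time uses that snapshot alone; a query on a
  grid node reproduces the node value exactly.
* `window` must be an integer multiple of `dt`; substepping below the
  archive cadence is available (`substeps`) and interpolates velocities to
  sub-step times.
* Population (not sample) standard deviation in group envelopes; at
  ensemble sizes of ~10³ the distinction is negligible, and the envelope is
  descriptive, not inferential.
* Empty statistic requests fail loudly: no bloom drifters, all-wet grids
  (distance undefined), non-positive MLD, negative distances.

## Problem sizes

Default test and analysis scale: 4000 drifters × 480 steps (60 days at
3 h) on a 120×100 grid — a complete scenario generation, trace, sampling
and contrast runs in seconds on one core. Oracle-equivalence checks run on
≤ 30×30 grids and ≤ 50-record bins where exhaustive brute force is exact
and fast.

## Known limitations

* First-order Euler only as the production scheme; higher-order integrators
  were not added because the traced product is group statistics over
  thousands of parcels, not individual path accuracy.
* Freeze-in-place beaching biases long histories of near-coast parcels
  toward their beaching position; such samples are excluded from
  statistics rather than imputed, which shrinks per-offset counts instead.
* Distance to coast is resolution-limited by the land mask; a parcel inside
  one grid cell of the shore can carry a distance of up to one cell size.
* The nutrient climatology applies no quality control beyond the IQR fence;
  duplicate casts or instrument drift in real extracts would pass through.
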