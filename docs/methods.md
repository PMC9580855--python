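# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `smlmtk`, and what the simulation-based tests do and
do not establish about real data.

## Localization tables

A localization table is rows of numbers with any single-character
separator. The reader sniffs the delimiter from the first data line
(tab, comma, semicolon, whitespace, whichever splits into the most
fields) and treats the first row as a header iff any of its fields
fails numeric parsing — this accepts headerless tables and labelled
ones without a dialect flag, and a property test guarantees a numeric
first row is never swallowed. Rows whose field count differs from the
first data row abort the read naming the offending line; silent data
loss is opt-in (`skip_malformed=True`). Units default to micrometres
and seconds; nanometre tables are handled by `scale=1e-3` at read time.
When no time column is mapped, the frame index times `dt` (default 1)
stands in; the conversion to seconds only matters inside the dynamics
estimators.

Analysis runs serialize to JSON records (tool, parameters including
seeds, outputs). The `created` timestamp is optional so that a
fixed-seed pipeline produces byte-identical records; the CLI stamps
wall-clock time.

## Geometric selection

All selections are closed sets: points exactly on a sphere surface,
hull facet, clipping plane or threshold bound are kept, which makes the
operations deterministic and lets every shape be checked against a
per-point brute-force predicate. Hull membership uses the facet
equations of the landmark convex hull with a 1e-9 inner-side tolerance.
The segment profile projects points onto the segment axis, keeps
parameters in [0, 1] (optionally within a cylinder radius) and bins
into equal intervals with the last bin right-closed, so the total count
is conserved. Angles are reported in degrees.

## Local density and blinking merge

Densities are k-nearest-neighbour (d = k / ((4/3)π r_k³), self
excluded) or fixed-radius counts. No boundary correction is applied, so
densities within ~r_k of the cloud edge are biased low; the kNN form
also carries the classical k/(k−1) upward bias for Poisson-distributed
points (exact for the interior, verified in tests). The estimate is a
colouring/exploration aid, not a calibrated intensity estimator.

The blinking merge links localization pairs within `eps` spatially
whose time gap is positive (one molecule emits at most once per frame,
so same-frame localizations never link directly) and at most `max_gap`.
Merged points are connected components of the link graph: a long-lived
emitter with short gaps merges into one point even when its first-to-
last span exceeds `max_gap`, and a slowly drifting blink chain stays
one component. Centroids are unweighted by default, intensity-weighted
on request. The component partition is verified against a dense
all-pairs transitive-closure oracle.

## Diffusion estimators

* **MSD** — time-averaged over overlapping pairs for a single selected
  trajectory (uniform frame interval required, 1e-6 relative
  tolerance); the ensemble variant pools pair-weighted across a set.
* **Apparent D** — OLS of MSD(τ) = 2dDτ + b over the first `n_fit`
  lags, default 4, the usual short-lag compromise between bias from
  confinement/anomalies and variance at long lags. b estimates 2dσ².
  A negative slope clamps to D = 0 with a flag.
* **Anomalous exponent** — OLS of log MSD vs log τ; default over all
  available lags, with the generalized coefficient from the intercept.
* **Translocation MLE** — the overdamped-Langevin Gaussian likelihood
  with static localization variance σ²/Δt added per step. For σ = 0 the
  maximizer is closed form (v̂ = ΣΔr/ΣΔt, D̂ = Σ|Δr − v̂Δt|²/Δt / 2dM).
  For σ > 0, v is profiled out by the precision-weighted mean and D
  found by bounded Brent search on [0, D_max] (D_max = 10× the naive
  closed-form estimate) followed by Newton polish on the profile score;
  the envelope theorem makes the profiled derivative exact. The numeric
  path reproduces the closed form to better than 1e-12 relative and
  matches a 2000-point grid search when σ > 0. A boundary optimum at
  D = 0 is flagged, as is a degenerate (all-identical-steps) input.
  With a flat prior the MAP coincides with this MLE; that is what the
  mapping pipeline reports. Motion-blur correction is deliberately
  omitted: only the static noise term is modelled, matching the
  simulator.

## Diffusion maps

k-means (k-means++ initialization, 10 restarts, fixed seed) tessellates
the positions; `points_per_region` can set k implicitly as
round(N/points_per_region). Each translocation belongs to the region of
its starting point — the standard convention in diffusivity mapping.
Regions with fewer than 20 translocations (configurable) are flagged
`insufficient_data` and carry no estimate rather than aborting the map.
Forces are reported as F = v·kT/D with kT defaulting to 1, i.e. in
kT/µm without a temperature input.

Region borders are the convex hulls of member points rather than
Voronoi cells of the centers: hulls are watertight, render as closed
surfaces, and are checkable against known polytopes; they can overlap
slightly and under-cover the domain, which is acceptable for
visualization. Colours come from min–max normalization of the mapped
value over valid regions through a named matplotlib colormap (default
viridis, colour-blind safe); transparency sets the alpha byte. Export
is ASCII PLY with per-vertex RGBA (byte-exact round trip, verified with
an independent parser) or OBJ with one group per region (OBJ carries no
colours).

## Simulator

The generator mirrors a nuclear bead-tracking experiment: default frame
interval 0.03 s, diffusivities of order 0.1–1 µm²/s, localization
precision tens of nm. Euler–Maruyama stepping (Δr = vΔt + √(2DΔt)η) is
adequate at these D·Δt scales; the heterogeneous landscape uses the D
and harmonic-well force of the region containing the current position
(Itô convention, no spurious-drift correction — so slow regions
accumulate density over time exactly as the estimators see in the
analysis). Boundaries reflect (a closed, nucleus-like volume).
Measurement noise is added to positions post hoc, producing precisely
the static σ²/Δt step-variance term the MLE corrects. Fractional
Brownian motion is generated exactly per axis by Cholesky factorization
of the fractional-Gaussian-noise covariance (Hurst H = α/2, capped at
5000 steps; jitter-and-retry on numerical non-PD). Blinking emitters
follow an on/off Markov chain with an absorbing bleached state, one
noisy localization per on frame.

Every generator draws from its own seeded `default_rng` stream and is
bit-reproducible. What the simulator does **not** emulate: motion blur
within an exposure, tracking errors (broken/switched trajectories),
anisotropic localization precision (real z-precision is typically 2–3×
worse than lateral), drift of the sample stage, and density-dependent
detection failure during blinking overlap. Passing recovery tests
therefore demonstrates estimator correctness under the stated model,
not robustness to those artefacts.

## Validation study designs

Problem sizes were chosen so the whole suite runs in minutes on one
core while leaving clear statistical margins:

* Homogeneous recovery: 100 trajectories × 100 steps at D = 0.5 µm²/s,
  σ ∈ {0, 0.03 µm}. The σ-naive MLE inflates D̂ by σ²/Δt = 0.03 µm²/s;
  the σ-aware MLE removes this within sampling error.
* Two-region landscape: D = 0.1 / 1.0 µm²/s in adjacent 10 µm boxes,
  2000 trajectories × 10 steps (≈10⁴ translocations per region). Boxes
  are deliberately much wider than the per-run diffusion length and the
  trajectories short: the k-means boundary plane then sits close to the
  true interface. Because the fast region's steps carry 10× the
  variance, even ~3% leakage across a misplaced boundary would inflate
  the slow region's D̂ by ~25%; this geometry keeps leakage well under
  1% (verified across 10 consecutive seeds).
* Anomalous exponents: α ∈ {0.5, 1.0, 1.5}, 100 fBm trajectories × 500
  steps, per-trajectory log–log fits over lags 1–10, mean within 0.1.
* Blinking: 200 molecules separated by ≥ 5·eps with σ = eps/5, so the
  spatial linking radius alone separates molecules and the recovered
  molecule count is exact.

## Camera paths

Waypoint scripts are JSON ({fps, waypoints: [{position, look_at,
dwell_s, transit_s, visual}]}); a whitespace line dialect is accepted.
The schedule dwells, then transits; positions interpolate linearly or
along a uniform Catmull-Rom spline with *reflected* endpoint phantoms
(p₋₁ = 2P₀ − P₁), which keeps the spline exactly linear through
collinear, evenly spaced waypoints. Orientation comes from the
interpolated look-at direction with world up +z, falling back to +y for
axial views. Frames are sampled at tᵢ = i/fps with
n = round(duration·fps) frames; since those samples end one interval
short of the path end, the final frame clamps to the last waypoint's
pose. Consequence: the last inter-frame step can span up to two frame
intervals — the price of having exact endpoints, an exact frame count
and exact on-grid samples simultaneously, which are jointly
incompatible with a uniform speed bound. Pose sequences export as CSV
(t, x, y, z, qw, qx, qy, qz) for any renderer; rendering itself is out
of scope.

## Known limitations

* No edge correction in density estimation; no Voronoi region mode yet.
* The MLE treats steps as independent; the σ > 0 static-noise model
  ignores the negative correlation that noise induces between
  consecutive translocations, a second-order effect at σ² ≪ DΔt.
* The interaction potential is summarized per region by the drift; no
  global (coupled-region) potential field is inferred.
* Convex-hull region meshes can overlap between regions.
* fBm generation is O(n²) memory in trajectory length (Cholesky), hence
  the 5000-step cap.
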