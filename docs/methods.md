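# Methods

## The measurement model

A micro-CT scan of a coral skeletal fragment is a 3D attenuation volume in
which three materials occupy ordered intensity bands: air (voids larger than
the voxel), a partial-volume intermediate band produced by pores smaller
than the scan resolution, and dense aragonite. The package's unit of
analysis is the *colony volume*: every voxel that belongs to the fragment,
including its internal voids. Container material, fragment separators and
any air connected to the exterior are excluded as mask — a void that opens
to the outside of the colony is an indentation of its surface, not a pore.

Four response variables are computed per cubic analysis window (default
0.9 mm edge, rounded to a whole voxel count, non-overlapping tiles anchored
at the colony bounding box):

- `MiP = 100 · micropore / (solid + micropore + air)`
- `MaP = 100 · air / (solid + micropore + air)`
- `SVF = 100 · solid / (solid + micropore + air)`
- `TP = MiP + MaP` (exactly, by construction)

so `MiP + MaP + SVF = 100` holds per window up to floating-point error.
Windows whose colony content is below `min_colony_fraction` (default 0.05)
of the *nominal* window volume are flagged invalid and excluded from all
statistics. Using the nominal rather than the clipped volume as the
denominator matters: a grid whose bounding box is extended by a single
stray voxel otherwise produces a thin clipped layer of near-pure crust that
masquerades as a fully valid window and biases the basal end of every
profile.

Whole voxels are counted; no partial-volume weighting is applied to the
intermediate band. Micropore content below a voxel therefore registers only
when it dominates that voxel's attenuation.

## Masking and segmentation

The masking filter floods air-intensity voxels (below `air_threshold`) from
the volume boundary with 6-connectivity (face adjacency, conservative
against diagonal leaks through thin walls; 26-connectivity is available).
Everything reached is exterior. Among the remaining voxels, only the
largest connected component is kept as the colony: the scanning tube and
separators are bathed in exterior air, so they form separate, much smaller
components and are masked without any assumption about their attenuation.
An optional intensity cap (`container_threshold`) can mask additional
high-attenuation material. Enclosed voids are inside the colony component
and survive as candidate macropores.

Phase thresholds come either from config (`fixed`) or from a three-class
multi-level Otsu criterion over the colony voxels (`auto`); labelling is the
deterministic rule AIR < `t_low` ≤ MICROPORE < `t_high` ≤ SOLID. No
morphological cleanup is applied by default. On noiseless phantoms the
chain recovers the generator's labels exactly; at noise σ = 5% of the
solid–air gap the voxel disagreement is orders of magnitude below 1%
(misclassification requires a ≳5σ noise excursion past the nearest
threshold).

## Vertical profiles and normalizations

The vertical (Z) axis runs apical (living tissue, index 0) to basal; scans
oriented the other way are flipped on read via `flip_z`. A fragment's
profile is the per-Z-level mean ± s.e.m. of each variable over the valid
windows at that level.

Two normalizations make fragments comparable before pooling:

- **Coordinates.** `z_norm = (z − z_min_own) / (Z_max − Z_min)`, where the
  denominator is the Z range of the *largest* selected fragment, then
  `z_mm = z_norm · conversion + correction` with defaults 8 mm (the length
  of the largest porosity map) and 0.45 mm (half a window, placing each
  point at the center of its sampling interval). The largest fragment's
  endpoints therefore map to 0.45 and 8.45 mm. The display cap of 10 mm is
  presentation only.
- **Variables.** Within each fragment, `Δ = v − v_min`,
  `Δ_max = v_max − v_min`, `v_norm = Δ / Δ_max`. A constant profile raises
  a zero-range error rather than dividing silently. Raw-value pooling
  across fragments flattens the band signal; the delta transform preserves
  it.

## LOESS and extremum localization

`fit_loess` is locally weighted polynomial regression: at each point of a
uniform grid spanning the data range (never extrapolating), the
`ceil(span · n)` nearest observations receive tricube weights and a local
quadratic is fitted by weighted least squares. Defaults: span 0.3, degree 2,
101 grid points; the neighborhood is floored at degree + 1 points. The fit
is deterministic. Optional case weights multiply the kernel, mirroring the
`weights` argument of R's `loess`.

`fit_map_loess` fits the window cloud of a porosity map directly (window
value against physical window-center z), weighting each window by its
colony voxel count. For a void process dominated by resolvable pores of
characteristic volume `v`, the sampling variance of a window's porosity
scales as `p(1−p)·v/V_colony`, so colony-volume weights are the
inverse-variance weights; equal weighting would let low-volume edge slivers
dominate the local fits.

Peaks and valleys are grid argmax/argmin of the fitted curve, ties broken
toward the apical end; an extremum on the first or last grid point carries
an `at_boundary` flag so monotone profiles can be screened out. Zone
assignment splits the profile at the stereoscope-measured band interval
`[low, high]`: tissue below `low` (half-open), band within `[low, high]`
(closed), skeleton above.

## Statistics

All tests are explicit wrappers around scipy/statsmodels returning tidy
records: Spearman correlations (average ranks, two-sided p) between aligned
profile series; extremum-vs-band concordance as a Spearman coefficient plus
a two-group one-way ANOVA on the paired location sets; three-zone one-way
ANOVA with Tukey HSD adjusted pairwise p-values (per variable × grouping
family, no global correction); Kruskal–Wallis for the unbalanced location
comparison; Pearson correlations across fragment means. Shapiro–Wilk and
Levene diagnostics are attached to zone results but never switch the test.
Two identical constant groups yield H = 0, p = 1 by definition rather than
a 0/0 tie correction. Simulated calibration at n = 30/zone gives a type-I
rate within [0.03, 0.07] at α = 0.05, and power ≈ 1 for a +5σ band shift at
n = 20/zone.

Per-Z observations within a zone are serially correlated along the profile;
the zone ANOVA treats them as independent, so its p-values are
anti-conservative in that respect. This matches the analysis convention the
package reproduces and is flagged here as a known caveat.

## The synthetic phantom

`generate_phantom` emulates the features the pipeline must handle, with an
exact per-voxel ground truth:

- **Geometry.** A cylindrical colony nested inside an open-ended
  cylindrical container wall (high attenuation), with an air gap between
  colony and wall and an air margin to the volume boundary. A solid crust
  (2 voxels radial, 1 axial) keeps the colony surface closed, so interior
  voids are genuine macropores rather than exterior-connected cavities.
- **Macropores.** A Boolean model of overlapping spheres, radii uniform in
  0.1–0.5 mm (resolvable at the 24.3 µm default voxel). The Poisson center
  intensity per Z layer is `λ(z) = −ln(1 − f(z)) / v̄` with `v̄` the mean
  sphere volume, so the expected void fraction tracks the target profile
  `f(z)`. Centers are sampled from the core padded by the maximum radius on
  all sides (carving clipped to the core) — the standard edge correction
  that keeps coverage stationary up to the core boundary.
- **Micropores.** Single voxels of intermediate attenuation drawn per voxel
  at a Z-dependent rate — a partial-volume proxy, since real boring
  channels (< 10 µm) are sub-resolution by definition. The per-voxel rate
  is rescaled by the realized solid fraction so the *colony-volume*
  micropore percentage matches its target.
- **Band.** A Gaussian bump (FWHM = `band_width_mm`) raises the micropore
  fraction by `mip_amplitude_pct` and lowers the macropore fraction by
  `map_decrement_pct` at its center; an optional skew parameter leans the
  bump toward the apical side. Defaults: baseline MiP 5%, amplitude +5
  points; baseline MaP 35%, decrement −10 points; band FWHM 1.2 mm. These
  land fragment means in the ranges observed for massive *Porites*
  (MiP ≈ 4–11%, MaP ≈ 20–47%).
- **Noise.** Additive Gaussian, σ = 5% of the solid–air intensity gap by
  default. Intensity levels: air 0, micropore 100, solid 200, container
  250.
- **Determinism.** One seed drives every draw; identical seeds give
  bit-identical volumes.

`truth_profile` counts the true labels per 0.9 mm slab — no segmentation —
and is the oracle against which pipeline estimates are tested.

What the phantom does *not* model: branching skeletal morphology, X-ray
physics (beam hardening, reconstruction artifacts, partial-volume
gradients at interfaces), spatially correlated noise, or irregular fragment
shapes. Passing recovery tests therefore demonstrates the correctness of
the measurement chain under the stated geometry and noise model, not
robustness to every artifact of real scans.

## Problem sizes and statistical design of the cohort checks

Macroporosity estimates are intrinsically noisy because single spheres are
large relative to an analysis window: the per-slab standard deviation
scales as `sqrt(p(1−p)·v_char/V_slab)`. The cohort analyses therefore use
phantom cross-sections wide enough that the smoothed profile noise is about
a third of the band dip: band-recovery cohorts run at 176 × 176 × 452
voxels (colony ≈ 4 mm diameter × 10.9 mm, twelve 0.9 mm levels), and the
profile-correlation cohort at 176 × 176 × 304 with a 2.5 mm-wide band, so
that the band structure spans most of the profile rather than two levels of
a flat curve. Unit tests use smaller phantoms (~100³) where only counting
identities, not localization power, are at stake.

At these sizes the pipeline localizes the microporosity peak within
±0.9 mm of the true band center in essentially every run, and the
macroporosity valley within ±1.8 mm in roughly nine of ten runs — the
residual failures are basal-side noise excursions in the long flat region
of the profile, which is also where real profiles show their largest
dispersion.

## Defaults at a glance

| Parameter | Default | Meaning |
|---|---|---|
| `voxel_size_um` | 24.3 | voxel edge; treated as data, never assumed from file |
| `window_size_mm` | 0.9 | porosity window edge (≈37 voxels) |
| `min_colony_fraction` | 0.05 | validity cutoff vs. nominal window volume |
| `loess_span` | 0.3 | neighbor fraction of the LOESS fits |
| `conversion_factor_mm` | 8 | length of the largest porosity map |
| `correction_factor_mm` | 0.45 | half-window centering offset |
| `threshold_mode` | auto | three-class multi-Otsu over colony voxels |
| connectivity | 6 | face adjacency for the boundary flood |

## Known limitations

- Micropore quantification is a whole-voxel proxy; it undercounts diffuse
  sub-voxel porosity and cannot separate channel geometry from other
  partial-volume sources.
- The automatic threshold criterion assumes three separable intensity
  modes within the colony; heavily beam-hardened or low-contrast scans need
  fixed thresholds.
- Zone statistics inherit the serial-correlation caveat above.
- The X/Y axes are exported but not modelled; the vertical axis is where
  the biology stratifies.
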