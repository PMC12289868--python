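# coralpore

Micro-CT porosity analysis of coral skeletons: quantifying how the
endolithic "green band" — the pigmented layer of boring microalgae living
beneath the coral tissue — reshapes the skeleton's internal structure.

Massive corals such as *Porites* stratify vertically into three
microenvironments: living tissue at the apical surface, the green band a few
millimeters below it, and bare skeleton toward the base. X-ray
microtomography resolves this structure as an attenuation volume in which
dense aragonite, resolvable voids (macropores) and sub-resolution boring
channels (micropores, visible only through their partial-volume intermediate
attenuation) occupy distinct intensity bands. `coralpore` implements the
full analysis chain for such volumes, for researchers studying coral
bioerosion and skeletal microstructure:

1. **Masking** — exterior air (anything flood-connected to the scan
   boundary) and container artifacts are excluded; interior voids remain
   part of the colony. Voids open to the colony exterior are *not* pores.
2. **Four-phase segmentation** — every voxel becomes SOLID, MICROPORE, AIR
   (macropore) or MASK, via a three-class multi-level Otsu criterion on the
   colony histogram (or fixed thresholds).
3. **Porosity mapping** — the labelled volume is tiled into 0.9 mm cubic
   windows; each window reports microporosity (MiP), macroporosity (MaP),
   total porosity (TP = MiP + MaP) and solid volume fraction (SVF), as
   percentages of the window's colony volume, with MiP + MaP + SVF = 100.
4. **Vertical profiles** — per-level means ± s.e.m. along the apical→basal
   axis; coordinates standardized against the largest fragment and mapped to
   millimeters,

   `z_mm = z_norm · 8 mm + 0.45 mm`,  `z_norm = (z − z_min) / (Z_max − Z_min)`,

   and variables delta-normalized within each fragment,

   `v_norm = Δ / Δ_max`,  `Δ = v − v_min`,  `Δ_max = v_max − v_min`.
5. **LOESS modelling** — local quadratic regression with tricube weights
   locates the microporosity peak and macroporosity valley that mark the
   green band; windows are weighted by colony volume so edge slivers do not
   dominate.
6. **Statistics** — Spearman correlations along the profile, extremum vs.
   observed-band concordance, three-zone ANOVA + Tukey HSD, species
   ANOVA/Tukey and location Kruskal–Wallis on fragment means, Pearson
   correlations across fragments.

Because deposited scans are tens of gigabytes, the package ships a
first-class synthetic-data module: `generate_phantom` builds tomograms with
a known phase ground truth — a cylindrical colony inside a scanning tube,
Boolean-model spherical macropores whose rate dips inside a configurable
green band, voxel-scale micropores whose rate rises there, and additive
Gaussian noise — so every stage is testable against exact labels.

## Worked example

```python
from coralpore import *

truth = SyntheticTruth(seed=7, band_center_mm=2.5, band_width_mm=2.5)
tomo, labels = generate_phantom(truth, (176, 176, 304), voxel_size_um=24.3)

phases = segment_tomogram(tomo)          # mask + auto thresholds + labels
pmap = compute_porosity_map(phases)      # 0.9 mm windows
print(fragment_mean(pmap).to_string(index=False))

curve = fit_map_loess(pmap, variable="MiP", span=0.3)
peak = locate_extremum(curve, kind="peak")
print(f"MiP peak at {peak.location_mm:.2f} mm (true band center {truth.band_center_mm} mm)")

prof = extract_vertical_profile(pmap)
rho = correlate_profiles(prof.data["MiP_mean"].to_numpy(),
                         prof.data["MaP_mean"].to_numpy())
print(f"Spearman rho(MiP, MaP) along Z = {rho.coefficient:.2f}")
```

prints

```
variable      mean      sem   n
     MiP  7.012477 0.205356 160
     MaP 31.811461 1.574554 160
      TP 38.823938 1.402691 160
     SVF 61.176062 1.402691 160
MiP peak at 2.43 mm (true band center 2.5 mm)
Spearman rho(MiP, MaP) along Z = -0.71
```

The fragment averages say micropores hold ~7% of the colony volume and
macropores ~32%; the solid fraction (61%) exceeds total porosity (39%). The
LOESS peak recovers the generator's band center to within a tenth of a
millimeter, and micro- and macroporosity move in opposite directions along
the vertical profile — the structural signature of the band.

A `coralpore` console script exposes the same pipeline stage by stage
(`simulate`, `segment`, `porosity`, `profile`, `stats`, `run`), writing a
manifest with checksums so that a given config + seed reproduces identical
artifacts.

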