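# octaquant

Quantification of vessel density in OCTA (optical coherence tomography
angiography) en-face images, and the cohort statistics built on it.

OCTA renders perfused vessels as bright pixels in a 3 × 3 mm en-face slab
(superficial retinal layer SRL, deep retinal layer DRL, or temporal
conjunctiva), sampled at 512 px per 3 mm. Case/control studies of ocular
microcirculation — e.g. in systemic autoimmune disease — compare *vessel
density* between groups, sector by sector around the fovea. `octaquant`
implements that pipeline end to end for researchers who have en-face rasters
and a cohort manifest:

1. **Vessel maps** — preprocessing (optional inversion, percentile contrast
   balance, morphological background removal), global Otsu thresholding into
   a binary perfusion map, removal of sub-vessel-scale components,
   topology-preserving skeletonization, caliber estimation from the Euclidean
   distance transform, and the split into microvessels (MIR, caliber
   ≤ 25 μm), macrovessels (MAR, > 25 μm) and their union (TMI).
2. **Sector geometry** — six concentric rings C1–C6 between the 0.6 mm
   foveal avascular zone and the 2.5 mm circle (radial bandwidth
   (2.5 − 0.6)/2 = 0.95 mm, each ring 0.95/6 ≈ 0.16 mm), SR/SL/IL/IR
   hemisphere quadrants, S/I/L/R ETDRS-style diagonal wedges, and the whole
   3 × 3 mm field (the only ROI used for conjunctival scans). Left-eye (OS)
   images are mirrored to right-eye orientation before pooling.
3. **Density metrics** — perfusion (area) density
   |vessel ∧ region| / |region| and skeleton (length) density in mm/mm²,
   per region × vessel class, then averaged across the two eyes of each
   subject.
4. **Cohort statistics** — two-sample t-tests (Welch default), Pearson
   correlation, and empirical ROC analysis with tie-corrected AUC
   (≡ Mann–Whitney U/(n₁n₂)), DeLong 95 % CI, Youden-optimal cutoff and
   likelihood ratios.
5. **Synthetic angiograms** — a seeded branching-walker generator produces
   images with exactly known vessel masks, calibers and per-region
   densities, plus two-group cohorts with configurable group means and a
   latent (negative) conjunctival-vs-deep-retinal density correlation, so
   the whole pipeline is testable without patient data.

## Worked example

```python
from octaquant import (SyntheticSpec, generate_tree, build_vessel_maps,
                       make_annuli, perfusion_density, skeleton_density,
                       ScanProtocol, validate_protocol)

spec = SyntheticSpec(target_perfusion=0.30, noise=0.1, seed=42)
img, truth = generate_tree(spec)
maps = build_vessel_maps(img)

print(f"true perfusion fraction : {truth.per_region_density['whole']:.4f}")
print(f"recovered (TMI, whole)  : {maps.total.mean():.4f}")
print(f"macrovessel share (MAR) : {maps.macro.sum() / maps.total.sum():.3f}")

annuli = make_annuli(img.grid_px, img.pixel_pitch_mm)
for name, region in annuli.regions.items():
    pd = perfusion_density(maps.total, region)
    sd = skeleton_density(maps.skeleton, region, img.pixel_pitch_mm)
    print(f"{name}: perfusion {pd:.3f}   skeleton {sd:.2f} mm/mm^2")

print(validate_protocol(ScanProtocol()))
```

prints

```
true perfusion fraction : 0.2859
recovered (TMI, whole)  : 0.2858
macrovessel share (MAR) : 0.465
C1: perfusion 0.348   skeleton 14.72 mm/mm^2
C2: perfusion 0.267   skeleton 10.14 mm/mm^2
C3: perfusion 0.301   skeleton 11.90 mm/mm^2
C4: perfusion 0.342   skeleton 12.80 mm/mm^2
C5: perfusion 0.274   skeleton 11.27 mm/mm^2
C6: perfusion 0.257   skeleton 11.09 mm/mm^2
{'b_scans_per_volume': 1080, 'total_a_scans': 933120}
```

The recovered whole-field density agrees with the generator's ground truth
to 10⁻⁴ (the speckle noise is separable from the bimodal vessel/background
intensities), per-ring densities vary with the local geometry of the grown
network, and the scan-protocol arithmetic derives 216 × 5 = 1080 B-scans per
volume and 4 × 1080 × 216 = 933 120 A-scans.

A full cohort run goes through the CLI:

```sh
octaquant simulate --outdir cohort --n-per-group 12 --seed 1
octaquant quantify --manifest cohort/manifest.csv --outdir results --level subject
octaquant stats --records results/density_eye.csv --out results/eye_level.csv --level eye
octaquant validate-protocol
```

`quantify` writes tidy eye-level and subject-level density CSVs, per-region
group-comparison tables (means ± SD, t, p, AUC with DeLong CI) and a JSON
run log; reruns with the same config and seed are bit-identical.

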