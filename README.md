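# ricevigor

Non-destructive, image-based phenotyping of **early seedling vigor** in rice.

Early seedling vigor — rapid shoot biomass accumulation in the first weeks
after sowing — is a key trait for direct-seeded rice, where seedlings compete
directly with weeds. Destructive growth analysis (uprooting, scanning, drying)
cannot follow the same plant over time and is impossible in segregating
breeding populations. `ricevigor` implements the alternative: photograph each
potted seedling from one top view and two side views at 90°, segment the green
shoot, and use calibrated projected areas as a biomass proxy.

The pipeline:

- **Segmentation** — hue/saturation/brightness thresholding (green band on a
  dark background; inverted brightness logic for flatbed scans), morphological
  opening and small-component removal, with every threshold recorded.
- **Calibration** — mm-per-pixel from a scale marker of known length:
  `mm_per_px = length_mm / ‖p₂ − p₁‖`.
- **Geometry** — per-view projected area; whole-plant area by imaging
  `WPA_i = A_top + A_side0 + A_side90` (mm²); whole-plant area by scanning
  `WPA_s = Σ object areas`; top-view shape descriptors: convex hull area,
  caliper length (maximum Feret diameter, by rotating calipers), compactness
  `= top view area / convex hull`, and moments-ellipse eccentricity.
- **Growth rates** between observation days t₁ < t₂ for any quantity v:
  `AGR = (v₂−v₁)/(t₂−t₁)`, `RGR = (ln v₂ − ln v₁)/(t₂−t₁)`,
  `CGR = (v₂−v₁)/(P·(t₂−t₁))` with P the spacing area in m² (default P = 1).
- **Statistics** — Pearson correlation and simple regression on genotype
  means, one-way ANOVA (from raw replicates or from mean ± SE summaries),
  covariance/correlation PCA with biplot coordinates, genotype ranking.
- **Synthetic scenes** — a parametric 3-D seedling projected into the three
  views with exact ground-truth masks, for validating the imaging operators.
- **Embedded tables** — published genotype-mean trait tables for seven rice
  genotypes (LB-46, GM-217, AC38399, ARC10656, Vandana, Sabita, Varshadhan)
  at 14 and 28 days after sowing (DAS), used by the statistics layer.

## Worked example

Simulate a scene, extract traits, and compute growth rates for LB-46:

```sh
$ ricevigor simulate --seed 7 --out scene/
wrote scene (seed 7) to scene

$ ricevigor traits --session scene/ --mm-per-px 0.25 --genotype SYN-1
genotype,replicate,das,area_top,area_side_0,area_side_90,wpa_i,top_view_area,convex_hull,caliper_length,eccentricity,major_axis_length,compactness,empty
SYN-1,1,14,631.75,1116.875,929.125,2677.75,631.75,7405.843750000002,127.15074714684141,0.5475959894687151,109.6009861231792,0.08530425719554235,False

$ ricevigor growth --fixtures --quantity wpa_i --genotype LB-46
genotype,agr,rgr,cgr
LB-46,212.36071428571427,0.09372208167160588,212.36071428571427
```

The traits row says the synthetic plant projects 631.75 mm² in the top view
and 2677.75 mm² summed over all three views (WPA_i); its top-view canopy
spans a 127.2 mm caliper with a convex hull of 7406 mm², giving the low
compactness (0.09) of an open, spread canopy. The growth row reproduces the
published LB-46 whole-plant-area rates between 14 and 28 DAS: CGR 212.36
mm² m⁻² day⁻¹ (at P = 1) and RGR 0.09 day⁻¹.

Segmentation of real captures works the same way:

```sh
ricevigor segment --image pot_top.jpg --view top \
    --marker 120,40,920,40,50 --out mask.png      # 800 px marker = 50 mm
```

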