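# carspat3d

Spatial quantification of CAR T cell imaging data, from whole-body
bioluminescence down to single cells — with synthetic phantoms so every
stage can be validated against exact ground truth.

Preclinical CAR T cell studies track the therapeutic cells at three
scales: reconstructed 3D bioluminescence tomography (BLT) volumes report
where luciferase-tagged T cells accumulate at the organ level; light-sheet
fluorescence microscopy (LSFM) of cleared tumors resolves individual
CD3-positive cells and their position relative to the tumor surface and
vasculature; and cyclic immunofluorescence of tumor sections phenotypes
those cells with dozens of markers. This package implements the
quantification that sits on top of all three:

* **`carspat3d.blt`** — organ-level BLT quantification. Light emitted deep
  in tissue reconstructs shifted and blurred, so anatomical organ masks
  under-collect signal; the standard compensation dilates the affected
  masks by a Euclidean ball of *n* voxels (`dilated_region`, exact against
  brute force). Also: sphere-based segmentation for organs without
  soft-tissue contrast (spleen, r = 10 mm), per-day whole-animal
  normalization, day-0 fold-change normalization of planar ROI series,
  caliper volume V = ½ L·W², and µCT mask volumes.
* **`carspat3d.lsfm`** — single-cell 3D spatial statistics: tumor masking,
  Otsu vessel segmentation, multiscale Laplacian-of-Gaussian spot
  detection with a minimum cell diameter of 8 µm, anisotropy-aware
  Euclidean distance maps to the tumor surface and vessel surfaces,
  distance-shell histograms, an exponential fit of infiltration depth
  (density ∝ exp(−d/λ)), a periphery/core split (equal-volume or fixed
  depth), neighbor-count density classes, middle-third maximum-projection
  profiles, and red→blue color-coded point-cloud export.
* **`carspat3d.cycif`** — 2D single-cell phenotyping: DAPI nucleus
  segmentation (18–60 px diameter, watershed separation), cytoplasm
  measured on an 11 px donut clipped against neighboring cells, per-cell
  log2(x+1) intensities with the per-channel background mode shifted to 0,
  3-SD outlier exclusion, CD3± gating (Otsu or explicit threshold) with
  CD4/CD8 subsets, marker distribution summaries, and a seeded UMAP
  embedding.
* **`carspat3d.stats`** — unpaired t-tests (Welch default), one-way ANOVA
  with all-pairs post-hoc tests (none/Holm/Tukey), and the pairwise
  significance matrix (PSM): one box per group pair, green if p < 0.05,
  red otherwise.
* **`carspat3d.synthetic`** — phantom generators with exact ground truth:
  a mouse-body phantom with ellipsoidal organs and shifted/blurred
  luminescent sources, a tumor phantom with a branching vessel tree and a
  T-cell point process (surface-decay plus optional vessel attraction),
  and a 2D cyclic-IF phantom with population-specific log-normal marker
  intensities.

## Worked example

Organ quantification with dilation compensation: a spleen source of 10⁶
a.u. whose reconstruction is shifted 3 mm and blurred by 1 mm.

```python
from carspat3d import blt, synthetic

spec = synthetic.BodyPhantomSpec(
    sources=[("spleen", 1.0e6, (3.0, 0.0, 0.0))],  # 3 mm apparent shift
    blur_sigma_mm=1.0,
)
volume, labels, truth = synthetic.make_body_phantom(spec)

anatomical = volume.data[labels.region("spleen")].sum()
compensated = volume.data[blt.dilated_region(labels, "spleen", 10)].sum()
print(f"anatomical mask recovers:   {anatomical:.3g}  ({anatomical/1e6:.1%})")
print(f"10-voxel dilation recovers: {compensated:.3g}  ({compensated/1e6:.1%})")
```

```
anatomical mask recovers:   4.22e+05  (42.2%)
10-voxel dilation recovers: 9.99e+05  (99.9%)
```

The anatomical mask misses more than half of the shifted signal; the
10-voxel dilation recovers it almost completely.

Single-cell infiltration statistics on the tumor phantom (2000 cells whose
density decays with a 50 µm length from the tumor surface, SNR 10):

```python
from carspat3d import lsfm

spec = synthetic.TumorPhantomSpec(seed=1)
channels, tumor_mask, vessel_mask, _ = synthetic.make_tumor_phantom(spec)
spots = lsfm.detect_spots(channels["cd3"], tumor_mask, min_diameter_um=8.0)
dmap = lsfm.distance_to_surface(tumor_mask)
lam = lsfm.fit_surface_decay(spots, dmap)
split = lsfm.periphery_core_split(tumor_mask, spots)
print(f"{len(spots)} cells detected")
print(f"infiltration decay length: {lam:.0f} um")
print(f"periphery: {split['periphery_pct']:.1f}%  core: {split['core_pct']:.1f}%")
```

```
1886 cells detected
infiltration decay length: 51 um
periphery: 80.7%  core: 19.3%
```

The detector recovers the generator's 50 µm decay length, and the
equal-volume split shows the surface-biased process concentrated in the
periphery — the spatial pattern these analyses are designed to quantify.

Every stage is also available from the shell:

```
carspat3d simulate body|tumor|cycif --config cfg.yaml --out DIR --seed N
carspat3d bltquant --volume v.tif --seg labels.tif --dilate spleen=10,lung=10 --out DIR
carspat3d lsfm --cd3 cd3.tif --lectin lectin.tif --tumor-mask mask.tif --out DIR
carspat3d cycif --dapi DAPI.tif --channels panel.yaml --out DIR
carspat3d psm --table groups.csv --alpha 0.05 --correction none --out DIR
```

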