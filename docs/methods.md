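# Methods

This note documents the models, conventions, and numerical choices behind
`carspat3d`, and what the phantom-based validation does and does not show
about real data.

## Grid and coordinate conventions

All volumes are regular anisotropic grids in (z, y, x) axis order. The
physical coordinate of voxel index *i* along an axis with spacing *s* is
(i + 0.5)·s — voxel centers, 0-based. Every distance is Euclidean in
physical units (mm for whole-body data, µm for microscopy). All spatial
statistics are invariant under axis permutation combined with the matching
spacing permutation; this is covered by a property test.

**Surface distance convention.** The distance of an interior voxel to a
region surface is the Euclidean distance from its center to the nearest
background voxel center, minus half the finest spacing, floored at zero.
This places voxels adjacent to background about half a voxel from the
surface, is exactly reproducible by brute-force enumeration (the oracle
used in the tests), and avoids committing to a sub-voxel surface model the
data cannot support.

## Body phantom and organ quantification

The body phantom is a set of disjoint organ ellipsoids inside a body
ellipsoid. Each luminescent source is rendered uniformly over its organ so
the integrated signal equals the requested total *exactly*, then
translated by a fixed integer-voxel offset and blurred with a Gaussian.
This mimics the dominant artifact of reconstructed deep-tissue
luminescence — an apparent centroid shift plus spread — without any claim
of photon-transport realism; translation and Gaussian blur are the
simplest signal-conserving model with those two effects. Boundary loss of
the blur is below 1% for the default geometry (0.5 mm voxels, organs well
inside an 80×64×64 grid).

Organ signal is the sum of voxel intensities over the (possibly dilated)
organ region. Dilation uses a Euclidean ball of radius *n* in **index
space** — the compensation is specified in voxels — with a
physical-distance variant behind a flag. "Dilated by 10 voxels" is read as
a single radius-10 ball; for a ball element this is nearly identical to 10
iterated unit dilations. After dilation a voxel may belong to several
organs; sums deliberately keep every membership (double counting), because
any tie-break would silently reassign signal; consequently organ fractions
are only guaranteed to sum to 1 for disjoint, undilated organs covering
all signal. The whole-animal region defaults to the union of labeled
voxels on phantoms; for real structural volumes `segment_body` thresholds
(Otsu by default). Missing measurement days are never interpolated.

Default body-phantom study conditions: three organs (lung, spleen, tumor),
1 mm blur, and a 3 mm source shift on the spleen — under which a 10-voxel
dilation recovers ≥ 95% of the emitted signal while the anatomical mask
recovers far less. These defaults are what the acceptance checks run.

## Tumor phantom and light-sheet analysis

The tumor is an ellipsoid (default semi-axes 240×280×280 µm on 2 µm
isotropic voxels — a scaled-down tumor chosen so the full pipeline runs in
tens of seconds; the geometry, not the scale, is what the analyses
measure). Vessels are a seeded branching random walk (4 trunks entering
from the surface, turn noise 0.25 per 10 µm step, branch probability 0.04,
capped at 800 centerline points ≈ 6% of tumor volume) rasterized as 15 µm
tubes via a distance query — the simplest connected surface for distance
statistics. Cells are drawn from a voxel-weighted point process with
density

    p(x) ∝ (1 − w)·exp(−d_surface(x)/λ_s) + w·exp(−d_vessel(x)/λ_v)

with λ_s = 50 µm (surface decay), λ_v = 25 µm, and attraction weight
w ∈ [0, 1] (default 0). Cells are rendered as Gaussian blobs of diameter
10–14 µm (σ = r/√3, the scale-space convention) at amplitude 100 over
additive Gaussian noise of SD 10 — SNR 10, the regime the detection
bounds are stated for. Noise is clipped at zero; no camera model is
implied. An optional minimum cell separation thins the process for
detection benchmarks ("well-separated" cells); the unthinned process is
used for distribution recovery.

**Spot detection** is scale-normalized Laplacian-of-Gaussian over five
physical scales spanning cell diameters 8–20 µm. Candidates are local
maxima of the cross-scale maximum response; a candidate is kept if

1. the mean intensity over the minimum-cell-diameter footprint reaches
   0.1× the in-mask channel maximum (the relative intensity threshold;
   footprint averaging rejects both noise maxima and aggregates of
   sub-resolution structures that do not fill a minimum-size cell), and
2. its LoG response at a guard scale 0.72× below the minimum does not
   exceed 1.2× its best in-range response (an object responding best
   below the minimum scale is smaller than the minimum diameter — the
   scale cutoff; for a 3D Gaussian blob the σ²-normalized LoG peaks at
   0.816× the blob σ, and the noiseless guard/main response ratio is
   ≈ 1.5–2.1 for 4 µm objects versus ≈ 0.6–1.15 for 8–14 µm cells on
   this grid, so 1.2 splits the two regimes).

Peak positions are refined per axis by quadratic interpolation of the
response. Detection errors out if any voxel spacing exceeds the minimum
diameter (such cells are unresolvable). No equivalence to any commercial
spot detector is claimed — only the published contract (cell diameter not
below 8 µm) and the recovery bounds the tests enforce.

**Infiltration decay fit.** Spot counts per depth shell are divided by
shell volumes (from the distance-map histogram) and a count-weighted
linear fit of log density against depth gives λ = −1/slope. Shells of
20 µm are used for fitting; presentation histograms default to 100 µm
bins.

**Periphery/core split.** Two boundary definitions are implemented because
the published description is ambiguous: the default places the boundary at
the median in-tumor surface distance (peripheral shell and core have equal
volumes; uniform cells then split 50/50 by construction), and a
fixed-depth mode takes an explicit boundary distance. Neither is asserted
to be the original tool's rule.

**Middle-third profile.** The tumor bounding box along the stack axis
(default z) is cut to its middle third (slices ⌊n/3⌋ to ⌊2n/3⌋−1),
maximum-projected, and reduced to a 1D profile along the longer in-plane
axis — by a second maximum by default, or by reading the projection's
central line (`reduce="centerline"`). The second maximum flattens
rim-bright signals, since every projected row crosses the rim; the
centerline mode preserves margin peaks and is the right choice for
margin-versus-core comparisons.

**Density classes** are neighbor counts within 100 µm, quantile-binned
into 5 ordered classes. **Vessel segmentation** is Otsu on in-tumor lectin
voxels with components under 10 voxels removed. **Color-coded export**
maps the chosen attribute linearly onto a red (minimum) → blue (maximum)
8-bit ramp; a degenerate range maps to the midpoint.

## Cyclic-IF phantom and phenotyping

The 2D phantom places non-overlapping nuclei (diameters 18–28 px by dart
throwing) and assigns populations by largest-remainder apportionment so
fractions are exact (default 60% "tumor" / 40% "tcell"). Marker
intensities are log-normal per population — parameterized as mean and SD
of log2 intensity (default SD 0.5; CD3 means 1 vs 6 give a cleanly bimodal
gate). Pixels are painted through a label image whose cytoplasm ring is
the nucleus expanded by the donut width and clipped against neighbors, so
every pixel carries exactly one cell's intensity plus background — the
ground truth is exactly the measurable quantity.

Segmentation smooths DAPI (σ = 2 px), thresholds with Otsu (which recovers
the half-maximum boundary of a blurred disc — important because a biased
boundary displaces the donut into background and biases all donut
intensities), and splits touching nuclei by a watershed seeded from
h-maxima of the smoothed distance transform. The tool-style percentage
parameters are mapped as: *nucleus separation* p → h-maxima depth
(1 − p)·mean nucleus radius (higher separation keeps more seeds; every
foreground component always keeps at least one seed); *nucleus detection*
p → minimum object peak brightness (1 − p)·image maximum. Both mappings
are calibrated on the package's phantoms and are not claimed to be
numerically equivalent to any vendor software. The cytoplasm donut is the
detected nucleus expanded by sensitivity×width with nearest-nucleus
clipping; the marker-weighted refinement of commercial "constrained donut"
features is not reproduced — the donut markers are only recorded.

Intensities are per-cell means over the compartment (donut by default),
then log2(x+1), then shifted so the per-channel mode (64-bin histogram) of
the cell population sits at 0. Outlier exclusion flags cells with any
channel outside mean ± 3 SD, computed once over all cells (single pass —
the iteration count of the original procedure is unstated); an
all-identical channel excludes nothing. The published excluded fraction
(5.7%) is a property of that study's tissue and is not a target here; on
a Gaussian null the rule excludes the analytic 0.27% two-sided tail,
which is what the calibration check asserts. Lint and out-of-focus
regions are accepted as an input QC mask (`apply_qc_mask`), not detected.
CD3 gating thresholds log2 CD3 (Otsu in auto mode as the stand-in for a
per-group heuristic threshold; explicit values supported; degenerate
distributions refuse auto mode); CD4/CD8 are gated within CD3+ by the
same rule. The embedding standardizes the marker matrix and runs UMAP
with a fixed random state (deterministic; single-threaded under a seed).

## Group statistics and the PSM

Two groups: unpaired two-sided t-test, Welch by default (safer for small
unequal-variance groups; pooled available). Three or more: one-way ANOVA,
then all-pairs tests feeding the pairwise significance matrix. The
post-hoc procedure behind the original matrices is unstated, so the
default is uncorrected pairwise Welch tests — matching a literal "p <
0.05" criterion — with Holm and Tukey HSD modes exposed. A pair is green
iff p < α strictly (p = 0.05 is red). Pair ordering defaults to
lexicographic and is configurable. Under a simulated null (four identical
normal groups of 7) the per-pair green rate matches α within binomial
error; Welch's exact size at n = 7 is ≈ 0.046, slightly conservative,
which the calibration test accommodates by checking the mean per-pair
rate.

## What the phantoms do and do not show

The phantoms give exact ground truth for geometry, signal totals, point
process laws, and population intensities, so they validate the
*quantification*: distance transforms against brute force, dilation
against enumeration, conservation, detection bounds at SNR 10,
distributional recovery, and statistical calibration. They deliberately
omit: photon transport and tomographic reconstruction artifacts beyond
shift+blur, realistic PSFs and light-sheet stripe/attenuation artifacts,
cell shape variation and clumping, staining gradients, illumination
fields, and cyclic-registration errors. Passing tests therefore show the
analysis code is correct under its stated model, not that the model
captures every property of real acquisitions.

## Problem sizes and determinism

Default problem sizes (2 µm tumor grids of ≈ 27M voxels, 2000 cells, 500
cyclic-IF cells, 1000 simulated null studies) were chosen so the full
validation runs in a few minutes on one CPU while keeping Monte-Carlo
error well inside every stated tolerance. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical spec
+ seed reproduces outputs bit for bit, and the CLI writes CSV with a fixed
float format so repeated runs are byte-identical.
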