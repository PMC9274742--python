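"""Synthetic phantom generators with known ground truth.

Three generators mirror the three data modalities the pipeline consumes:

* :func:`make_body_phantom` — a mouse-body phantom for organ-level
  bioluminescence quantification: ellipsoidal organs inside a body
  ellipsoid, each luminescent source rendered with an exactly known total
  signal, optionally translated (modeling the apparent shift of light
  emitted deep in tissue) and blurred.
* :func:`make_tumor_phantom` — a cleared-tumor light-sheet phantom: an
  ellipsoidal tumor, a branching vessel tree rasterized as tubes, and a
  T-cell point process whose density decays exponentially with distance
  from the tumor surface and can be mixed with attraction to vessels.
* :func:`make_cycif_phantom` — a 2D multiplexed-IF phantom: non-overlapping
  nuclei with population-specific log-normal marker intensities rendered
  on nucleus + cytoplasm-ring footprints.

No claim of optical realism is made anywhere: sources are uniform, blur is
Gaussian, noise is additive Gaussian clipped at zero.  The point is exact
ground truth for validating the quantification stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import LabelMask, SpotSet, VolumeImage, voxel_centers

__all__ = [
    "BodyPhantomSpec",
    "TumorPhantomSpec",
    "VesselParams",
    "CellParams",
    "CycIFPhantomSpec",
    "PopulationSpec",
    "make_body_phantom",
    "make_tumor_phantom",
    "make_cycif_phantom",
]

BODY_LABEL_NAME = "body"


# --------------------------------------------------------------------------
# body phantom
# --------------------------------------------------------------------------

@dataclass
class BodyPhantomSpec:
    """Mouse-body phantom: labeled organ ellipsoids with luminescent sources.

    Lengths are in mm.  ``sources`` entries are
    ``(organ_name, total_signal, centroid_shift_mm)`` where the shift is a
    3-vector translating the emitted light relative to the organ.
    """

    grid_shape: tuple[int, int, int] = (80, 64, 64)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    organs: list[tuple[str, tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=lambda: [
            ("lung", (12.0, 16.0, 16.0), (5.0, 4.0, 4.0)),
            ("spleen", (24.0, 16.0, 16.0), (4.0, 4.0, 4.0)),
            ("tumor", (34.0, 16.0, 16.0), (4.5, 4.0, 4.0)),
        ]
    )
    sources: list[tuple[str, float, tuple[float, float, float]]] = field(
        default_factory=lambda: [
            ("lung", 1.0e6, (0.0, 0.0, 0.0)),
            ("spleen", 1.0e6, (3.0, 0.0, 0.0)),
            ("tumor", 1.0e6, (0.0, 0.0, 0.0)),
        ]
    )
    body: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (20.0, 16.0, 16.0),
        (19.5, 11.0, 11.0),
    )
    blur_sigma_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma_mm < 0:
            raise ValueError("blur_sigma_mm must be >= 0")
        names = [o[0] for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("organ names must be unique")
        for name, total, _ in self.sources:
            if name not in names:
                raise ValueError(f"source references unknown organ {name!r}")
            if total < 0:
                raise ValueError(f"total_signal for {name!r} must be >= 0")
        extent = np.array(self.grid_shape) * np.array(self.voxel_spacing)
        for name, center, radii in self.organs:
            c, r = np.asarray(center), np.asarray(radii)
            if np.any(r <= 0):
                raise ValueError(f"organ {name!r} has non-positive radius")
            if np.any(c - r < 0) or np.any(c + r > extent):
                raise ValueError(
                    f"organ {name!r} does not fit the grid (extent {extent} mm)"
                )


def _ellipsoid_mask(shape, spacing, center, radii) -> np.ndarray:
    zz, yy, xx = voxel_centers(shape, spacing)
    c, r = np.asarray(center, float), np.asarray(radii, float)
    return (
        ((zz - c[0]) / r[0]) ** 2
        + ((yy - c[1]) / r[1]) ** 2
        + ((xx - c[2]) / r[2]) ** 2
    ) <= 1.0


def _integer_shift(arr: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    """Translate by integer voxels with zero fill (no wrap-around)."""
    out = arr
    for ax, s in enumerate(shift_vox):
        s = int(s)
        if s == 0:
            continue
        shifted = np.zeros_like(out)
        src = [slice(None)] * out.ndim
        dst = [slice(None)] * out.ndim
        if s > 0:
            dst[ax], src[ax] = slice(s, None), slice(None, -s)
        else:
            dst[ax], src[ax] = slice(None, s), slice(-s, None)
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return out


def make_body_phantom(
    spec: BodyPhantomSpec,
) -> tuple[VolumeImage, LabelMask, pd.DataFrame]:
    """Render the body phantom.

    Returns the luminescence volume, a label mask (organs labeled 1..n,
    remaining body tissue labeled n+1 as ``"body"``), and a ground-truth
    table of the per-organ emitted totals.  Before blurring, the in-organ
    integrated signal equals the requested total exactly; the centroid
    shift is applied as an integer-voxel translation and the blur as a
    Gaussian filter, both signal-conserving up to grid-boundary loss.
    """
    shape, spacing = spec.grid_shape, spec.voxel_spacing
    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    organ_masks: dict[str, np.ndarray] = {}
    for i, (name, center, radii) in enumerate(spec.organs, start=1):
        m = _ellipsoid_mask(shape, spacing, center, radii)
        if not m.any():
            raise ValueError(f"grid too small: organ {name!r} rasterizes to 0 voxels")
        for other, om in organ_masks.items():
            if np.any(m & om):
                raise ValueError(f"organs overlap: {other!r} and {name!r}")
        organ_masks[name] = m
        labels[m] = i
        names[i] = name

    body = _ellipsoid_mask(shape, spacing, *spec.body)
    body_label = len(spec.organs) + 1
    labels[body & (labels == 0)] = body_label
    names[body_label] = BODY_LABEL_NAME

    vol = np.zeros(shape, dtype=np.float64)
    rows = []
    sigma_vox = np.array(spec.blur_sigma_mm) / np.array(spacing)
    for organ_name, total, shift_mm in spec.sources:
        m = organ_masks[organ_name]
        src = np.zeros(shape, dtype=np.float64)
        src[m] = total / m.sum()  # uniform source, exact total
        shift_vox = np.rint(np.asarray(shift_mm, float) / np.asarray(spacing))
        src = _integer_shift(src, shift_vox)
        if spec.blur_sigma_mm > 0:
            src = ndimage.gaussian_filter(src, sigma=sigma_vox, mode="constant")
        vol += src
        rows.append({"organ": organ_name, "total_signal": float(total)})

    truth = pd.DataFrame(rows)
    return (
        VolumeImage(vol, spacing),
        LabelMask(labels, spacing, names),
        truth,
    )


# --------------------------------------------------------------------------
# tumor (light-sheet) phantom
# --------------------------------------------------------------------------

@dataclass
class VesselParams:
    """Branching random-walk vessel tree rasterized as tubes (µm units)."""

    n_trunks: int = 4
    branch_prob: float = 0.04
    radius_um: float = 15.0
    step_um: float = 10.0
    max_steps_per_branch: int = 150
    max_centerline_points: int = 800

    def __post_init__(self) -> None:
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.radius_um <= 0 or self.step_um <= 0:
            raise ValueError("vessel radius and step must be positive")


@dataclass
class CellParams:
    """T-cell point process inside the tumor (µm units).

    Cell density is proportional to
    ``(1 - w) * exp(-d_surface / lambda_s) + w * exp(-d_vessel / lambda_v)``
    with ``w = vessel_attraction_weight``.
    """

    n_cells: int = 2000
    surface_decay_length_um: float = 50.0
    vessel_attraction_weight: float = 0.0
    min_cell_diameter_um: float = 8.0
    vessel_decay_length_um: float = 25.0
    diameter_um_range: tuple[float, float] = (10.0, 14.0)
    amplitude: float = 100.0
    min_separation_um: float = 0.0  # >0 thins the process to separated cells

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 <= self.vessel_attraction_weight <= 1:
            raise ValueError("vessel_attraction_weight must lie in [0, 1]")
        if self.surface_decay_length_um <= 0 or self.vessel_decay_length_um <= 0:
            raise ValueError("decay lengths must be positive")
        lo, hi = self.diameter_um_range
        if not 0 < lo <= hi:
            raise ValueError("diameter_um_range must satisfy 0 < lo <= hi")


@dataclass
class TumorPhantomSpec:
    """Cleared-tumor LSFM phantom (µm units).

    The grid is sized from the tumor semi-axes plus ``margin_um`` unless
    ``grid_shape`` is given explicitly.
    """

    tumor_radii_um: tuple[float, float, float] = (240.0, 280.0, 280.0)
    voxel_spacing_um: tuple[float, float, float] = (2.0, 2.0, 2.0)
    grid_shape: tuple[int, int, int] | None = None
    margin_um: float = 30.0
    vessel_params: VesselParams = field(default_factory=VesselParams)
    cell_params: CellParams = field(default_factory=CellParams)
    background_level: float = 20.0
    vessel_amplitude: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.vessel_params, dict):
            self.vessel_params = VesselParams(**self.vessel_params)
        if isinstance(self.cell_params, dict):
            self.cell_params = CellParams(**self.cell_params)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cell_params.min_cell_diameter_um < min(self.voxel_spacing_um):
            raise ValueError("min_cell_diameter_um must be >= the finest voxel size")
        if self.grid_shape is None:
            self.grid_shape = tuple(
                int(math.ceil(2 * (r + self.margin_um) / s))
                for r, s in zip(self.tumor_radii_um, self.voxel_spacing_um)
            )


def _grow_vessel_tree(spec: TumorPhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Centerline points (physical µm) of a branching random walk."""
    vp = spec.vessel_params
    extent = np.array(spec.grid_shape) * np.array(spec.voxel_spacing_um)
    center = extent / 2.0
    radii = np.asarray(spec.tumor_radii_um, float)

    def inside(p):
        return np.sum(((p - center) / radii) ** 2) <= 1.0

    points: list[np.ndarray] = []
    # walker: (position, direction); trunks enter from the surface inward
    stack = []
    for _ in range(vp.n_trunks):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        start = center + radii * u
        d = center - start
        d /= np.linalg.norm(d)
        stack.append((start, d))
    max_points = vp.max_centerline_points
    while stack and len(points) < max_points:
        pos, d = stack.pop()
        for _ in range(vp.max_steps_per_branch):
            if len(points) >= max_points:
                break
            pos = pos + vp.step_um * d
            if not inside(pos):
                break
            points.append(pos.copy())
            d = d + 0.25 * rng.normal(size=3)
            d /= np.linalg.norm(d)
            if rng.random() < vp.branch_prob:
                db = d + 0.8 * rng.normal(size=3)
                db /= np.linalg.norm(db)
                stack.append((pos.copy(), db))
    return np.asarray(points).reshape(-1, 3)


def make_tumor_phantom(
    spec: TumorPhantomSpec,
) -> tuple[dict[str, VolumeImage], LabelMask, LabelMask, SpotSet]:
    """Render the tumor phantom.

    Returns channels (``"background"``, ``"lectin"``, ``"cd3"``), the tumor
    mask, the vessel mask, and the ground-truth cells as a
    :class:`~carspat3d.types.SpotSet` with exact physical centers.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    spacing = spec.voxel_spacing_um
    extent = np.array(shape) * np.array(spacing)
    center = extent / 2.0

    tumor = _ellipsoid_mask(shape, spacing, center, spec.tumor_radii_um)
    if spec.cell_params.n_cells > 0 and not tumor.any():
        raise ValueError("tumor volume is 0 but n_cells > 0")

    # vessels: centerline walk -> tube of given radius via an EDT query
    pts = _grow_vessel_tree(spec, rng)
    vessel = np.zeros(shape, dtype=bool)
    if len(pts):
        idx = np.floor(pts / np.array(spacing)).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        centerline = np.zeros(shape, dtype=bool)
        centerline[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        d_cl = ndimage.distance_transform_edt(~centerline, sampling=spacing)
        vessel = (d_cl <= spec.vessel_params.radius_um) & tumor

    # cell sampling weights on tumor voxels
    cp = spec.cell_params
    n = cp.n_cells
    if n > 0:
        d_surf = ndimage.distance_transform_edt(tumor, sampling=spacing)
        w_surf = np.exp(-d_surf[tumor] / cp.surface_decay_length_um)
        w = (1.0 - cp.vessel_attraction_weight) * w_surf
        if cp.vessel_attraction_weight > 0:
            if not vessel.any():
                raise ValueError("vessel attraction requested but vessel tree is empty")
            d_ves = ndimage.distance_transform_edt(~vessel, sampling=spacing)
            w = w + cp.vessel_attraction_weight * np.exp(
                -d_ves[tumor] / cp.vessel_decay_length_um
            )
        p = w / w.sum()
        tumor_idx = np.argwhere(tumor)

        def _draw(k):
            choice = rng.choice(len(tumor_idx), size=k, replace=True, p=p)
            vox = tumor_idx[choice] + rng.uniform(0.0, 1.0, size=(k, 3))
            return vox * np.array(spacing)

        if cp.min_separation_um > 0:
            from scipy.spatial import cKDTree

            kept: list[np.ndarray] = []
            for _ in range(50):
                if len(kept) >= n:
                    break
                cand = _draw(2 * (n - len(kept)))
                for c in cand:
                    if len(kept) >= n:
                        break
                    if not kept or cKDTree(np.array(kept)).query(c)[0] >= cp.min_separation_um:
                        kept.append(c)
            if len(kept) < n:
                raise RuntimeError(
                    f"placed only {len(kept)}/{n} cells at separation "
                    f">= {cp.min_separation_um} µm"
                )
            centers_um = np.array(kept)
        else:
            centers_um = _draw(n)
        diameters = rng.uniform(*cp.diameter_um_range, size=n)
    else:
        centers_um = np.empty((0, 3))
        diameters = np.empty(0)

    # render channels
    cd3 = np.zeros(shape, dtype=np.float64)
    for c_um, d_um in zip(centers_um, diameters):
        _add_gaussian_blob(cd3, c_um, d_um, cp.amplitude, spacing)
    lectin = np.where(vessel, spec.vessel_amplitude, 0.0)
    background = np.where(tumor, spec.background_level, 0.0)

    channels = {}
    for name, arr in (("background", background), ("lectin", lectin), ("cd3", cd3)):
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, size=shape)
        channels[name] = VolumeImage(
            np.clip(arr, 0.0, None).astype(np.float32), spacing
        )

    true_cells = SpotSet(
        centers_um, diameters / 2.0, np.full(len(centers_um), cp.amplitude),
        provenance="ground_truth",
    )
    tumor_mask = LabelMask(tumor.astype(np.int32), spacing, {1: "tumor"})
    vessel_mask = LabelMask(vessel.astype(np.int32), spacing, {1: "vessel"})
    return channels, tumor_mask, vessel_mask, true_cells


# For a Gaussian blob detected by a scale-normalized Laplacian of Gaussian,
# the response peaks at sigma = r / sqrt(3) in 3D; we render at that sigma so
# a blob of diameter d is recovered at radius d/2.
def blob_sigma_um(diameter_um: float) -> float:
    return (diameter_um / 2.0) / math.sqrt(3.0)


def _add_gaussian_blob(vol, center_um, diameter_um, amplitude, spacing) -> None:
    sigma_um = blob_sigma_um(diameter_um)
    spacing = np.asarray(spacing, float)
    c_vox = np.asarray(center_um, float) / spacing - 0.5
    half = np.ceil(4.0 * sigma_um / spacing).astype(int)
    lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
    hi = np.minimum(np.floor(c_vox).astype(int) + half + 1, vol.shape)
    if np.any(lo >= hi):
        return
    ax = [
        ((np.arange(lo[k], hi[k]) + 0.5) * spacing[k] - center_um[k]) ** 2
        for k in range(3)
    ]
    zz, yy, xx = np.ix_(*ax)
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(
        -(zz + yy + xx) / (2.0 * sigma_um**2)
    )


# --------------------------------------------------------------------------
# cyclic-IF phantom
# --------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """One cell population: marker intensities are log-normal per marker,
    parameterized as (mean, sd) of log2 intensity."""

    name: str
    fraction: float
    markers: dict[str, tuple[float, float]]


@dataclass
class CycIFPhantomSpec:
    """2D multiplexed-IF phantom (pixel units)."""

    image_shape: tuple[int, int] = (1024, 1024)
    n_cells: int = 500
    nucleus_diameter_px_range: tuple[float, float] = (18.0, 28.0)
    donut_width_px: int = 11
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec(
                "tumor", 0.6,
                {"CD3": (1.0, 0.5), "CD4": (1.0, 0.5), "CD8": (1.0, 0.5),
                 "EGFR": (7.0, 0.5), "CD38": (2.0, 0.5)},
            ),
            PopulationSpec(
                "tcell", 0.4,
                {"CD3": (6.0, 0.5), "CD4": (5.0, 0.5), "CD8": (2.0, 0.5),
                 "EGFR": (1.0, 0.5), "CD38": (4.0, 0.5)},
            ),
        ]
    )
    background_level: float = 0.0
    dapi_level: float = 100.0
    max_place_attempts: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.populations[0], dict):
            self.populations = [PopulationSpec(**p) for p in self.populations]
        fracs = [p.fraction for p in self.populations]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"population fractions must sum to 1, got {sum(fracs)}")
        lo, hi = self.nucleus_diameter_px_range
        if not 0 < lo <= hi:
            raise ValueError("nucleus diameter range must satisfy 0 < lo <= hi")
        if self.donut_width_px < 1:
            raise ValueError("donut_width_px must be >= 1")
        marker_sets = {frozenset(p.markers) for p in self.populations}
        if len(marker_sets) != 1:
            raise ValueError("all populations must define the same marker set")

    @property
    def marker_names(self) -> list[str]:
        return sorted(self.populations[0].markers)


def _population_counts(fracs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment so counts hit fractions exactly."""
    raw = fracs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def make_cycif_phantom(
    spec: CycIFPhantomSpec,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render the 2D phantom.

    Returns channels (``"DAPI"`` plus one per marker) and the ground-truth
    cell table with centroids, population labels, and per-marker true
    intensities (raw and as ``log2(x + 1)``).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    lo_d, hi_d = spec.nucleus_diameter_px_range

    # dart-throwing placement of non-overlapping nuclei
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    margin = hi_d / 2 + spec.donut_width_px + 2
    for i in range(spec.n_cells):
        placed = False
        for _ in range(spec.max_place_attempts):
            r = rng.uniform(lo_d, hi_d) / 2.0
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ok = all(
                (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2.0) ** 2
                for (py, px), pr in zip(centers, radii)
            )
            if ok:
                centers.append((cy, cx))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping nuclei "
                f"(placed {len(centers)}); reduce n_cells or enlarge the image"
            )

    n = len(centers)
    fracs = np.array([p.fraction for p in spec.populations])
    counts = _population_counts(fracs, n)
    pop_idx = np.repeat(np.arange(len(spec.populations)), counts)
    rng.shuffle(pop_idx)

    markers = spec.marker_names
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # paint non-overlapping nucleus labels, then expand by the donut width
    # clipped against neighbors, so each pixel belongs to at most one cell:
    # marker channels are then exactly one cell's intensity plus background
    nuc_labels = np.zeros((h, w), dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuc_labels[d2 <= r**2] = i
    from skimage.segmentation import expand_labels

    cell_labels = expand_labels(nuc_labels, distance=spec.donut_width_px)
    dapi = np.where(nuc_labels > 0, float(spec.dapi_level), 0.0)

    rows = []
    luts = {m: np.full(n + 1, float(spec.background_level)) for m in markers}
    for i, ((cy, cx), r, pi) in enumerate(zip(centers, radii, pop_idx)):
        pop = spec.populations[pi]
        row = {
            "cell_id": i,
            "y_px": cy,
            "x_px": cx,
            "nucleus_radius_px": r,
            "population": pop.name,
        }
        for m in markers:
            mean, sd = pop.markers[m]
            intensity = float(2.0 ** rng.normal(mean, sd))
            luts[m][i + 1] = intensity + spec.background_level
            row[f"{m}_true_intensity"] = intensity
            row[f"{m}_true_log2"] = math.log2(intensity + 1.0)
        rows.append(row)

    out = {"DAPI": dapi.astype(np.float32)}
    out.update({m: luts[m][cell_labels].astype(np.float32) for m in markers})
    return out, pd.DataFrame(rows)
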