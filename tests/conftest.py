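"""Shared fixtures: phantoms are generated once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from carspat3d import cycif, lsfm, synthetic


def match_spots(detected, truth, tol_um: float = 8.0):
    """Greedy one-to-one matching of detected spots to ground-truth cells.

    Returns (precision, recall, matched distance list).
    """
    if len(detected) == 0:
        return 1.0, 0.0, []
    tree = cKDTree(truth.coords)
    d, idx = tree.query(detected.coords)
    used: set[int] = set()
    locs = []
    for k in np.argsort(d):
        if d[k] <= tol_um and idx[k] not in used:
            used.add(int(idx[k]))
            locs.append(float(d[k]))
    tp = len(locs)
    return tp / len(detected), tp / len(truth), locs


def random_blob_mask(rng, max_side=20):
    """A random non-empty, non-full blob mask on a small grid."""
    shape = tuple(rng.integers(8, max_side + 1, size=3))
    field = rng.normal(size=shape)
    from scipy import ndimage

    field = ndimage.gaussian_filter(field, 2.0)
    mask = field > np.quantile(field, 0.7)
    if not mask.any() or mask.all():
        mask = np.zeros(shape, bool)
        mask[tuple(s // 2 for s in shape)] = True
    return mask


def brute_force_surface_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive nearest-background-voxel distance for interior voxels."""
    spacing = np.asarray(spacing, float)
    inside = np.argwhere(mask) * spacing
    outside = np.argwhere(~mask) * spacing
    out = np.full(mask.shape, np.nan)
    vals = np.empty(len(inside))
    for i in range(0, len(inside), 512):
        block = inside[i : i + 512]
        d2 = ((block[:, None, :] - outside[None, :, :]) ** 2).sum(-1)
        vals[i : i + 512] = np.sqrt(d2.min(axis=1))
    vals = np.maximum(vals - 0.5 * spacing.min(), 0.0)
    out[mask] = vals
    return out


def brute_force_dilation(mask: np.ndarray, radius: float) -> np.ndarray:
    """All voxels within index-space Euclidean distance ``radius`` of the set."""
    region = np.argwhere(mask).astype(float)
    allv = np.indices(mask.shape).reshape(3, -1).T.astype(float)
    out = np.zeros(mask.size, bool)
    for i in range(0, len(allv), 2048):
        block = allv[i : i + 2048]
        d2 = ((block[:, None, :] - region[None, :, :]) ** 2).sum(-1)
        out[i : i + 2048] = d2.min(axis=1) <= radius**2 + 1e-9
    return out.reshape(mask.shape)


# ----------------------------------------------------------------- phantoms

@pytest.fixture(scope="session")
def cycif_phantom():
    spec = synthetic.CycIFPhantomSpec(seed=0)
    channels, truth = synthetic.make_cycif_phantom(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def cycif_cells(cycif_phantom):
    """Segmented + quantified cell table with truth assignment."""
    spec, channels, truth = cycif_phantom
    seg = cycif.segment_cells(channels["DAPI"])
    cells = cycif.quantify_markers(
        seg, {m: channels[m] for m in spec.marker_names}
    )
    tree = cKDTree(truth[["y_px", "x_px"]].to_numpy())
    dist, idx = tree.query(cells[["y_px", "x_px"]].to_numpy())
    cells = cells.copy()
    cells["match_dist_px"] = dist
    cells["true_population"] = truth["population"].to_numpy()[idx]
    cells["true_index"] = idx
    return spec, cells, truth


@pytest.fixture(scope="session")
def separated_tumor():
    """200 well-separated bright cells, uniform in the tumor, SNR 10."""
    spec = synthetic.TumorPhantomSpec(
        seed=3,
        tumor_radii_um=(160.0, 180.0, 180.0),
        cell_params=synthetic.CellParams(
            n_cells=200, min_separation_um=25.0, surface_decay_length_um=1e6
        ),
    )
    channels, tumor_mask, vessel_mask, cells = synthetic.make_tumor_phantom(spec)
    spots = lsfm.detect_spots(channels["cd3"], tumor_mask)
    return spec, channels, tumor_mask, vessel_mask, cells, spots


@pytest.fixture(scope="session")
def decay_tumor():
    """Default phantom: 2000 cells, surface decay length 50 µm, SNR 10."""
    spec = synthetic.TumorPhantomSpec(seed=1)
    channels, tumor_mask, vessel_mask, cells = synthetic.make_tumor_phantom(spec)
    spots = lsfm.detect_spots(channels["cd3"], tumor_mask)
    return spec, channels, tumor_mask, vessel_mask, cells, spots
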