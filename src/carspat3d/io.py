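"""Reading and writing volumes, masks and tables.

Volumes go to multi-page TIFF (ImageJ-style metadata carrying the voxel
spacing) or NIfTI (spacing in the affine); tables to CSV with a fixed
float format so identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import LabelMask, VolumeImage

CSV_FLOAT_FORMAT = "%.10g"


def save_volume_tiff(path, vol: VolumeImage | LabelMask) -> None:
    """Write a (z, y, x) volume as ImageJ TIFF with spacing metadata.

    ImageJ metadata stores z-spacing as ``spacing`` and the in-plane
    spacing as x/y resolution (pixels per unit).
    """
    sz, sy, sx = vol.spacing
    data = vol.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    elif np.issubdtype(data.dtype, np.integer):
        if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
            raise ValueError("integer volume out of uint16 range for ImageJ TIFF")
        data = data.astype(np.uint16)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def load_volume_tiff(path) -> VolumeImage:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        sz = float(meta.get("spacing", 1.0))
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")

        def _res_to_spacing(tag):
            if tag is None:
                return 1.0
            num, den = tag.value
            return den / num if num else 1.0

        sx = _res_to_spacing(xres)
        sy = _res_to_spacing(yres)
    if data.ndim == 2:
        data = data[None]
    return VolumeImage(data, (sz, sy, sx))


def save_volume_nifti(path, vol: VolumeImage | LabelMask) -> None:
    # NIfTI is (x, y, z); transpose and put spacing on the affine diagonal.
    sz, sy, sx = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.data).T, affine)
    nib.save(img, str(path))


def load_volume_nifti(path) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).T
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(data, (float(zooms[2]), float(zooms[1]), float(zooms[0])))


def load_volume(path) -> VolumeImage:
    """Dispatch on suffix: .tif/.tiff or .nii/.nii.gz."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        return load_volume_tiff(p)
    if p.suffix.lower() == ".nii" or p.name.lower().endswith(".nii.gz"):
        return load_volume_nifti(p)
    raise ValueError(f"unrecognized volume format: {p.name}")


def load_label_mask(path, names: dict[int, str] | None = None) -> LabelMask:
    vol = load_volume(path)
    return LabelMask(np.rint(vol.data).astype(np.int32), vol.spacing, names or {})


def save_table(path, df: pd.DataFrame) -> None:
    """Deterministic CSV: fixed float format, no index."""
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def save_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
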