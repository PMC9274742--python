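"""Core in-memory containers shared by every pipeline stage.

All volumes live on a regular anisotropic grid in (z, y, x) axis order.
The physical coordinate of voxel index ``i`` along an axis is
``(i + 0.5) * spacing`` — voxel *centers*, 0-based — and every distance in
this package is Euclidean in physical units (mm for whole-body data, µm
for microscopy data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VolumeImage", "LabelMask", "SpotSet", "voxel_centers"]


def _check_grid(data: np.ndarray, spacing) -> tuple[float, float, float]:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing!r}")
    return spacing


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with per-axis voxel spacing.

    Parameters
    ----------
    data :
        Intensity array, axis order (z, y, x).
    spacing :
        Physical size of one voxel per axis, same order. Units are the
        caller's (mm for whole-body volumes, µm for microscopy volumes).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = _check_grid(self.data, self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeImage | LabelMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def require_same_grid(self, other: "VolumeImage | LabelMask") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def world_to_index(self, coords_phys: np.ndarray) -> np.ndarray:
        """Map physical (z,y,x) coordinates to fractional voxel indices."""
        return np.asarray(coords_phys, dtype=float) / np.asarray(self.spacing) - 0.5

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return (np.asarray(idx, dtype=float) + 0.5) * np.asarray(self.spacing)


@dataclass
class LabelMask:
    """An integer label volume naming organs / tumor / vessels on a grid.

    ``names`` maps each positive label to a region name; 0 is background.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer) and self.data.dtype != bool:
            raise TypeError(f"label data must be integer or bool, got {self.data.dtype}")
        if self.data.dtype == bool:
            self.data = self.data.astype(np.int32)
        self.spacing = _check_grid(self.data, self.spacing)
        self.names = {int(k): str(v) for k, v in self.names.items()}

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    same_grid = VolumeImage.same_grid
    require_same_grid = VolumeImage.require_same_grid
    world_to_index = VolumeImage.world_to_index
    index_to_world = VolumeImage.index_to_world

    @property
    def labels(self) -> np.ndarray:
        labs = np.unique(self.data)
        return labs[labs > 0]

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(f"unknown region {name!r}; known: {sorted(self.names.values())}")

    def region(self, name_or_label: "str | int") -> np.ndarray:
        """Boolean mask of one labeled region."""
        lab = (
            self.label_of(name_or_label)
            if isinstance(name_or_label, str)
            else int(name_or_label)
        )
        return self.data == lab

    def binary(self) -> np.ndarray:
        return self.data > 0


@dataclass
class SpotSet:
    """Point-like detected or ground-truth cells in physical coordinates.

    ``coords`` is (n, 3) in µm, (z, y, x) order; ``radius_um`` and
    ``intensity`` are per-spot.
    """

    coords: np.ndarray
    radius_um: np.ndarray
    intensity: np.ndarray
    provenance: str = "detected"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.radius_um = np.broadcast_to(
            np.asarray(self.radius_um, dtype=float), (n,)
        ).copy()
        self.intensity = np.broadcast_to(
            np.asarray(self.intensity, dtype=float), (n,)
        ).copy()
        if self.provenance not in ("detected", "ground_truth"):
            raise ValueError(f"bad provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def empty(cls, provenance: str = "detected") -> "SpotSet":
        return cls(np.empty((0, 3)), np.empty(0), np.empty(0), provenance)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_um": self.coords[:, 0],
                "y_um": self.coords[:, 1],
                "x_um": self.coords[:, 2],
                "radius_um": self.radius_um,
                "intensity": self.intensity,
                "provenance": self.provenance,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpotSet":
        prov = df["provenance"].iloc[0] if len(df) else "detected"
        return cls(
            df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float),
            df["radius_um"].to_numpy(dtype=float),
            df["intensity"].to_numpy(dtype=float),
            str(prov),
        )


def voxel_centers(shape, spacing) -> tuple[np.ndarray, ...]:
    """Physical center coordinate arrays (open meshgrid) for a grid."""
    spacing = tuple(float(s) for s in spacing)
    axes = [
        (np.arange(n, dtype=float) + 0.5) * s for n, s in zip(shape, spacing)
    ]
    return np.ix_(*axes)
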