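"""3D scalar volumes and tissue label maps with world-coordinate geometry.

A :class:`Volume` carries a 3D array plus the affine-free geometry used
throughout the package: per-axis spacing in mm, a world origin, and an
anatomical orientation label.  World coordinates follow the node-centred
convention ``world_mm = origin + index * spacing`` with 0-based indices.
NIfTI round-trips go through nibabel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib

__all__ = ["Volume", "LabelMap", "Label", "ORIENTATIONS"]

#: valid 3-letter orientation codes (one of the 48 axis permutations/flips),
#: e.g. "RAS": +x right, +y anterior, +z superior
_AX = "RLAPSI"
_PLANE = {"R": "RL", "L": "RL", "A": "AP", "P": "AP", "S": "SI", "I": "SI"}
ORIENTATIONS = frozenset(
    a + b + c
    for a in _AX for b in _AX for c in _AX
    if len({_PLANE[a], _PLANE[b], _PLANE[c]}) == 3
)


class Label(enum.IntEnum):
    """Tissue classes of a :class:`LabelMap`."""

    BACKGROUND = 0
    ADIPOSE = 1
    FIBROGLANDULAR = 2
    LESION = 3
    CHEST_WALL = 4


@dataclass
class Volume:
    """3D scalar image with spacing (mm), origin (mm) and orientation."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("Volume data must be 3D (or 3D + channel)")
        if self.spacing.shape != (3,) or not (self.spacing > 0).all():
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"invalid orientation code {self.orientation!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    def world_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world-mm points."""
        return (np.asarray(pts_mm, float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.spacing

    def same_grid(self, other: "Volume") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin)
                and self.orientation == other.orientation)

    def copy_with(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)

    # -- NIfTI I/O ---------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, np.float32), self.affine())

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, orientation: str = "RAS") -> "Volume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.linalg.norm(aff[:3, :3], axis=0)
        return cls(data=np.asarray(img.dataobj), spacing=spacing,
                   origin=aff[:3, 3].copy(), orientation=orientation)


@dataclass
class LabelMap(Volume):
    """Integer tissue label volume aligned to a companion :class:`Volume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be integer")
        bad = set(np.unique(self.data)) - {int(v) for v in Label}
        if bad:
            raise ValueError(f"unknown label values {sorted(bad)}")

    def mask(self, *labels: Label) -> np.ndarray:
        return np.isin(self.data, [int(l) for l in labels])

    def breast_mask(self) -> np.ndarray:
        """Adipose + fibro-glandular + lesion."""
        return self.mask(Label.ADIPOSE, Label.FIBROGLANDULAR, Label.LESION)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, np.int16), self.affine())

    @classmethod
    def load(cls, path, orientation: str = "RAS") -> "LabelMap":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.linalg.norm(aff[:3, :3], axis=0)
        return cls(data=np.asarray(img.dataobj).astype(np.int64), spacing=spacing,
                   origin=aff[:3, 3].copy(), orientation=orientation)
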