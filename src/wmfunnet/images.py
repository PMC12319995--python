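"""Lightweight containers for volumetric data.

All volumetric inputs are assumed co-registered on a common grid; the
containers carry the voxel-to-world affine and the repetition time so that
downstream stages (filtering, smoothing, symmetry) can work in physical
units.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["BoldImage", "TissueProbMaps", "save_nifti", "load_bold", "load_volume"]


def save_nifti(img: nib.Nifti1Image, path: str | Path) -> Path:
    """Write a NIfTI-1 image, gzipping reproducibly for ``.gz`` paths.

    The gzip stream is written with ``mtime=0`` so that identical images
    produce byte-identical files regardless of wall-clock time.
    """
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(img.to_bytes())
    else:
        nib.save(img, str(path))
    return path


@dataclass
class BoldImage:
    """A 4D BOLD series: ``data`` is (x, y, z, t), ``tr`` in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("BOLD image must contain at least one volume")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along each spatial axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def from_file(cls, path: str | Path, tr: float | None = None) -> "BoldImage":
        img = nib.load(str(path))
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 else 0.0
            if tr <= 0:
                raise ValueError(f"{path}: TR not recorded in header; pass tr explicitly")
        return cls(np.asanyarray(img.dataobj, dtype=np.float64), img.affine, float(tr))

    def to_image(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = self.tr
        img.header.set_zooms(zooms)
        return img

    def save(self, path: str | Path) -> Path:
        return save_nifti(self.to_image(), path)

    def with_data(self, data: np.ndarray) -> "BoldImage":
        return BoldImage(data, self.affine.copy(), self.tr)


@dataclass
class TissueProbMaps:
    """GM/WM/CSF probability maps on the BOLD grid, values in [0, 1]."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        for name in ("gm", "wm", "csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"{name} map must be 3D")
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            setattr(self, name, arr)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm.shape

    @classmethod
    def from_files(cls, gm: str | Path, wm: str | Path, csf: str | Path) -> "TissueProbMaps":
        imgs = [nib.load(str(p)) for p in (gm, wm, csf)]
        return cls(*(np.asanyarray(i.dataobj, dtype=np.float64) for i in imgs), affine=imgs[0].affine)


def load_bold(path: str | Path, tr: float | None = None) -> BoldImage:
    return BoldImage.from_file(path, tr=tr)


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D volume, returning ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine
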