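"""3D scalar image volumes with voxel spacing and modality metadata.

Volumes are indexed ``(row, col, slice)``; world coordinates in mm are
``index * spacing`` per axis.  T1W/T2W pairs are assumed co-registered
(acquired in the same exam), so no resampling or registration happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "load_volume", "save_volume", "normalize"]


@dataclass
class ImageVolume:
    """A 3D scalar image plus its voxel spacing and modality tag.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, slices)
        Scalar voxel intensities.
    spacing_mm : tuple of float
        Voxel size per axis (row, col, slice) in millimetres.
    modality : str
        Free-form tag, conventionally ``"t1w"`` or ``"t2w"``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume must be 3D, got {self.data.ndim}D shape {self.data.shape}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def slice(self, k: int) -> np.ndarray:
        """In-plane 2D array for slice index ``k``."""
        return self.data[:, :, k]

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


def load_volume(path: str | Path, modality: str = "unknown") -> ImageVolume:
    """Load a 3D NIfTI volume, failing rather than guessing metadata.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the image is not 3D or carries no positive voxel spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing {zooms!r}")
    return ImageVolume(data=data, spacing_mm=tuple(float(z) for z in zooms), modality=modality)


def save_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI, encoding spacing in the header/affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


def normalize(volume: ImageVolume) -> ImageVolume:
    """Standardize intensities to zero mean, unit variance over the volume.

    Raises
    ------
    ValueError
        If the volume is constant (variance zero).
    """
    data = np.asarray(volume.data, dtype=np.float64)
    sd = data.std()
    if sd == 0:
        raise ValueError("cannot normalize a constant volume")
    return volume.with_data((data - data.mean()) / sd)
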