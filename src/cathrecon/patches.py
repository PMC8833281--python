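"""2D patch extraction and augmentation for segmentation training/inference.

Training patches are cut per slice, either at requested centers (catheter
centroids plus random background) or by stride tiling.  Windows near an edge
are shifted inward so every patch is a genuine sub-image — never zero-padded.
Augmentation applies one affine (translation/scale/rotation in the axial
plane) identically to pixels and label, re-binarizing the label afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, normalize  # noqa: F401  (normalize is part of this surface)

__all__ = [
    "Patch",
    "extract_patches",
    "tile_offsets",
    "augment",
    "sample_training_patches",
    "save_patches",
    "load_patches",
    "normalize",
]


@dataclass
class Patch:
    """A square image window plus its aligned binary label.

    ``source`` records (volume id, slice index, row offset, col offset) of
    the window's top-left corner in the parent slice.
    """

    pixels: np.ndarray
    label: np.ndarray
    source: tuple[str, int, int, int]
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.label = np.asarray(self.label)
        if self.pixels.shape != self.label.shape:
            raise ValueError(
                f"pixels {self.pixels.shape} and label {self.label.shape} differ"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("patch pixels must be finite")
        u = np.unique(self.label)
        if not np.all(np.isin(u, (0, 1))):
            raise ValueError("label must be strictly binary")
        self.label = self.label.astype(np.float32)


def _clamp_offset(start: int, patch: int, dim: int) -> int:
    return int(min(max(start, 0), dim - patch))


def tile_offsets(dim: int, patch: int, stride: int) -> list[int]:
    """Window start offsets covering [0, dim) with the last one shifted inward."""
    if patch > dim:
        raise ValueError(f"patch size {patch} exceeds dimension {dim}")
    offs = list(range(0, dim - patch + 1, stride))
    if offs[-1] != dim - patch:
        offs.append(dim - patch)
    return offs


def extract_patches(
    volume: ImageVolume,
    labels: np.ndarray,
    patch_size: int,
    centers: list[tuple[int, float, float]] | None = None,
    stride: int | None = None,
    volume_id: str = "vol",
) -> list[Patch]:
    """Cut aligned pixel/label windows from a volume.

    Provide either ``centers`` — (slice, row, col) triples, each window
    clamped so it fits inside the slice — or ``stride`` for regular tiling
    of every slice.

    Raises
    ------
    ValueError
        If ``patch_size`` exceeds an in-plane dimension, or neither/both of
        ``centers`` and ``stride`` are given.
    """
    rows, cols, n_slices = volume.shape
    if patch_size > rows or patch_size > cols:
        raise ValueError(
            f"patch size {patch_size} larger than slice {rows}x{cols}"
        )
    if (centers is None) == (stride is None):
        raise ValueError("provide exactly one of centers= or stride=")
    labels = np.asarray(labels)
    if labels.shape != volume.shape:
        raise ValueError(f"label shape {labels.shape} != volume shape {volume.shape}")

    half = patch_size // 2
    windows: list[tuple[int, int, int]] = []
    if centers is not None:
        for s, r, c in centers:
            r0 = _clamp_offset(int(round(r)) - half, patch_size, rows)
            c0 = _clamp_offset(int(round(c)) - half, patch_size, cols)
            windows.append((int(s), r0, c0))
    else:
        for s in range(n_slices):
            for r0 in tile_offsets(rows, patch_size, stride):
                for c0 in tile_offsets(cols, patch_size, stride):
                    windows.append((s, r0, c0))

    out = []
    for s, r0, c0 in windows:
        px = volume.data[r0 : r0 + patch_size, c0 : c0 + patch_size, s]
        lb = labels[r0 : r0 + patch_size, c0 : c0 + patch_size, s]
        out.append(
            Patch(
                pixels=px,
                label=(np.asarray(lb) > 0).astype(np.float32),
                source=(volume_id, s, r0, c0),
                modality=volume.modality,
            )
        )
    return out


#: Default augmentation ranges: translation +-8 px, scale 0.9-1.1, rotation +-15 deg.
AUGMENT_RANGES = {"translation": 8.0, "scale": (0.9, 1.1), "rotation_deg": 15.0}


def augment(
    patch: Patch,
    translation: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
    rotation_deg: float = 0.0,
    ranges: dict | None = None,
) -> Patch:
    """Apply one in-plane affine to pixels and label alike.

    Parameters outside the configured ranges are clamped, never rejected.
    The label is linearly interpolated and re-binarized at 0.5.
    """
    rng_cfg = dict(AUGMENT_RANGES, **(ranges or {}))
    tmax = float(rng_cfg["translation"])
    slo, shi = rng_cfg["scale"]
    rmax = float(rng_cfg["rotation_deg"])
    dr = float(np.clip(translation[0], -tmax, tmax))
    dc = float(np.clip(translation[1], -tmax, tmax))
    s = float(np.clip(scale, slo, shi))
    theta = np.deg2rad(float(np.clip(rotation_deg, -rmax, rmax)))

    if dr == 0.0 and dc == 0.0 and s == 1.0 and theta == 0.0:
        return Patch(patch.pixels, patch.label, patch.source, patch.modality)

    n = patch.pixels.shape[0]
    center = (n - 1) / 2.0
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    # output coord o samples input at M @ o + offset; forward map is
    # p -> s*R*(p - c) + c + t, so M = (1/s) * R^-1
    m = rot.T / s
    offset = np.array([center, center]) - m @ (np.array([center, center]) + np.array([dr, dc]))
    px = ndimage.affine_transform(
        patch.pixels.astype(np.float64), m, offset=offset, order=1, mode="nearest"
    )
    lb = ndimage.affine_transform(
        patch.label.astype(np.float64), m, offset=offset, order=1, mode="constant", cval=0.0
    )
    return Patch(
        pixels=px.astype(np.float32),
        label=(lb > 0.5).astype(np.float32),
        source=patch.source,
        modality=patch.modality,
    )


def random_augment(patch: Patch, rng: np.random.Generator, ranges: dict | None = None) -> Patch:
    """Draw one augmentation uniformly from the configured ranges."""
    rng_cfg = dict(AUGMENT_RANGES, **(ranges or {}))
    t = rng_cfg["translation"]
    slo, shi = rng_cfg["scale"]
    r = rng_cfg["rotation_deg"]
    return augment(
        patch,
        translation=tuple(rng.uniform(-t, t, size=2)),
        scale=rng.uniform(slo, shi),
        rotation_deg=rng.uniform(-r, r),
        ranges=rng_cfg,
    )


def sample_training_patches(
    volume: ImageVolume,
    labels: np.ndarray,
    patch_size: int,
    n_patches: int,
    rng: np.random.Generator,
    volume_id: str = "vol",
) -> list[Patch]:
    """Class-balanced patch sampling: half centered on labeled catheter
    component centroids, half at random background positions.

    Catheter-centered windows are jittered by a few voxels so the target is
    not always dead-center.  Background centers are drawn uniformly over the
    slice; class balance keeps the trivial all-background solution from
    minimizing the loss.
    """
    rows, cols, n_slices = volume.shape
    labels = np.asarray(labels) > 0
    fg_centers: list[tuple[int, float, float]] = []
    for s in range(n_slices):
        lab, n = ndimage.label(labels[:, :, s], structure=np.ones((3, 3), dtype=int))
        if n:
            for r, c in ndimage.center_of_mass(labels[:, :, s], lab, range(1, n + 1)):
                fg_centers.append((s, r, c))
    if not fg_centers:
        raise ValueError("labels contain no foreground; cannot sample catheter patches")

    n_pos = n_patches // 2
    n_neg = n_patches - n_pos
    pick = rng.integers(0, len(fg_centers), size=n_pos)
    jitter = rng.uniform(-4, 4, size=(n_pos, 2))
    pos_centers = [
        (fg_centers[k][0], fg_centers[k][1] + jr, fg_centers[k][2] + jc)
        for k, (jr, jc) in zip(pick, jitter)
    ]
    neg_centers = [
        (int(s), float(r), float(c))
        for s, r, c in zip(
            rng.integers(0, n_slices, size=n_neg),
            rng.uniform(0, rows - 1, size=n_neg),
            rng.uniform(0, cols - 1, size=n_neg),
        )
    ]
    return extract_patches(
        volume, labels, patch_size, centers=pos_centers + neg_centers, volume_id=volume_id
    )


def save_patches(patches: list[Patch], path: str | Path) -> Path:
    """Persist a patch set as one .npz plus a JSON manifest alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        pixels=np.stack([p.pixels for p in patches]),
        labels=np.stack([p.label for p in patches]),
    )
    manifest = {
        "n_patches": len(patches),
        "patch_size": int(patches[0].pixels.shape[0]) if patches else 0,
        "sources": [list(p.source) for p in patches],
        "modalities": [p.modality for p in patches],
    }
    path.with_suffix(".json").write_text(json.dumps(manifest))
    return path


def load_patches(path: str | Path) -> list[Patch]:
    path = Path(path)
    arrs = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    return [
        Patch(px, lb, tuple(src), mod)
        for px, lb, src, mod in zip(
            arrs["pixels"], arrs["labels"], manifest["sources"], manifest["modalities"]
        )
    ]
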