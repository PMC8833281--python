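"""Synthetic paired T1W/T2W MR phantoms with known catheter trajectories.

Emulates the salient features of interstitial gynecologic implant MRI:
marker-filled plastic catheters that are hyperintense on T1W and appear as
signal voids on T2W, embedded in smoothly textured tissue background along
with dark air cavities that confound void-based detection.  Catheter tracks
are smooth in-plane random walks (clinical catheters curve), entering at a
template plane and ending at a tip determined by the insertion length.

No MR physics is simulated: no bias fields, no k-space artifacts, no
anatomy.  The phantom exists to exercise segmentation, linking, and
evaluation with exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .volume import ImageVolume

__all__ = [
    "PhantomConfig",
    "GroundTruthPath",
    "generate_phantom",
    "rasterize_truth_mask",
    "save_truth_paths",
    "load_truth_paths",
]

#: Default voxel spacing (mm): in-plane 0.5327 mm, 1 mm slices, matching the
#: 3D T1W/T2W protocol the method targets.
DEFAULT_SPACING = (0.5327, 0.5327, 1.0)


@dataclass
class PhantomConfig:
    """Parameters of the synthetic implant volume.

    Attributes
    ----------
    shape : (rows, cols, slices)
        Voxels per axis; each must be >= 8.
    spacing_mm : per-axis voxel size in mm.
    n_catheters : number of catheter tracks (>= 1).
    curvature : max in-plane drift per slice, voxels.  Values <= 1 keep
        adjacent-slice steps well inside the 8-pixel linking neighborhood.
    t1_contrast : catheter-to-background offset in T1W; must be > 0 (bright).
    t2_contrast : offset in T2W; must be < 0 (signal void).
    noise_sd : additive Gaussian noise scale.
    n_cavities : dark ellipsoidal confounders (dark in both contrasts).
    catheter_radius : rendered in-plane radius, voxels (~6F at 0.53 mm pixels).
    template_slice : index of the template plane (first covered slice).
    insertion_range_mm : (lo, hi) of per-catheter insertion lengths.
    total_length_mm / template_thickness_mm : catheter geometry used to derive
        each track's free length (total - template - insertion).
    rng_seed : seed for all randomness.
    """

    shape: tuple[int, int, int] = (96, 96, 40)
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    n_catheters: int = 10
    curvature: float = 1.0
    t1_contrast: float = 4.0
    t2_contrast: float = -4.0
    noise_sd: float = 0.5
    n_cavities: int = 3
    catheter_radius: float = 2.0
    template_slice: int = 2
    insertion_range_mm: tuple[float, float] = (28.0, 34.0)
    total_length_mm: float = 294.0
    template_thickness_mm: float = 20.0
    min_track_separation: float | None = None  # default 2*radius + 2 voxels
    rng_seed: int = 0

    @property
    def track_separation(self) -> float:
        """Smallest allowed same-slice distance between two catheters.

        Implanted catheters are solid and roughly parallel; their cross
        sections never overlap, so tracks keep at least two radii apart.
        """
        if self.min_track_separation is not None:
            return self.min_track_separation
        return 2.0 * self.catheter_radius + 2.0

    def validate(self) -> None:
        if any(int(s) < 8 for s in self.shape) or len(self.shape) != 3:
            raise ValueError(f"phantom shape must be three axes all >= 8, got {self.shape}")
        if self.n_catheters < 1:
            raise ValueError("n_catheters must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not (self.t1_contrast > 0 and self.t2_contrast < 0):
            raise ValueError(
                "contrast polarity must be bright-in-T1W (t1_contrast > 0) and "
                f"dark-in-T2W (t2_contrast < 0); got {self.t1_contrast}, {self.t2_contrast}"
            )
        if self.curvature < 0 or self.noise_sd < 0 or self.catheter_radius < 0:
            raise ValueError("curvature, noise_sd and catheter_radius must be non-negative")


@dataclass
class GroundTruthPath:
    """One catheter's true trajectory: one (row, col) point per covered slice."""

    catheter_id: int
    start_slice: int
    points: np.ndarray  # (n_slices, 2) float, in-plane (row, col)
    insertion_length_mm: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {self.points.shape}")

    @property
    def slices(self) -> np.ndarray:
        """Consecutive slice indices covered by this path."""
        return np.arange(self.start_slice, self.start_slice + len(self.points))

    @property
    def seed(self) -> tuple[float, float]:
        """Ground-truth position on the template plane (reconstruction seed)."""
        return tuple(self.points[0])


def _place_seeds(config: PhantomConfig, margin: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid seed placement; raises if the field of view is too small."""
    rows, cols, _ = config.shape
    sep = max(4.0 * config.catheter_radius, 10.0)
    r_lo, r_hi = margin, rows - 1 - margin
    c_lo, c_hi = margin, cols - 1 - margin
    if r_hi <= r_lo or c_hi <= c_lo:
        raise ValueError(
            f"volume shape {config.shape} too small for margin {margin:.1f} "
            "(catheter tracks would exit the field of view)"
        )
    nr = int((r_hi - r_lo) // sep) + 1
    nc = int((c_hi - c_lo) // sep) + 1
    if nr * nc < config.n_catheters:
        raise ValueError(
            f"cannot place {config.n_catheters} catheters with separation {sep:.1f} px "
            f"in shape {config.shape} (capacity {nr * nc}); reduce the count or curvature"
        )
    grid = [
        (r_lo + i * sep, c_lo + j * sep)
        for i in range(nr)
        for j in range(nc)
    ]
    chosen = rng.choice(len(grid), size=config.n_catheters, replace=False)
    seeds = np.array([grid[k] for k in chosen], dtype=float)
    seeds += rng.uniform(-1.5, 1.5, size=seeds.shape)
    return np.clip(seeds, [r_lo, c_lo], [r_hi, c_hi])


def _reflect(x: float, lo: float, hi: float) -> float:
    # fold a coordinate back into [lo, hi] (tracks never leave the margin box)
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
    return x


def _random_walk(
    seed_rc: np.ndarray, n_steps: int, config: PhantomConfig, margin: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth in-plane random walk with per-slice step <= curvature."""
    rows, cols, _ = config.shape
    pts = np.empty((n_steps + 1, 2))
    pts[0] = seed_rc
    if n_steps == 0:
        return pts
    steps = rng.normal(size=(n_steps, 2))
    steps = gaussian_filter1d(steps, sigma=2.0, axis=0, mode="nearest")
    peak = np.abs(steps).max()
    if peak > 0:
        steps *= config.curvature * rng.uniform(0.6, 1.0) / peak
    for i, (dr, dc) in enumerate(steps):
        r = _reflect(pts[i, 0] + dr, margin, rows - 1 - margin)
        c = _reflect(pts[i, 1] + dc, margin, cols - 1 - margin)
        pts[i + 1] = (r, c)
    return pts


def _soft_disk(sl: np.ndarray, center: np.ndarray, radius: float, amplitude: float) -> None:
    """Add an anti-aliased disk of the given amplitude to a 2D slice in place."""
    r0 = int(np.floor(center[0] - radius - 1))
    r1 = int(np.ceil(center[0] + radius + 1)) + 1
    c0 = int(np.floor(center[1] - radius - 1))
    c1 = int(np.ceil(center[1] + radius + 1)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, sl.shape[0]), min(c1, sl.shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d = np.hypot(rr - center[0], cc - center[1])
    sl[r0:r1, c0:c1] += amplitude * np.clip(radius + 0.5 - d, 0.0, 1.0)


def generate_phantom(
    config: PhantomConfig,
) -> tuple[ImageVolume, ImageVolume, list[GroundTruthPath]]:
    """Render paired T1W/T2W volumes and the ground-truth catheter paths.

    Both volumes share shape and spacing.  Each track starts on the template
    plane and spans ``floor(insertion_length / slice_thickness) + 1`` slices.
    Catheter voxels are brighter than local background in T1W and darker in
    T2W; cavities are dark in both and are kept away from the tracks.
    Identical config (including ``rng_seed``) reproduces output bitwise.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    rows, cols, n_slices = (int(s) for s in config.shape)
    slice_mm = config.spacing_mm[2]
    margin = config.catheter_radius + config.curvature + 2.0

    seeds = _place_seeds(config, margin, rng)

    # tracks and their insertion depths; walks are redrawn until every pair
    # keeps the physical separation (catheter cross sections cannot overlap)
    paths: list[GroundTruthPath] = []
    max_cov = n_slices - 1 - config.template_slice
    sep = config.track_separation
    for cid in range(config.n_catheters):
        ins = rng.uniform(*config.insertion_range_mm)
        n_cov = int(np.floor(ins / slice_mm))
        if config.template_slice + n_cov > n_slices - 1:
            raise ValueError(
                f"catheter {cid}: insertion {ins:.1f} mm needs "
                f"{n_cov} slices beyond the template plane but only {max_cov} fit "
                f"in shape {config.shape}"
            )
        pts = None
        for _ in range(60):
            trial = _random_walk(seeds[cid], n_cov, config, margin, rng)
            ok = True
            for other in paths:
                k = min(len(trial), len(other.points))
                if k and np.hypot(
                    *(trial[:k] - other.points[:k]).T
                ).min() < sep:
                    ok = False
                    break
            if ok:
                pts = trial
                break
        if pts is None:
            raise ValueError(
                f"catheter {cid}: could not keep {sep:.1f}-voxel separation from "
                f"other tracks in shape {config.shape}; reduce n_catheters or curvature"
            )
        paths.append(
            GroundTruthPath(
                catheter_id=cid,
                start_slice=config.template_slice,
                points=pts,
                insertion_length_mm=float(ins),
            )
        )

    # tissue-like background: base level plus low-pass-filtered texture
    base = 100.0
    t1 = np.full(config.shape, base, dtype=np.float64)
    t2 = np.full(config.shape, base, dtype=np.float64)
    for vol in (t1, t2):
        texture = gaussian_filter(rng.normal(size=config.shape), sigma=(4, 4, 2))
        vol += 1.5 * texture / max(texture.std(), 1e-12)

    # dark air-cavity confounders, rejected near any track point
    track_pts = np.concatenate(
        [np.column_stack([p.points, p.slices]) for p in paths]
    )
    cavities = 0
    attempts = 0
    while cavities < config.n_cavities and attempts < 200:
        attempts += 1
        center = rng.uniform([margin, margin, 2], [rows - margin, cols - margin, n_slices - 2])
        semi = rng.uniform([3, 3, 2], [7, 7, 4])
        scaled = (track_pts - center) / semi
        if (scaled**2).sum(axis=1).min() < 4.0:  # within 2 semi-axes of a track
            continue
        rr, cc, ss = np.meshgrid(
            np.arange(rows), np.arange(cols), np.arange(n_slices), indexing="ij"
        )
        d2 = (
            ((rr - center[0]) / semi[0]) ** 2
            + ((cc - center[1]) / semi[1]) ** 2
            + ((ss - center[2]) / semi[2]) ** 2
        )
        hole = np.exp(-d2 * 1.5)
        t1 -= 6.0 * hole
        t2 -= 6.0 * hole
        cavities += 1

    # render catheters: bright in T1W, dark (void) in T2W
    for p in paths:
        for k, s in enumerate(p.slices):
            _soft_disk(t1[:, :, s], p.points[k], config.catheter_radius, config.t1_contrast)
            _soft_disk(t2[:, :, s], p.points[k], config.catheter_radius, config.t2_contrast)

    if config.noise_sd > 0:
        t1 += rng.normal(0.0, config.noise_sd, size=config.shape)
        t2 += rng.normal(0.0, config.noise_sd, size=config.shape)

    t1w = ImageVolume(t1, config.spacing_mm, modality="t1w")
    t2w = ImageVolume(t2, config.spacing_mm, modality="t2w")
    return t1w, t2w, paths


def rasterize_truth_mask(
    paths: list[GroundTruthPath],
    shape: tuple[int, int, int],
    radius: float = 2.0,
) -> np.ndarray:
    """Binary mask stack with a disk at each path point (training labels).

    A voxel is foreground when its center lies within ``radius`` of the path
    point; the voxel nearest the point is always included, so ``radius=0``
    marks exactly one voxel.

    Raises
    ------
    ValueError
        If any point falls outside ``shape`` (names the catheter and slice).
    """
    rows, cols, n_slices = shape
    mask = np.zeros(shape, dtype=bool)
    for p in paths:
        for k, s in enumerate(p.slices):
            r, c = p.points[k]
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < rows and 0 <= ci < cols and 0 <= s < n_slices):
                raise ValueError(
                    f"catheter {p.catheter_id}: point ({r:.1f}, {c:.1f}) on slice {s} "
                    f"is outside volume shape {shape}"
                )
            mask[ri, ci, s] = True
            if radius > 0:
                r0 = max(int(np.floor(r - radius)), 0)
                r1 = min(int(np.ceil(r + radius)) + 1, rows)
                c0 = max(int(np.floor(c - radius)), 0)
                c1 = min(int(np.ceil(c + radius)) + 1, cols)
                rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
                mask[r0:r1, c0:c1, s] |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    return mask


def save_truth_paths(paths: list[GroundTruthPath], path: str | Path) -> Path:
    """Serialize ground-truth paths to JSON."""
    out = {
        str(p.catheter_id): {
            "start_slice": int(p.start_slice),
            "insertion_length_mm": p.insertion_length_mm,
            "points": np.asarray(p.points).tolist(),
        }
        for p in paths
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=1))
    return path


def load_truth_paths(path: str | Path) -> list[GroundTruthPath]:
    raw = json.loads(Path(path).read_text())
    return [
        GroundTruthPath(
            catheter_id=int(cid),
            start_slice=int(rec["start_slice"]),
            points=np.asarray(rec["points"], dtype=float),
            insertion_length_mm=float(rec["insertion_length_mm"]),
        )
        for cid, rec in sorted(raw.items(), key=lambda kv: int(kv[0]))
    ]
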