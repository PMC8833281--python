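"""Slice-to-slice catheter path building from per-contrast binary masks.

The second stage of the method.  Per slice, connected components of the
binarized network output become candidates; each candidate is refined to the
intensity extremum inside a small rectangle (argmax in T1W where catheters
are bright, argmin in T2W where they are voids); candidates from the two
contrasts are fused; tracked catheters are linked to their nearest fused
candidate within an 8-pixel neighborhood; catheters with no candidate in
reach ("jumping catheters") are imputed by adding the mean absolute
displacement of the detected catheters; and tracking stops per catheter at
the slice implied by its physical insertion length
(total - [free length + template thickness]).

Coordinates are 0-based (row, col) voxel indices in-plane plus a slice
index; world mm = index * spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "Candidate",
    "CatheterPath",
    "TemplateGeometry",
    "find_candidates",
    "refine_in_rectangle",
    "link_next_slice",
    "correct_jumping",
    "compute_stop_slice",
    "merge_modalities",
    "reconstruct",
    "save_paths_json",
    "load_paths_json",
    "paths_to_dataframe",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class Candidate:
    """A putative catheter cross-section on one slice."""

    slice_index: int
    centroid: tuple[float, float]  # (row, col)
    modality: str = "unknown"
    size: int = 1  # component size in voxels
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("component size must be >= 1")
        if not self.sources:
            self.sources = (self.modality,)

    @property
    def dual(self) -> bool:
        """True when the candidate was confirmed by both contrasts."""
        return len(set(self.sources)) > 1


@dataclass
class CatheterPath:
    """Ordered reconstruction of one catheter: one point per slice.

    ``provenance[k]`` records how point ``k`` was obtained: ``"seed"`` for
    the manual template-plane position, ``"linked"`` for a matched (refined)
    candidate, ``"jump-corrected"`` for an imputed position.
    """

    catheter_id: int
    start_slice: int
    points: np.ndarray  # (n, 2) float (row, col)
    provenance: list[str] = field(default_factory=list)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not self.provenance:
            self.provenance = ["seed"] + ["linked"] * (len(self.points) - 1)
        if len(self.provenance) != len(self.points):
            raise ValueError("provenance length must match point count")

    @property
    def slices(self) -> np.ndarray:
        return np.arange(self.start_slice, self.start_slice + len(self.points))

    def world_points(self) -> np.ndarray:
        """(n, 3) positions in mm: (row, col, slice) * spacing."""
        sr, sc, sz = self.spacing_mm
        return np.column_stack(
            [self.points[:, 0] * sr, self.points[:, 1] * sc, self.slices * sz]
        )


@dataclass
class TemplateGeometry:
    """Physical implant geometry driving the free-length stopping rule.

    Per catheter: total length and free length (mm); global: template
    thickness (mm), template-plane slice index, and the per-catheter seed
    coordinates on that slice.
    """

    total_length_mm: np.ndarray
    free_length_mm: np.ndarray
    template_thickness_mm: float
    start_slice: int
    seeds: np.ndarray  # (n, 2) float (row, col)

    def __post_init__(self) -> None:
        self.total_length_mm = np.atleast_1d(np.asarray(self.total_length_mm, dtype=float))
        self.free_length_mm = np.atleast_1d(np.asarray(self.free_length_mm, dtype=float))
        self.seeds = np.atleast_2d(np.asarray(self.seeds, dtype=float))
        n = len(self.seeds)
        if n == 0:
            raise ValueError("geometry needs at least one seed")
        if len(self.total_length_mm) == 1:
            self.total_length_mm = np.repeat(self.total_length_mm, n)
        if len(self.free_length_mm) == 1:
            self.free_length_mm = np.repeat(self.free_length_mm, n)
        if not (len(self.total_length_mm) == len(self.free_length_mm) == n):
            raise ValueError("per-catheter lengths must match the number of seeds")
        used = self.free_length_mm + self.template_thickness_mm
        if np.any(used < 0) or np.any(used > self.total_length_mm):
            raise ValueError("need 0 <= free_length + template_thickness <= total_length")
        if len(np.unique(self.seeds, axis=0)) != n:
            raise ValueError("seed coordinates must be distinct")

    @property
    def n_catheters(self) -> int:
        return len(self.seeds)


def find_candidates(
    mask_slice: np.ndarray,
    slice_index: int = 0,
    modality: str = "unknown",
    min_size: int = 1,
) -> list[Candidate]:
    """Connected-component candidates on one binary slice.

    Components are 8-connected; each yields one candidate at its voxel-mean
    centroid.  Components smaller than ``min_size`` voxels are dropped.
    An empty slice yields an empty list.
    """
    mask_slice = np.asarray(mask_slice) > 0
    lab, n = ndimage.label(mask_slice, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(mask_slice, lab, range(1, n + 1))
    centroids = ndimage.center_of_mass(mask_slice, lab, range(1, n + 1))
    return [
        Candidate(
            slice_index=slice_index,
            centroid=(float(r), float(c)),
            modality=modality,
            size=int(s),
        )
        for (r, c), s in zip(centroids, sizes)
        if s >= min_size
    ]


def refine_in_rectangle(
    image_slice: np.ndarray,
    approx: tuple[float, float],
    halfsize: int = 5,
    modality: str = "t1w",
) -> tuple[int, int]:
    """Snap an approximate position to the intensity extremum in a rectangle.

    The rectangle of half-width ``halfsize`` around ``approx`` is clipped to
    the slice; the returned voxel is the intensity argmax for T1W (catheters
    bright) or argmin for T2W (signal voids).  Exact ties are broken by
    smallest Euclidean distance to ``approx``, then row-major order.

    Raises
    ------
    ValueError
        If the clipped rectangle is empty or the modality is unknown.
    """
    if modality not in ("t1w", "t2w"):
        raise ValueError(f"modality must be 't1w' or 't2w', got {modality!r}")
    rows, cols = image_slice.shape
    r0 = max(int(np.floor(approx[0])) - halfsize, 0)
    r1 = min(int(np.ceil(approx[0])) + halfsize + 1, rows)
    c0 = max(int(np.floor(approx[1])) - halfsize, 0)
    c1 = min(int(np.ceil(approx[1])) + halfsize + 1, cols)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"rectangle around {approx} is empty after clipping")
    window = np.asarray(image_slice[r0:r1, c0:c1], dtype=float)
    target = window.max() if modality == "t1w" else window.min()
    hits = np.argwhere(window == target)
    rr = hits[:, 0] + r0
    cc = hits[:, 1] + c0
    d2 = (rr - approx[0]) ** 2 + (cc - approx[1]) ** 2
    order = np.lexsort((cc, rr, d2))  # distance first, then row-major
    k = order[0]
    return int(rr[k]), int(cc[k])


def refine_region_centroid(
    image_slice: np.ndarray,
    approx: tuple[float, float],
    halfsize: int = 5,
    modality: str = "t1w",
) -> tuple[float, float]:
    """Snap a position to the centroid of the extreme-intensity *region*.

    Within the clipped rectangle the hyperintense (T1W) or hypointense
    (T2W) region is segmented by thresholding halfway between the window
    median and its extremum; of the resulting 8-connected components the
    one nearest ``approx`` is kept and its intensity-unweighted centroid
    returned.  Averaging over the whole cross-section makes this robust to
    single-pixel noise, unlike the pure extremum of
    :func:`refine_in_rectangle`.

    Raises
    ------
    ValueError
        If the clipped rectangle is empty or the modality is unknown.
    """
    if modality not in ("t1w", "t2w"):
        raise ValueError(f"modality must be 't1w' or 't2w', got {modality!r}")
    rows, cols = image_slice.shape
    r0 = max(int(np.floor(approx[0])) - halfsize, 0)
    r1 = min(int(np.ceil(approx[0])) + halfsize + 1, rows)
    c0 = max(int(np.floor(approx[1])) - halfsize, 0)
    c1 = min(int(np.ceil(approx[1])) + halfsize + 1, cols)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"rectangle around {approx} is empty after clipping")
    window = np.asarray(image_slice[r0:r1, c0:c1], dtype=float)
    if modality == "t2w":
        window = -window  # voids become peaks
    thr = 0.5 * (np.median(window) + window.max())
    blob = window >= thr
    if not blob.any():  # constant window: nothing to segment
        return float(approx[0]), float(approx[1])
    lab, n = ndimage.label(blob, structure=_EIGHT_CONNECTED)
    centroids = ndimage.center_of_mass(blob, lab, range(1, n + 1))
    best = min(
        centroids,
        key=lambda rc: (rc[0] + r0 - approx[0]) ** 2 + (rc[1] + c0 - approx[1]) ** 2,
    )
    return float(best[0] + r0), float(best[1] + c0)


def link_next_slice(
    current_positions: dict[int, tuple[float, float]],
    candidates: list[Candidate],
    neighborhood_px: float = 8.0,
) -> tuple[dict[int, Candidate], list[int]]:
    """Greedy one-to-one nearest-candidate assignment within the neighborhood.

    Pairs are taken in ascending Euclidean distance (ties by catheter id,
    then candidate order); each candidate serves at most one catheter, and
    surplus candidates are discarded as false positives.  Catheters left
    without a candidate within ``neighborhood_px`` are returned as jumped.

    Returns
    -------
    (assignments, jumped) : dict catheter id -> Candidate, list of jumped ids.
    """
    if not current_positions:
        raise ValueError("need at least one tracked catheter")
    pairs = []
    for cid, (r, c) in current_positions.items():
        for j, cand in enumerate(candidates):
            d = float(np.hypot(cand.centroid[0] - r, cand.centroid[1] - c))
            if d <= neighborhood_px:
                pairs.append((d, cid, j))
    pairs.sort()
    assignments: dict[int, Candidate] = {}
    used: set[int] = set()
    for d, cid, j in pairs:
        if cid in assignments or j in used:
            continue
        assignments[cid] = candidates[j]
        used.add(j)
    jumped = [cid for cid in current_positions if cid not in assignments]
    return assignments, jumped


def correct_jumping(
    prev_detected: np.ndarray,
    next_detected: np.ndarray,
    jumped_prev: np.ndarray,
    signed: bool = False,
) -> np.ndarray:
    """Impute jumped-catheter positions from the detected catheters' motion.

    The per-axis shifts are the means over detected catheters of the
    *absolute* displacements between consecutive slices, and are added to
    each jumped catheter's coordinates.  ``signed=True`` switches to signed
    mean displacements (an alternative for oscillating implants; off by
    default).

    Raises
    ------
    ValueError
        If no catheter was detected on both slices (the mean is undefined;
        callers fall back to carrying positions over unchanged).
    """
    prev_detected = np.atleast_2d(np.asarray(prev_detected, dtype=float))
    next_detected = np.atleast_2d(np.asarray(next_detected, dtype=float))
    jumped_prev = np.atleast_2d(np.asarray(jumped_prev, dtype=float))
    if prev_detected.size == 0 or len(prev_detected) == 0:
        raise ValueError("jump correction undefined with zero detected catheters")
    if prev_detected.shape != next_detected.shape:
        raise ValueError("prev/next detected position arrays must match in shape")
    disp = next_detected - prev_detected
    delta = disp.mean(axis=0) if signed else np.abs(disp).mean(axis=0)
    return jumped_prev + delta


def compute_stop_slice(
    geometry: TemplateGeometry, slice_thickness_mm: float
) -> np.ndarray:
    """Last covered slice index per catheter from the free-length rule.

    insertion = total - (free + template thickness);
    covered slices beyond the template plane = floor(insertion / thickness);
    stop = start_slice + covered.  Assumes roughly axial insertion so that
    physical depth maps to slice count by division by slice thickness.

    Raises
    ------
    ValueError
        If any insertion length is negative or thickness is not positive.
    """
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be positive")
    insertion = geometry.total_length_mm - (
        geometry.free_length_mm + geometry.template_thickness_mm
    )
    if np.any(insertion < 0):
        raise ValueError(f"negative insertion length: {insertion}")
    covered = np.floor(insertion / slice_thickness_mm + 1e-9).astype(int)
    return geometry.start_slice + covered


def merge_modalities(
    t1w_candidates: list[Candidate],
    t2w_candidates: list[Candidate],
    tolerance_px: float = 2.0,
) -> list[Candidate]:
    """Fuse candidate lists from the two contrasts.

    Pairs within ``tolerance_px`` (greedy, ascending distance) merge to
    their coordinate mean and are flagged dual-modality; unmatched
    candidates are kept as single-modality entries.
    """
    pairs = []
    for i, a in enumerate(t1w_candidates):
        for j, b in enumerate(t2w_candidates):
            d = float(np.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1]))
            if d <= tolerance_px:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    fused: list[Candidate] = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = t1w_candidates[i], t2w_candidates[j]
        fused.append(
            Candidate(
                slice_index=a.slice_index,
                centroid=(
                    (a.centroid[0] + b.centroid[0]) / 2.0,
                    (a.centroid[1] + b.centroid[1]) / 2.0,
                ),
                modality="fused",
                size=a.size + b.size,
                sources=tuple(a.sources) + tuple(b.sources),
            )
        )
    fused.extend(a for i, a in enumerate(t1w_candidates) if i not in used_a)
    fused.extend(b for j, b in enumerate(t2w_candidates) if j not in used_b)
    return fused


def _slice_candidates(
    mask_stack: np.ndarray,
    intensity: ImageVolume | None,
    s: int,
    modality: str,
    min_size: int,
    rect_halfsize: int,
    refine_mode: str | None,
) -> list[Candidate]:
    cands = find_candidates(mask_stack[:, :, s], s, modality, min_size)
    if refine_mode is not None and intensity is not None:
        fn = refine_region_centroid if refine_mode == "region" else refine_in_rectangle
        out = []
        for c in cands:
            r, cc = fn(intensity.slice(s), c.centroid, rect_halfsize, modality)
            out.append(
                Candidate(s, (float(r), float(cc)), modality, c.size, c.sources)
            )
        return out
    return cands


def reconstruct(
    t1w: ImageVolume | None,
    t2w: ImageVolume | None,
    t1w_masks: np.ndarray | None,
    t2w_masks: np.ndarray | None,
    geometry: TemplateGeometry,
    rect_halfsize: int = 5,
    neighborhood_px: float = 8.0,
    merge_tolerance_px: float = 2.0,
    min_component_size: int = 1,
    signed_jump: bool = False,
    refine_mode: str | None = "region",
    arc_length_stop: bool = False,
) -> list[CatheterPath]:
    """Build one complete path per seed from template plane to computed tip.

    Iterates slice-by-slice: per-contrast candidate detection ->
    extremum refinement inside rectangles on the *intensity* images ->
    cross-contrast fusion -> nearest-candidate linking -> jumping-catheter
    correction.  Every seed yields a path covering every slice up to its
    stop slice (no catheter is ever dropped): a transition where all
    catheters jump falls back to carrying positions over unchanged.

    ``refine_mode`` selects how candidates are localized on the intensity
    images: ``"region"`` (default) segments the hyper/hypointense region in
    the rectangle and takes its centroid; ``"extremum"`` uses the
    single-pixel argmax/argmin of :func:`refine_in_rectangle`; ``None``
    keeps the raw mask-component centroids.

    With ``arc_length_stop=True`` the stop criterion accumulates 3D path
    length until it reaches the insertion length, instead of converting
    insertion depth to a slice count.

    Raises
    ------
    ValueError
        If no seeds are given, the volumes/masks disagree in shape, or a
        required slice is missing from the inputs.
    """
    if geometry.n_catheters == 0:
        raise ValueError("no seeds: at least one catheter is required")
    streams = []
    if t1w_masks is not None:
        streams.append(("t1w", np.asarray(t1w_masks), t1w))
    if t2w_masks is not None:
        streams.append(("t2w", np.asarray(t2w_masks), t2w))
    if not streams:
        raise ValueError("need at least one of t1w_masks / t2w_masks")
    shape = streams[0][1].shape
    for name, m, vol in streams:
        if m.shape != shape:
            raise ValueError(f"{name} mask shape {m.shape} != {shape}")
        if vol is not None and vol.shape != shape:
            raise ValueError(f"{name} volume shape {vol.shape} != mask shape {shape}")
    spacing = None
    for _, _, vol in streams:
        if vol is not None:
            spacing = vol.spacing_mm
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)

    m = geometry.start_slice
    thickness = spacing[2]
    stops = compute_stop_slice(geometry, thickness)
    insertion = geometry.total_length_mm - (
        geometry.free_length_mm + geometry.template_thickness_mm
    )
    n_slices = shape[2]
    if m >= n_slices:
        raise ValueError(f"start slice {m} outside volume with {n_slices} slices")
    if not arc_length_stop and stops.max() >= n_slices:
        raise ValueError(
            f"stop slice {stops.max()} beyond last volume slice {n_slices - 1}; "
            "volume does not cover the implanted length"
        )

    n = geometry.n_catheters
    pts: list[list[np.ndarray]] = [[geometry.seeds[i].copy()] for i in range(n)]
    prov: list[list[str]] = [["seed"] for _ in range(n)]
    arc_len = np.zeros(n)

    def active_ids(s: int) -> list[int]:
        if arc_length_stop:
            return [i for i in range(n) if arc_len[i] < insertion[i]]
        return [i for i in range(n) if stops[i] >= s]

    s = m
    while True:
        s += 1
        act = active_ids(s)
        if not act or s >= n_slices:
            break
        per_mod: dict[str, list[Candidate]] = {}
        for name, masks, vol in streams:
            per_mod[name] = _slice_candidates(
                masks, vol, s, name, min_component_size, rect_halfsize, refine_mode
            )
        if len(streams) == 2:
            fused = merge_modalities(
                per_mod["t1w"], per_mod["t2w"], merge_tolerance_px
            )
        else:
            fused = next(iter(per_mod.values()))

        current = {i: tuple(pts[i][-1]) for i in act}
        assigned, jumped = link_next_slice(current, fused, neighborhood_px)

        det_prev = np.array([current[i] for i in assigned])
        det_next = np.array([assigned[i].centroid for i in assigned])
        if jumped:
            jp = np.array([current[i] for i in jumped])
            if len(det_prev):
                corrected = correct_jumping(det_prev, det_next, jp, signed=signed_jump)
            else:
                corrected = jp  # nothing detected: carry positions over
        for i in act:
            if i in assigned:
                new = np.asarray(assigned[i].centroid, dtype=float)
                prov[i].append("linked")
            else:
                new = corrected[jumped.index(i)]
                prov[i].append("jump-corrected")
            step = new - pts[i][-1]
            arc_len[i] += float(
                np.sqrt((step[0] * spacing[0]) ** 2 + (step[1] * spacing[1]) ** 2
                        + spacing[2] ** 2)
            )
            pts[i].append(new)

    return [
        CatheterPath(
            catheter_id=i,
            start_slice=m,
            points=np.vstack(pts[i]),
            provenance=prov[i],
            spacing_mm=spacing,
        )
        for i in range(n)
    ]


# -- path serialization ---------------------------------------------------

def paths_to_dataframe(paths: list[CatheterPath]) -> pd.DataFrame:
    """Flat table: catheter_id, slice, row, col, x_mm, y_mm, z_mm, provenance."""
    rows = []
    for p in paths:
        world = p.world_points()
        for k, s in enumerate(p.slices):
            rows.append(
                {
                    "catheter_id": p.catheter_id,
                    "slice": int(s),
                    "row": p.points[k, 0],
                    "col": p.points[k, 1],
                    "x_mm": world[k, 0],
                    "y_mm": world[k, 1],
                    "z_mm": world[k, 2],
                    "provenance": p.provenance[k],
                }
            )
    return pd.DataFrame(rows)


def save_paths_json(paths: list[CatheterPath], path: str | Path) -> Path:
    out = {
        str(p.catheter_id): {
            "start_slice": int(p.start_slice),
            "spacing_mm": list(p.spacing_mm),
            "points": p.points.tolist(),
            "provenance": p.provenance,
        }
        for p in paths
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=1))
    return path


def load_paths_json(path: str | Path) -> list[CatheterPath]:
    raw = json.loads(Path(path).read_text())
    return [
        CatheterPath(
            catheter_id=int(cid),
            start_slice=int(rec["start_slice"]),
            points=np.asarray(rec["points"], dtype=float),
            provenance=list(rec["provenance"]),
            spacing_mm=tuple(rec["spacing_mm"]),
        )
        for cid, rec in sorted(raw.items(), key=lambda kv: int(kv[0]))
    ]
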