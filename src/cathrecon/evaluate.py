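"""Agreement metrics between reconstructed and reference catheter paths.

Paths are compared through dwell positions: 3D points resampled at 1 mm
arc-length intervals along each path (HDR afterloaders step the source at
fixed intervals, so these are the clinically meaningful locations).  Each
dwell's deviation is its distance to the nearest point on the other path's
polyline, which separates lateral reconstruction error from longitudinal
dwell indexing.  Overlap of the rasterized paths is summarized by the Dice
similarity coefficient, and worst-case disagreement by the symmetric
point-set Hausdorff distance on dwells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .phantom import rasterize_truth_mask

__all__ = [
    "DwellSet",
    "EvalReport",
    "sample_dwells",
    "dwell_deviation",
    "dsc",
    "hausdorff",
    "evaluate_paths",
    "export_report",
]


@dataclass
class DwellSet:
    """Ordered 3D dwell points (mm) at 1 mm arc-length spacing along a path.

    The terminal path point is always included even when the last interval
    is shorter than the spacing (the tip is clinically salient).
    """

    catheter_id: int
    points: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError(f"dwell points must be (n, 3), got {self.points.shape}")


def _world_points(path, spacing_mm=None) -> np.ndarray:
    """Accept a CatheterPath/GroundTruthPath or a raw (n, 3) mm array."""
    if hasattr(path, "world_points"):
        return path.world_points()
    if hasattr(path, "points") and hasattr(path, "slices"):
        if spacing_mm is None:
            raise ValueError("spacing_mm required to convert voxel path to mm")
        sr, sc, sz = spacing_mm
        pts = np.asarray(path.points, dtype=float)
        return np.column_stack([pts[:, 0] * sr, pts[:, 1] * sc, np.asarray(path.slices) * sz])
    return np.atleast_2d(np.asarray(path, dtype=float))


def sample_dwells(path, spacing_mm=None, interval_mm: float = 1.0) -> DwellSet:
    """Resample a path at fixed arc-length intervals (piecewise linear).

    Points sit at arc lengths 0, ``interval_mm``, 2*``interval_mm``, ... and
    the terminal point is appended when it does not coincide with the last
    regular sample.  A single-point path yields a single dwell.

    Raises
    ------
    ValueError
        If the path is empty.
    """
    pts = _world_points(path, spacing_mm)
    if pts.size == 0:
        raise ValueError("cannot sample dwells from an empty path")
    cid = int(getattr(path, "catheter_id", -1))
    if len(pts) == 1:
        return DwellSet(cid, pts.copy())
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(0.0, total + 1e-9, interval_mm)
    if total - targets[-1] > 1e-9:
        targets = np.append(targets, total)
    dwells = np.column_stack([np.interp(targets, cum, pts[:, k]) for k in range(3)])
    return DwellSet(cid, dwells)


def _point_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest location on a polyline."""
    points = np.atleast_2d(points)
    poly = np.atleast_2d(poly)
    if len(poly) == 1:
        return np.linalg.norm(points - poly[0], axis=1)
    a = poly[:-1]  # (m, 3)
    ab = poly[1:] - a
    denom = (ab * ab).sum(axis=1)
    denom[denom == 0] = 1.0
    ap = points[:, None, :] - a[None, :, :]  # (n, m, 3)
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def dwell_deviation(
    a: DwellSet, b: DwellSet, paired: bool = False
) -> tuple[np.ndarray, dict]:
    """Per-dwell deviations of ``a`` against path ``b`` plus summary stats.

    Default mode measures each dwell of ``a`` against the nearest point on
    ``b``'s polyline; ``paired=True`` instead pairs dwells by index (a
    sensitivity mode that conflates longitudinal offset with lateral error).

    Returns
    -------
    (distances_mm, summary) where summary holds mean, sd, fraction < 2 mm,
    fraction > 3 mm, and the dwell count.

    Raises
    ------
    ValueError
        If either dwell set is empty.
    """
    if a.points.size == 0 or b.points.size == 0:
        raise ValueError("dwell sets must be non-empty")
    if paired:
        n = min(len(a.points), len(b.points))
        d = np.linalg.norm(a.points[:n] - b.points[:n], axis=1)
    else:
        d = _point_to_polyline(a.points, b.points)
    summary = {
        "mean_mm": float(d.mean()),
        "sd_mm": float(d.std()),
        "frac_below_2mm": float((d < 2.0).mean()),
        "frac_above_3mm": float((d > 3.0).mean()),
        "n_dwells": int(len(d)),
    }
    return d, summary


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 1.0 when both empty.

    Raises
    ------
    ValueError
        On shape mismatch.
    """
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def hausdorff(a: DwellSet | np.ndarray, b: DwellSet | np.ndarray) -> float:
    """Symmetric point-set Hausdorff distance (mm) between dwell sets.

    Raises
    ------
    ValueError
        If either set is empty.
    """
    pa = a.points if isinstance(a, DwellSet) else np.atleast_2d(np.asarray(a, dtype=float))
    pb = b.points if isinstance(b, DwellSet) else np.atleast_2d(np.asarray(b, dtype=float))
    if pa.size == 0 or pb.size == 0:
        raise ValueError("point sets must be non-empty")
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


@dataclass
class EvalReport:
    """Pooled per-dwell agreement between two sets of paths."""

    deviations_mm: np.ndarray
    mean_mm: float
    sd_mm: float
    frac_below_2mm: float
    frac_above_3mm: float
    dsc: float
    hausdorff_mm: float
    n_dwells: int
    per_catheter: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "mean_mm": self.mean_mm,
            "sd_mm": self.sd_mm,
            "frac_below_2mm": self.frac_below_2mm,
            "frac_above_3mm": self.frac_above_3mm,
            "dsc": self.dsc,
            "hausdorff_mm": self.hausdorff_mm,
            "n_dwells": self.n_dwells,
            "per_catheter": self.per_catheter,
        }


def evaluate_paths(
    predicted: list,
    truth: list,
    spacing_mm: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
    mask_radius: float = 2.0,
    interval_mm: float = 1.0,
) -> EvalReport:
    """Full agreement report between predicted and reference paths.

    Paths are matched by ``catheter_id``.  Deviations are pooled per dwell
    across catheters; Hausdorff is computed per catheter and averaged; DSC
    compares the two path sets rasterized with ``mask_radius`` (the same
    disk radius used for training labels) when ``shape`` is given.
    """
    truth_by_id = {int(t.catheter_id): t for t in truth}
    devs = []
    per_catheter = []
    hds = []
    for p in predicted:
        t = truth_by_id.get(int(p.catheter_id))
        if t is None:
            continue
        da = sample_dwells(p, spacing_mm, interval_mm)
        db = sample_dwells(t, spacing_mm, interval_mm)
        d, s = dwell_deviation(da, db)
        hd = hausdorff(da, db)
        hds.append(hd)
        devs.append(d)
        per_catheter.append({"catheter_id": int(p.catheter_id), **s, "hausdorff_mm": hd})
    if not devs:
        raise ValueError("no catheter ids in common between predicted and truth")
    d = np.concatenate(devs)
    overlap = np.nan
    if shape is not None:
        pred_mask = rasterize_truth_mask(predicted, shape, radius=mask_radius)
        true_mask = rasterize_truth_mask(truth, shape, radius=mask_radius)
        overlap = dsc(pred_mask, true_mask)
    return EvalReport(
        deviations_mm=d,
        mean_mm=float(d.mean()),
        sd_mm=float(d.std()),
        frac_below_2mm=float((d < 2.0).mean()),
        frac_above_3mm=float((d > 3.0).mean()),
        dsc=float(overlap),
        hausdorff_mm=float(np.mean(hds)),
        n_dwells=int(len(d)),
        per_catheter=per_catheter,
    )


def export_report(
    report: EvalReport, out_dir: str | Path, bin_width_mm: float = 0.25
) -> dict[str, Path]:
    """Write a JSON summary and a CSV deviation histogram.

    Histogram bins start at 0 with the given width; counts sum to the total
    dwell count.

    Raises
    ------
    OSError
        If the output location cannot be written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = report.deviations_mm
    n_bins = max(int(np.ceil((d.max() + 1e-9) / bin_width_mm)), 1)
    edges = np.arange(0.0, (n_bins + 1) * bin_width_mm, bin_width_mm)[: n_bins + 1]
    counts, edges = np.histogram(d, bins=edges)
    hist = pd.DataFrame(
        {"bin_lo_mm": edges[:-1], "bin_hi_mm": edges[1:], "count": counts}
    )
    hist_path = out_dir / "deviation_histogram.csv"
    hist.to_csv(hist_path, index=False)
    summary_path = out_dir / "evaluation_summary.json"
    summary_path.write_text(json.dumps(report.summary(), indent=1))
    return {"histogram": hist_path, "summary": summary_path}
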