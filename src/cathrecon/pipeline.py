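"""Multi-stage reproducible pipeline: simulate -> train -> predict ->
reconstruct -> evaluate, with a single configuration and a run manifest.

All randomness flows from explicit seeds in the configuration; every file a
run produces is listed in ``manifest.json`` with its SHA-256 hash, so two
runs with the same configuration can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import phantom as ph
from .evaluate import EvalReport, evaluate_paths, export_report
from .patches import sample_training_patches
from .postprocess import (
    TemplateGeometry,
    paths_to_dataframe,
    reconstruct,
    save_paths_json,
)
from .unet import UNetSegmenter, binarize, load_checkpoint, save_checkpoint
from .volume import ImageVolume, load_volume, normalize, save_volume

__all__ = [
    "RunConfig",
    "run_pipeline",
    "save_geometry",
    "load_geometry",
]

log = logging.getLogger("cathrecon")

#: Desk-scale network defaults used when a config omits the unet section.
_UNET_DEFAULTS = {
    "widths": (8, 16, 32, 64, 128),
    "learning_rate": 1e-3,
    "epochs": 10,
    "batch_size": 8,
    "smooth_eps": 1.0,
    "augment": False,
}
_TRAIN_DEFAULTS = {"patch_size": 64, "n_patches": 1000}
_POST_DEFAULTS = {
    "rect_halfsize": 5,
    "neighborhood_px": 8.0,
    "merge_tolerance_px": 2.0,
    "min_component_size": 1,
    "signed_jump": False,
    "refine_mode": "region",
    "arc_length_stop": False,
}
_EVAL_DEFAULTS = {"interval_mm": 1.0, "bin_width_mm": 0.25, "mask_radius": 2.0}


class RunConfig:
    """Validated pipeline configuration (YAML/JSON file or plain dict)."""

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.seed = int(raw.get("seed", 0))
        self.phantom = raw.get("phantom")
        self.volumes = raw.get("volumes", {})
        self.checkpoints = raw.get("checkpoints", {})
        self.seeds_file = raw.get("seeds_file")
        self.unet = {**_UNET_DEFAULTS, **raw.get("unet", {})}
        self.train = {**_TRAIN_DEFAULTS, **raw.get("train", {})}
        self.post = {**_POST_DEFAULTS, **raw.get("postprocess", {})}
        self.eval = {**_EVAL_DEFAULTS, **raw.get("evaluate", {})}
        for key in ("t1w", "t2w"):
            p = self.volumes.get(key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured {key} volume not found: {p}")
        if self.seeds_file is not None and not Path(self.seeds_file).exists():
            raise FileNotFoundError(f"seeds/geometry file not found: {self.seeds_file}")
        if self.phantom is None and not self.volumes:
            raise ValueError("config needs either a phantom section or volume paths")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls(raw or {})


def save_geometry(geometry: TemplateGeometry, path: str | Path) -> Path:
    """Write the seeds/geometry sidecar as JSON."""
    out = {
        "start_slice": int(geometry.start_slice),
        "template_thickness_mm": float(geometry.template_thickness_mm),
        "catheters": [
            {
                "id": i,
                "seed": list(map(float, geometry.seeds[i])),
                "total_length_mm": float(geometry.total_length_mm[i]),
                "free_length_mm": float(geometry.free_length_mm[i]),
            }
            for i in range(geometry.n_catheters)
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=1))
    return path


def load_geometry(path: str | Path) -> TemplateGeometry:
    raw = json.loads(Path(path).read_text())
    cats = raw["catheters"]
    return TemplateGeometry(
        total_length_mm=np.array([c["total_length_mm"] for c in cats]),
        free_length_mm=np.array([c["free_length_mm"] for c in cats]),
        template_thickness_mm=float(raw["template_thickness_mm"]),
        start_slice=int(raw["start_slice"]),
        seeds=np.array([c["seed"] for c in cats]),
    )


def geometry_from_truth(
    paths: list[ph.GroundTruthPath],
    total_length_mm: float = 294.0,
    template_thickness_mm: float = 20.0,
) -> TemplateGeometry:
    """Implant geometry consistent with a set of ground-truth paths: the
    free length of each catheter is whatever remains of the total length
    after its insertion depth and the template thickness."""
    return TemplateGeometry(
        total_length_mm=np.full(len(paths), total_length_mm),
        free_length_mm=np.array(
            [total_length_mm - template_thickness_mm - p.insertion_length_mm for p in paths]
        ),
        template_thickness_mm=template_thickness_mm,
        start_slice=paths[0].start_slice,
        seeds=np.array([p.seed for p in paths]),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager logging stage wall time (informational only)."""

    def __init__(self, name: str, **params):
        self.name, self.params = name, params

    def __enter__(self):
        log.info("stage %s: start %s", self.name, self.params or "")
        self._t0 = time.time()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            log.error("stage %s: failed: %s", self.name, exc)
            return False
        log.info("stage %s: done in %.1fs", self.name, time.time() - self._t0)
        return False


def run_pipeline(config: RunConfig | dict, out_dir: str | Path) -> EvalReport | None:
    """Execute the configured stages, writing all artifacts under ``out_dir``.

    Returns the evaluation report, or None when no ground truth is
    available (reconstruction outputs are still produced).  Deterministic
    given the configuration, including its seeds.
    """
    if isinstance(config, dict):
        config = RunConfig(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    rng_root = np.random.default_rng(config.seed)

    truth = None
    if config.phantom is not None:
        with _Stage("simulate", seed=config.seed):
            pcfg = ph.PhantomConfig(**{**config.phantom, "rng_seed": config.seed})
            # separate training phantom so evaluation is held out
            train_cfg = ph.PhantomConfig(
                **{**config.phantom, "rng_seed": config.seed + 1}
            )
            t1w, t2w, truth = ph.generate_phantom(pcfg)
            tr1, tr2, truth_train = ph.generate_phantom(train_cfg)
            geometry = geometry_from_truth(truth)
            for vol, name in ((t1w, "t1w"), (t2w, "t2w")):
                artifacts.append(save_volume(vol, out_dir / f"{name}.nii.gz"))
            artifacts.append(ph.save_truth_paths(truth, out_dir / "truth_paths.json"))
            artifacts.append(save_geometry(geometry, out_dir / "geometry.json"))
    else:
        with _Stage("load"):
            t1w = load_volume(config.volumes["t1w"], "t1w")
            t2w = load_volume(config.volumes["t2w"], "t2w")
            geometry = load_geometry(config.seeds_file)

    models = {}
    if config.checkpoints:
        with _Stage("load-checkpoints"):
            for mod, p in config.checkpoints.items():
                models[mod] = load_checkpoint(p)
    elif config.phantom is not None:
        with _Stage("train", **{k: v for k, v in config.unet.items()}):
            labels = ph.rasterize_truth_mask(
                truth_train, train_cfg.shape, radius=config.eval["mask_radius"]
            )
            for mod, vol in (("t1w", tr1), ("t2w", tr2)):
                rng = np.random.default_rng(rng_root.integers(2**31))
                pats = sample_training_patches(
                    normalize(vol),
                    labels,
                    config.train["patch_size"],
                    config.train["n_patches"],
                    rng,
                )
                seg = UNetSegmenter(
                    widths=tuple(config.unet["widths"]),
                    learning_rate=config.unet["learning_rate"],
                    epochs=config.unet["epochs"],
                    batch_size=config.unet["batch_size"],
                    smooth_eps=config.unet["smooth_eps"],
                    augment=config.unet["augment"],
                    rng_seed=config.seed,
                    modality=mod,
                )
                seg.fit(pats)
                models[mod] = seg
                artifacts.append(save_checkpoint(seg, out_dir / f"unet_{mod}.npz"))
                (out_dir / f"train_log_{mod}.json").write_text(
                    json.dumps(seg.loss_log_, indent=1)
                )
                artifacts.append(out_dir / f"train_log_{mod}.json")

    with _Stage("predict"):
        masks = {}
        ps = int(config.train["patch_size"])
        for mod, vol in (("t1w", t1w), ("t2w", t2w)):
            stack = models[mod].predict_mask_stack(
                normalize(vol), patch_size=ps, overlap=ps // 2
            )
            masks[mod] = binarize(stack)
            mvol = ImageVolume(
                masks[mod].astype(np.uint8), vol.spacing_mm, modality=mod
            )
            artifacts.append(save_volume(mvol, out_dir / f"mask_{mod}.nii.gz"))

    with _Stage("reconstruct", **config.post):
        rec = reconstruct(t1w, t2w, masks["t1w"], masks["t2w"], geometry, **config.post)
        artifacts.append(save_paths_json(rec, out_dir / "paths.json"))
        csv_path = out_dir / "paths.csv"
        paths_to_dataframe(rec).to_csv(csv_path, index=False)
        artifacts.append(csv_path)

    report = None
    if truth is not None:
        with _Stage("evaluate", **config.eval):
            report = evaluate_paths(
                rec,
                truth,
                t1w.spacing_mm,
                shape=t1w.shape,
                mask_radius=config.eval["mask_radius"],
                interval_mm=config.eval["interval_mm"],
            )
            files = export_report(report, out_dir, config.eval["bin_width_mm"])
            artifacts.extend(files.values())
    else:
        log.info("no ground truth available; evaluation skipped")

    manifest = {
        "config": config.raw,
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in artifacts},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
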