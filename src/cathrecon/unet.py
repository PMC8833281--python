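"""2D encoder-decoder segmentation network (U-net) for catheter probability maps.

One model is trained per MR contrast (T1W and T2W independently), on square
patches, optimizing soft Dice.  The architecture is the classic symmetric
U-net: each encoder level applies two 3x3 convolutions + ReLU then 2x2 max
pooling; each decoder level applies a 2x2 stride-2 transposed convolution +
ReLU, concatenates the matching encoder feature map, and applies two 3x3
convolutions + ReLU; a final 1x1 convolution + sigmoid emits a per-pixel
catheter probability.  With a 128x128 input and five levels the bottleneck
feature maps are 8x8.

The default configuration mirrors the clinical-scale setup (widths
64..1024, learning rate 1e-5, 100 epochs, batch size 8); desk-scale runs
pass reduced widths and epochs explicitly.  Training is deterministic given
``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn import dice_loss
from .patches import Patch, random_augment, tile_offsets
from .volume import ImageVolume

__all__ = [
    "UNetConfig",
    "build_unet",
    "dice_loss",
    "UNetSegmenter",
    "train",
    "predict_mask_stack",
    "binarize",
    "ProbabilityMaskStack",
    "save_checkpoint",
    "load_checkpoint",
]

#: Channel widths of the original full-scale architecture.
CANONICAL_WIDTHS = (64, 128, 256, 512, 1024)


@dataclass
class UNetConfig:
    """Architecture and training hyperparameters.

    ``widths`` are the encoder channel counts per level (strictly
    increasing); the decoder mirrors them.  ``smooth_eps`` is the Dice
    smoothing constant keeping the loss defined when both prediction and
    truth are empty.
    """

    widths: tuple[int, ...] = CANONICAL_WIDTHS
    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 8
    smooth_eps: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.widths) < 2:
            raise ValueError("need at least 2 levels (len(widths) >= 2)")
        if any(b <= a for a, b in zip(self.widths, self.widths[1:])):
            raise ValueError(f"widths must strictly increase down the encoder: {self.widths}")
        if self.learning_rate <= 0 or self.smooth_eps <= 0:
            raise ValueError("learning_rate and smooth_eps must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def build_unet(config: UNetConfig, input_size: int = 128) -> dict:
    """Symbolic model descriptor: layer list, shapes, and parameter count.

    The trainable-parameter count is the layer-by-layer sum of
    ``kernel_area * c_in * c_out + c_out`` over every convolution, transposed
    convolution, and the 1x1 head; it equals the array sizes a fitted
    :class:`UNetSegmenter` allocates.
    """
    config.validate()
    widths = config.widths
    n_levels = len(widths)
    layers: list[dict] = []
    size = input_size

    def conv(name: str, k: int, c_in: int, c_out: int, sz: int) -> None:
        layers.append(
            {
                "name": name,
                "kernel": f"{k}x{k}",
                "c_in": c_in,
                "c_out": c_out,
                "n_params": k * k * c_in * c_out + c_out,
                "output_size": sz,
            }
        )

    c_in = 1
    for i, c in enumerate(widths):
        conv(f"enc{i}_conv_a", 3, c_in, c, size)
        conv(f"enc{i}_conv_b", 3, c, c, size)
        c_in = c
        if i < n_levels - 1:
            size //= 2
            layers.append(
                {"name": f"pool{i}", "kernel": "2x2", "c_in": c, "c_out": c,
                 "n_params": 0, "output_size": size}
            )
    bottleneck_size = size
    for i in range(n_levels - 2, -1, -1):
        size *= 2
        conv(f"dec{i}_upconv", 2, widths[i + 1], widths[i], size)
        conv(f"dec{i}_conv_a", 3, 2 * widths[i], widths[i], size)
        conv(f"dec{i}_conv_b", 3, widths[i], widths[i], size)
    conv("head", 1, widths[0], 1, size)

    return {
        "widths": list(widths),
        "n_levels": n_levels,
        "input_size": input_size,
        "bottleneck_size": bottleneck_size,
        "layers": layers,
        "n_parameters": int(sum(l["n_params"] for l in layers)),
    }


class _UNet:
    """The live network: layer objects, forward pass, and backprop."""

    def __init__(self, widths: tuple[int, ...], rng: np.random.Generator):
        self.widths = tuple(widths)
        L = len(widths)
        self.enc: list[tuple[nn.Conv3x3, nn.Conv3x3]] = []
        c_in = 1
        for c in widths:
            self.enc.append((nn.Conv3x3(c_in, c, rng), nn.Conv3x3(c, c, rng)))
            c_in = c
        self.pools = [nn.MaxPool2() for _ in range(L - 1)]
        self.dec: list[tuple[nn.ConvTranspose2x2, nn.Conv3x3, nn.Conv3x3]] = []
        for i in range(L - 2, -1, -1):
            self.dec.append(
                (
                    nn.ConvTranspose2x2(widths[i + 1], widths[i], rng),
                    nn.Conv3x3(2 * widths[i], widths[i], rng),
                    nn.Conv3x3(widths[i], widths[i], rng),
                )
            )
        self.head = nn.Conv1x1(widths[0], 1, rng, sigmoid=True)

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for a, b in self.enc:
            out += [a, b]
        for up, a, b in self.dec:
            out += [up, a, b]
        out.append(self.head)
        return out

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (n, h, w, 1) float32 -> probabilities (n, h, w, 1)."""
        L = len(self.widths)
        div = 2 ** (L - 1)
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(
                f"input spatial size {x.shape[1:3]} must be divisible by {div} "
                f"for {L} levels"
            )
        skips = []
        for i, (a, b) in enumerate(self.enc):
            x = b.forward(a.forward(x))
            if i < L - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        for (up, a, b), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=-1)
            x = b.forward(a.forward(x))
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> None:
        L = len(self.widths)
        g = self.head.backward(g)
        skip_grads: list[np.ndarray] = []
        # decoder ran shallowest-last, so walk it in reverse
        for up, a, b in reversed(self.dec):
            g = a.backward(b.backward(g))
            c = up.c_out
            skip_grads.append(g[..., :c])
            g = up.backward(np.ascontiguousarray(g[..., c:]))
        # g now flows into the bottleneck encoder level; skip_grads[i] is the
        # gradient reaching encoder level i through its skip connection
        for i in range(L - 1, -1, -1):
            a, b = self.enc[i]
            if i < L - 1:
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            g = a.backward(b.backward(g))


@dataclass
class ProbabilityMaskStack:
    """Per-slice probability maps in [0, 1], aligned with the source volume."""

    data: np.ndarray  # (rows, cols, slices) float
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask stack must be 3D, got shape {self.data.shape}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around the patch-trained U-net.

    Parameters mirror :class:`UNetConfig`.  ``fit`` consumes either a list
    of :class:`~cathrecon.patches.Patch` or an ``(n, size, size)`` array with
    matching binary labels in ``y``.  Fitted attributes carry the trailing
    underscore: ``net_``, ``n_parameters_``, ``loss_log_``.

    Examples
    --------
    >>> seg = UNetSegmenter(widths=(4, 8), epochs=2, learning_rate=1e-3,
    ...                     rng_seed=0)
    >>> seg.fit(train_patches)                          # doctest: +SKIP
    >>> stack = seg.predict_mask_stack(t1w_normalized)  # doctest: +SKIP
    """

    def __init__(
        self,
        widths: tuple[int, ...] = CANONICAL_WIDTHS,
        learning_rate: float = 1e-5,
        epochs: int = 100,
        batch_size: int = 8,
        smooth_eps: float = 1.0,
        augment: bool = False,
        rng_seed: int = 0,
        modality: str | None = None,
    ):
        self.widths = widths
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.smooth_eps = smooth_eps
        self.augment = augment
        self.rng_seed = rng_seed
        self.modality = modality

    # -- internal helpers -------------------------------------------------
    def _config(self) -> UNetConfig:
        return UNetConfig(
            widths=tuple(self.widths),
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            smooth_eps=self.smooth_eps,
            rng_seed=self.rng_seed,
        )

    @staticmethod
    def _as_arrays(X, y=None) -> tuple[np.ndarray, np.ndarray | None, list[Patch] | None]:
        if len(X) and isinstance(X[0], Patch):
            px = np.stack([p.pixels for p in X]).astype(np.float32)
            lb = np.stack([p.label for p in X]).astype(np.float32)
            return px, lb, list(X)
        px = np.asarray(X, dtype=np.float32)
        lb = None if y is None else np.asarray(y, dtype=np.float32)
        return px, lb, None

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y=None, validation=None):
        """Train on patches; logs per-epoch train loss and validation Dice."""
        cfg = self._config()
        cfg.validate()
        px, lb, patch_list = self._as_arrays(X, y)
        if px.shape[0] == 0:
            raise ValueError("cannot train on an empty patch set")
        if lb is None:
            raise ValueError("labels required: pass Patch objects or y=")
        val = None
        if validation is not None:
            vx, vy, _ = self._as_arrays(validation)
            val = (vx[..., None], vy[..., None])

        rng = np.random.default_rng(cfg.rng_seed)
        net = _UNet(cfg.widths, rng)
        opt = nn.Adam(net.layers(), lr=cfg.learning_rate)
        n = px.shape[0]
        log: list[dict] = []
        for epoch in range(cfg.epochs):
            if self.augment and patch_list is not None:
                aug = [random_augment(p, rng) for p in patch_list]
                ex = np.stack([p.pixels for p in aug]).astype(np.float32)
                ey = np.stack([p.label for p in aug]).astype(np.float32)
            else:
                ex, ey = px, lb
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                xb = ex[idx][..., None]
                yb = ey[idx][..., None]
                prob = net.forward(xb)
                loss, grad = dice_loss(prob, yb, cfg.smooth_eps, with_grad=True)
                net.backward(grad)
                opt.step()
                losses.append(loss)
            rec = {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_dice": float(1.0 - np.mean(losses)),
            }
            if val is not None:
                vp = self._forward_chunks(net, val[0])
                rec["val_dice"] = 1.0 - dice_loss(vp, val[1], cfg.smooth_eps)
            log.append(rec)

        self.net_ = net
        self.n_parameters_ = net.n_params()
        self.loss_log_ = log
        self.patch_size_ = int(px.shape[1])
        return self

    @staticmethod
    def _forward_chunks(net: _UNet, x: np.ndarray, chunk: int = 16) -> np.ndarray:
        return np.concatenate([net.forward(x[i : i + chunk]) for i in range(0, len(x), chunk)])

    def predict_proba_patches(self, X) -> np.ndarray:
        """Per-pixel catheter probabilities for an (n, size, size) array."""
        self._check_fitted()
        px = np.asarray(X, dtype=np.float32)
        return self._forward_chunks(self.net_, px[..., None])[..., 0]

    def predict_mask_stack(
        self, volume: ImageVolume, patch_size: int = 64, overlap: int = 32
    ) -> ProbabilityMaskStack:
        """Tiled sliding-window inference over every slice of a volume."""
        self._check_fitted()
        return predict_mask_stack(self, volume, patch_size=patch_size, overlap=overlap)

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("UNetSegmenter is not fitted; call fit() first")


def train(
    patches: list[Patch],
    config: UNetConfig,
    validation: list[Patch] | None = None,
    modality: str | None = None,
) -> tuple[UNetSegmenter, list[dict]]:
    """Functional wrapper: train a segmenter from a config, return it + log."""
    seg = UNetSegmenter(
        widths=tuple(config.widths),
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        smooth_eps=config.smooth_eps,
        rng_seed=config.rng_seed,
        modality=modality,
    )
    seg.fit(patches, validation=validation)
    return seg, seg.loss_log_


def predict_mask_stack(
    model, volume: ImageVolume, patch_size: int = 64, overlap: int = 32
) -> ProbabilityMaskStack:
    """Stitch overlapping patch predictions into full-slice probability maps.

    Each slice is tiled with windows of ``patch_size`` advancing by
    ``patch_size - overlap``; overlapping predictions are averaged, so any
    stitched value stays within the range of its contributing patch outputs.
    ``model`` needs only a ``predict_proba_patches`` method, which makes the
    stitching testable with stub predictors.
    """
    rows, cols, n_slices = volume.shape
    stride = patch_size - overlap
    if stride < 1:
        raise ValueError(f"overlap {overlap} must be smaller than patch size {patch_size}")
    r_offs = tile_offsets(rows, patch_size, stride)
    c_offs = tile_offsets(cols, patch_size, stride)
    acc = np.zeros(volume.shape, dtype=np.float64)
    cnt = np.zeros(volume.shape, dtype=np.float64)
    windows = [(s, r0, c0) for s in range(n_slices) for r0 in r_offs for c0 in c_offs]
    batch = np.empty((len(windows), patch_size, patch_size), dtype=np.float32)
    for k, (s, r0, c0) in enumerate(windows):
        batch[k] = volume.data[r0 : r0 + patch_size, c0 : c0 + patch_size, s]
    probs = model.predict_proba_patches(batch)
    for k, (s, r0, c0) in enumerate(windows):
        acc[r0 : r0 + patch_size, c0 : c0 + patch_size, s] += probs[k]
        cnt[r0 : r0 + patch_size, c0 : c0 + patch_size, s] += 1.0
    return ProbabilityMaskStack(acc / cnt, modality=volume.modality)


def binarize(mask: ProbabilityMaskStack | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities: strictly greater than ``threshold`` is catheter."""
    data = mask.data if isinstance(mask, ProbabilityMaskStack) else np.asarray(mask)
    return data > threshold


def save_checkpoint(model: UNetSegmenter, path: str | Path) -> Path:
    """Save weights (.npz) plus a JSON sidecar with the configuration."""
    model._check_fitted()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {
        f"p{i:04d}": p
        for i, p in enumerate(q for l in model.net_.layers() for q in l.params)
    }
    np.savez(path, **arrays)
    sidecar = asdict(model._config())
    sidecar["modality"] = model.modality
    sidecar["patch_size"] = getattr(model, "patch_size_", None)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_checkpoint(path: str | Path) -> UNetSegmenter:
    path = Path(path)
    npz = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    meta = json.loads(Path(str(path) + ".json").read_text())
    seg = UNetSegmenter(
        widths=tuple(meta["widths"]),
        learning_rate=meta["learning_rate"],
        epochs=meta["epochs"],
        batch_size=meta["batch_size"],
        smooth_eps=meta["smooth_eps"],
        rng_seed=meta["rng_seed"],
        modality=meta.get("modality"),
    )
    net = _UNet(tuple(meta["widths"]), np.random.default_rng(0))
    arrs = np.load(npz if npz.exists() else path)
    flat = [q for l in net.layers() for q in l.params]
    for i, p in enumerate(flat):
        p[...] = arrs[f"p{i:04d}"]
    seg.net_ = net
    seg.n_parameters_ = net.n_params()
    seg.loss_log_ = []
    seg.patch_size_ = meta.get("patch_size")
    return seg
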