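"""SheepVGG-Lite: a shallow VGG-style CNN used as a deep-feature extractor.

Architecture (fixed):

    input 100x100x3
      -> conv 3x3, 3->16, stride 1, pad 1, ReLU -> maxpool 2x2   (50x50x16)
      -> conv 3x3, 16->32, stride 1, pad 1, ReLU -> maxpool 2x2  (25x25x32)
      -> flatten (20,000)
      -> FC1: 20,000 -> 128, ReLU     (deep-feature tap "FC1")
      -> FC2: 128 -> 3 class logits   (deep-feature tap "FC2")

2,565,603 trainable float32 parameters (~10.26 MB serialized).  Training
uses Adam with a per-epoch linear learning-rate ramp from 1e-3 to 1e-4 over
50 epochs, batch size 32, cross-entropy loss, and a stratified 25%
validation split; the returned weights are the checkpoint with the best
validation weighted F1.  Everything is plain numpy: im2col convolutions
with hand-written backward passes, so training is exactly reproducible from
the seed on a single CPU.

EigenCAM localization projects the final pooled convolutional activations
onto their first right singular vector and upsamples the (sign-corrected,
non-negatively clamped) projection to the input resolution.
"""

from __future__ import annotations

import copy
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

from .audio_io import LABELS
from .spectrograms import IMAGE_SIZE, SpectrogramImage, bilinear_resize

_MAGIC = b"FOLDEARCNN1\n"
PARAM_ORDER = ("conv1_w", "conv1_b", "conv2_w", "conv2_b", "fc1_w", "fc1_b", "fc2_w", "fc2_b")
PARAM_SHAPES = {
    "conv1_w": (16, 3, 3, 3),
    "conv1_b": (16,),
    "conv2_w": (32, 16, 3, 3),
    "conv2_b": (32,),
    "fc1_w": (128, 20_000),
    "fc1_b": (128,),
    "fc2_w": (3, 128),
    "fc2_b": (3,),
}
N_PARAMETERS = sum(int(np.prod(s)) for s in PARAM_SHAPES.values())  # 2,565,603
FC1_WIDTH = 128
N_CLASSES = 3


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr_start: float = 1e-3
    lr_end: float = 1e-4
    val_fraction: float = 0.25
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def learning_rate(self, epoch: int) -> float:
        """Linear per-epoch interpolation; epoch is 1-based."""
        if self.epochs == 1:
            return self.lr_start
        frac = (epoch - 1) / (self.epochs - 1)
        return self.lr_start + frac * (self.lr_end - self.lr_start)


@dataclass
class DeepFeatureMatrix:
    values: np.ndarray  # (n, 128) for FC1, (n, 3) for FC2
    layer: str
    source_ids: Optional[list[str]] = None


# ---------------------------------------------------------------- layers


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 / stride 1 / pad 1 convolution via im2col.  x: (N, C, H, W)."""
    n, c, h, wd = x.shape
    oc = w.shape[0]
    pad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(pad, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    out = cols @ w.reshape(oc, c * 9).T + b
    out = out.reshape(n, h, wd, oc).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    n, c, h, wd = x_shape
    oc = w.shape[0]
    dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * wd, oc)
    dw = (dflat.T @ cols).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcols = (dflat @ w.reshape(oc, c * 9)).reshape(n, h, wd, c, 3, 3)
    dpad = np.zeros((n, c, h + 2, wd + 2), dtype=dout.dtype)
    for di in range(3):
        for dj in range(3):
            dpad[:, :, di : di + h, dj : dj + wd] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dpad[:, :, 1:-1, 1:-1], dw, db


def _pool_forward(x: np.ndarray):
    """2x2 max pooling, stride 2; gradient routed to the first argmax."""
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    arg = r.argmax(axis=-1)
    out = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(out), arg


def _pool_backward(dout: np.ndarray, arg: np.ndarray, x_shape):
    n, c, h, w = x_shape
    dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dr, arg[..., None], dout[..., None], axis=-1)
    return (
        dr.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------- model


class SheepVGGLite:
    """The shallow CNN; parameters live in a name -> float32 ndarray dict."""

    def __init__(self, seed: int = 0, dtype=np.float32, classes: tuple[str, ...] = LABELS):
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self.classes = tuple(classes)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for name in PARAM_ORDER:
            shape = PARAM_SHAPES[name]
            if name.endswith("_b"):
                self.params[name] = np.zeros(shape, dtype=self.dtype)
            else:
                fan_in = int(np.prod(shape[1:]))
                std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU
                self.params[name] = (rng.standard_normal(shape) * std).astype(self.dtype)

    # -- forward -----------------------------------------------------

    def num_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def serialized_size_bytes(self) -> int:
        """Raw 32-bit parameter payload, excluding the small JSON header."""
        return 4 * self.num_parameters()

    def forward(self, x: np.ndarray, cache: bool = False):
        """x: (N, 3, 100, 100) in [0, 1].  Returns activation dict."""
        p = self.params
        x = np.ascontiguousarray(x, dtype=self.dtype)
        z1, cols1 = _conv_forward(x, p["conv1_w"], p["conv1_b"])
        a1 = np.maximum(z1, 0)
        p1, arg1 = _pool_forward(a1)
        z2, cols2 = _conv_forward(p1, p["conv2_w"], p["conv2_b"])
        a2 = np.maximum(z2, 0)
        p2, arg2 = _pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ p["fc1_w"].T + p["fc1_b"]
        fc1 = np.maximum(z3, 0)
        logits = fc1 @ p["fc2_w"].T + p["fc2_b"]
        acts = {"fc1": fc1, "fc2": logits, "conv2_pooled": p2}
        if cache:
            acts.update(
                x=x, z1=z1, cols1=cols1, a1=a1, arg1=arg1, p1=p1,
                z2=z2, cols2=cols2, a2=a2, arg2=arg2, flat=flat, z3=z3,
            )
        return acts

    def predict_logits(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = _to_nchw(images, self.dtype)
        out = [self.forward(x[i : i + batch_size])["fc2"] for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def predict_labels(self, images: np.ndarray) -> np.ndarray:
        idx = self.predict_logits(images).argmax(axis=1)
        return np.array([self.classes[i] for i in idx])

    # -- backward ----------------------------------------------------

    def backward(self, acts: dict, y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        """Cross-entropy loss and gradients for integer labels y."""
        p = self.params
        n = y.size
        probs = _softmax(acts["fc2"].astype(np.float64)).astype(self.dtype)
        loss = float(-np.mean(np.log(np.maximum(probs[np.arange(n), y], 1e-12))))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        grads["fc2_w"] = dlogits.T @ acts["fc1"]
        grads["fc2_b"] = dlogits.sum(axis=0)
        dfc1 = (dlogits @ p["fc2_w"]) * (acts["z3"] > 0)
        grads["fc1_w"] = dfc1.T @ acts["flat"]
        grads["fc1_b"] = dfc1.sum(axis=0)
        dflat = dfc1 @ p["fc1_w"]
        dp2 = dflat.reshape(acts["conv2_pooled"].shape)
        da2 = _pool_backward(dp2, acts["arg2"], acts["a2"].shape)
        dz2 = da2 * (acts["z2"] > 0)
        dp1, grads["conv2_w"], grads["conv2_b"] = _conv_backward(
            dz2, acts["cols2"], p["conv2_w"], acts["p1"].shape
        )
        da1 = _pool_backward(dp1, acts["arg1"], acts["a1"].shape)
        dz1 = da1 * (acts["z1"] > 0)
        _, grads["conv1_w"], grads["conv1_b"] = _conv_backward(
            dz1, acts["cols1"], p["conv1_w"], acts["x"].shape
        )
        return loss, grads

    # -- persistence -------------------------------------------------

    def save(self, path: Path | str, extra_meta: Optional[dict] = None) -> None:
        """Single-file binary: magic, JSON header, raw float32 LE params."""
        header = {
            "classes": list(self.classes),
            "seed": self.seed,
            "param_order": list(PARAM_ORDER),
            "param_shapes": {k: list(v) for k, v in PARAM_SHAPES.items()},
        }
        if extra_meta:
            header["meta"] = extra_meta
        blob = json.dumps(header, sort_keys=True).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<I", len(blob)))
            fh.write(blob)
            for name in PARAM_ORDER:
                fh.write(self.params[name].astype("<f4").tobytes())

    @classmethod
    def load(cls, path: Path | str) -> "SheepVGGLite":
        with open(path, "rb") as fh:
            if fh.read(len(_MAGIC)) != _MAGIC:
                raise ValueError(f"{path} is not a SheepVGG-Lite model file")
            (hlen,) = struct.unpack("<I", fh.read(4))
            header = json.loads(fh.read(hlen))
            model = cls(seed=header["seed"], classes=tuple(header["classes"]))
            for name in header["param_order"]:
                shape = tuple(header["param_shapes"][name])
                count = int(np.prod(shape))
                buf = fh.read(4 * count)
                model.params[name] = np.frombuffer(buf, dtype="<f4").reshape(shape).copy()
        return model


def _to_nchw(images, dtype) -> np.ndarray:
    """Accept (N, 100, 100, 3) arrays or SpectrogramImage lists."""
    if isinstance(images, np.ndarray):
        arr = images
    else:
        arr = np.stack([im.pixels if isinstance(im, SpectrogramImage) else im for im in images])
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[1:] != (IMAGE_SIZE, IMAGE_SIZE, 3):
        raise ValueError(f"expected (n, {IMAGE_SIZE}, {IMAGE_SIZE}, 3) images, got {arr.shape}")
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2), dtype=dtype)


def encode_labels(labels: Iterable[str], classes: tuple[str, ...] = LABELS) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lut[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; known classes: {classes}") from exc


def build_model(seed: int = 0) -> SheepVGGLite:
    """Freshly initialized SheepVGG-Lite with seeded He-normal weights."""
    return SheepVGGLite(seed=seed)


def train(
    model: SheepVGGLite,
    images,
    labels: Iterable[str],
    config: TrainConfig = TrainConfig(),
) -> tuple[SheepVGGLite, list[dict]]:
    """Train in place; returns (model-with-best-weights, per-epoch history).

    The incoming set is split 75/25 (stratified, seeded) into train and
    validation; the checkpoint with the highest validation weighted F1 is
    restored at the end (earliest epoch wins ties).  History records train
    loss, validation loss, validation weighted F1 and the learning rate.
    """
    x = _to_nchw(images, model.dtype)
    y = encode_labels(labels, model.classes)
    if np.unique(y).size < 2:
        raise ValueError("training requires at least 2 classes")
    idx_tr, idx_va = train_test_split(
        np.arange(y.size), test_size=config.val_fraction, stratify=y, random_state=config.seed
    )
    if np.unique(y[idx_va]).size < np.unique(y).size:
        raise ValueError("a class is absent from the validation split; add data or reseed")
    x_tr, y_tr, x_va, y_va = x[idx_tr], y[idx_tr], x[idx_va], y[idx_va]

    rng = np.random.default_rng(config.seed)
    m = {k: np.zeros_like(v, dtype=np.float64) for k, v in model.params.items()}
    v = {k: np.zeros_like(p, dtype=np.float64) for k, p in model.params.items()}
    step = 0
    history: list[dict] = []
    best_f1, best_params = -1.0, None

    for epoch in range(1, config.epochs + 1):
        lr = config.learning_rate(epoch)
        order = rng.permutation(y_tr.size)
        total_loss = 0.0
        for start in range(0, y_tr.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            acts = model.forward(x_tr[batch], cache=True)
            loss, grads = model.backward(acts, y_tr[batch])
            total_loss += loss * batch.size
            step += 1
            for name, g in grads.items():
                g64 = g.astype(np.float64)
                m[name] = config.beta1 * m[name] + (1 - config.beta1) * g64
                v[name] = config.beta2 * v[name] + (1 - config.beta2) * g64**2
                mhat = m[name] / (1 - config.beta1**step)
                vhat = v[name] / (1 - config.beta2**step)
                upd = lr * mhat / (np.sqrt(vhat) + config.eps)
                model.params[name] = (model.params[name].astype(np.float64) - upd).astype(
                    model.dtype
                )
        va_acts = model.forward(x_va)
        va_probs = _softmax(va_acts["fc2"].astype(np.float64))
        va_loss = float(-np.mean(np.log(np.maximum(va_probs[np.arange(y_va.size), y_va], 1e-12))))
        va_f1 = float(
            f1_score(y_va, va_acts["fc2"].argmax(axis=1), average="weighted", zero_division=0)
        )
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": total_loss / y_tr.size,
                "val_loss": va_loss,
                "val_f1": va_f1,
            }
        )
        if va_f1 > best_f1:
            best_f1 = va_f1
            best_params = copy.deepcopy(model.params)
    if best_params is not None:
        model.params = best_params
    return model, history


def extract_deep_features(
    model: SheepVGGLite, images, layer: str, source_ids: Optional[list[str]] = None
) -> DeepFeatureMatrix:
    """Per-image activations of a named fully connected tap.

    FC1 rows are the 128 post-ReLU activations; FC2 rows are the 3
    pre-softmax class logits.  Deterministic: repeated calls are identical.
    """
    if layer not in ("FC1", "FC2"):
        raise ValueError(f"unknown layer {layer!r}; valid taps: FC1, FC2")
    x = _to_nchw(images, model.dtype)
    outs = []
    for i in range(0, x.shape[0], 64):
        acts = model.forward(x[i : i + 64])
        outs.append(acts["fc1"] if layer == "FC1" else acts["fc2"])
    return DeepFeatureMatrix(
        values=np.concatenate(outs, axis=0).astype(np.float64), layer=layer, source_ids=source_ids
    )


def eigencam(model: SheepVGGLite, image) -> np.ndarray:
    """EigenCAM heatmap (100x100 in [0, 1]) for one input image.

    The pooled post-ReLU activations of the last convolutional block
    (25x25x32) are reshaped to (625, 32) and projected onto their first
    right singular vector; the sign is chosen to make the projection's
    maximum positive, negatives are clamped, and the 25x25 map is
    bilinearly upsampled and min-max normalized.
    """
    x = _to_nchw(image, model.dtype)
    acts = model.forward(x[:1])
    a = acts["conv2_pooled"][0].astype(np.float64)  # (32, 25, 25)
    mat = a.transpose(1, 2, 0).reshape(-1, a.shape[0])  # (625, 32)
    if not mat.any():
        return np.zeros((IMAGE_SIZE, IMAGE_SIZE))
    _, _, vt = np.linalg.svd(mat, full_matrices=False)
    proj = mat @ vt[0]
    if -proj.min() > proj.max():
        proj = -proj
    heat = np.maximum(proj.reshape(25, 25), 0.0)
    up = np.maximum(bilinear_resize(heat, IMAGE_SIZE, IMAGE_SIZE), 0.0)
    peak = up.max()
    return up / peak if peak > 0 else up
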