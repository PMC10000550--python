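"""CNN landmark regressor for one photographic view.

Architecture: six stride-1 convolutions — (32,5×5), (32,3×3), (64,3×3),
(64,3×3), (128,3×3), (256,3×3) — each followed by batch normalization and
ReLU, with 2×2/2 max pooling after conv blocks 2, 4 and 6 (VGG-style
pairing), then three fully connected layers (1024, 512, 2·K) whose final
linear outputs are the (u, v) coordinates of the view's K landmarks,
normalized by the input size.  Training minimizes mean squared error on the
normalized coordinates with Adam (default learning rate 0.001).

One model is trained per view; the three views share the architecture and
differ only in K.  Images are preprocessed to grayscale ``input_size``
squares (green-screen removal, aspect-preserving resize + pad), and the
affine pixel map is retained so predictions are reported in original image
pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from PIL import Image

from . import nn
from .landmarks import Point2D, View, ViewAnnotation, mirror_id, visibility_set

__all__ = [
    "DetectorConfig",
    "AffineMap",
    "TrainingHistory",
    "Detector",
    "preprocess",
    "augment",
    "build_model",
    "train",
    "predict",
]

DEFAULT_CONV_SPECS: tuple[tuple[int, int, int], ...] = (
    (32, 5, 1),
    (32, 3, 1),
    (64, 3, 1),
    (64, 3, 1),
    (128, 3, 1),
    (256, 3, 1),
)


class DetectorConfigError(ValueError):
    pass


@dataclass
class DetectorConfig:
    view: str = "frontal"
    input_size: int = 416
    conv_specs: tuple = DEFAULT_CONV_SPECS
    pool_after: tuple = (2, 4, 6)  # 1-based conv-block indices
    fc_sizes: tuple = (1024, 512)
    landmark_ids: tuple = ()
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    val_fraction: float = 0.2
    seed: int = 0
    augment: bool = True
    rot_deg: float = 10.0
    scale_range: tuple = (0.9, 1.1)
    flip_prob: float = 0.5
    remove_green: bool = True
    warm_start_bias: bool = True
    zero_init_head: bool = False
    warmup_steps: int = 0
    lr_schedule: str = "constant"  # or "cosine" (decay to 0 after warmup)

    def __post_init__(self) -> None:
        if not self.landmark_ids:
            self.landmark_ids = tuple(sorted(visibility_set(self.view)))
        if len(set(self.landmark_ids)) != len(self.landmark_ids):
            raise DetectorConfigError("duplicate landmark ids in config")
        if self.input_size % 8 != 0 or self.input_size < 32:
            raise DetectorConfigError(f"input_size must be a multiple of 8 and >= 32, got {self.input_size}")
        if any(i > len(self.conv_specs) for i in self.pool_after):
            raise DetectorConfigError("pool_after index exceeds number of conv blocks")

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_ids)


@dataclass
class AffineMap:
    """Original-pixel → model-pixel map: model = orig * scale + offset."""

    scale: float
    offset: tuple[float, float]

    def to_model(self, uv: np.ndarray) -> np.ndarray:
        return np.asarray(uv, dtype=float) * self.scale + np.asarray(self.offset)

    def to_original(self, uv: np.ndarray) -> np.ndarray:
        return (np.asarray(uv, dtype=float) - np.asarray(self.offset)) / self.scale


def _to_array(image) -> np.ndarray:
    if isinstance(image, (str,)) or hasattr(image, "__fspath__"):
        try:
            image = Image.open(image)
        except OSError as exc:
            raise OSError(f"cannot read image {image}: {exc}") from exc
    if isinstance(image, Image.Image):
        image = np.asarray(image)
    return np.asarray(image)


def preprocess(image, config: DetectorConfig | int, remove_green: bool | None = None) -> tuple[np.ndarray, AffineMap]:
    """Normalize one photograph to the model input.

    Green background pixels (G dominating R and B) are blanked to 0, the
    image is converted to grayscale, resized preserving aspect ratio and
    centre-padded to ``input_size`` × ``input_size``, and scaled to [0, 1].
    Returns the image and the affine original→model pixel map.
    """
    if isinstance(config, DetectorConfig):
        size = config.input_size
        if remove_green is None:
            remove_green = config.remove_green
    else:
        size = int(config)
        if remove_green is None:
            remove_green = True
    arr = _to_array(image)
    if arr.ndim == 3:
        rgb = arr.astype(np.float32)
        if remove_green:
            g_dom = (rgb[..., 1] > rgb[..., 0] + 25) & (rgb[..., 1] > rgb[..., 2] + 25)
        gray = rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114
        if remove_green:
            gray[g_dom] = 0.0
    else:
        gray = arr.astype(np.float32)
    if gray.max() > 1.5:  # 8-bit input
        gray = gray / 255.0
    h, w = gray.shape
    scale = min(size / w, size / h)
    nw, nh = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    resized = np.asarray(Image.fromarray(gray, mode="F").resize((nw, nh), Image.BILINEAR))
    out = np.zeros((size, size), dtype=np.float32)
    ox, oy = (size - nw) // 2, (size - nh) // 2
    out[oy : oy + nh, ox : ox + nw] = resized
    # the map sends an original pixel centre to its resized location
    return out, AffineMap(scale=scale, offset=(float(ox), float(oy)))


def augment(
    image: np.ndarray,
    points: dict[str, Point2D] | dict[str, tuple[float, float]],
    config: DetectorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, Point2D]]:
    """Random rotation/scale (and horizontal flip off-lateral) of an
    image/annotation pair, both transformed with the same affine map.

    Flips swap the left/right landmark identities; the lateral (profile) view
    is never flipped, since its mirror would show the other body side.
    Deterministic under the supplied generator.
    """
    h, w = image.shape[:2]
    theta = math.radians(rng.uniform(-config.rot_deg, config.rot_deg)) if config.rot_deg > 0 else 0.0
    lo, hi = config.scale_range
    s = rng.uniform(lo, hi) if hi > lo else lo
    flip = View(config.view) is not View.LATERAL and rng.random() < config.flip_prob

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cos, sin = math.cos(theta), math.sin(theta)
    # forward map: p' = C + F (p - C); flip applied first
    fx = -1.0 if flip else 1.0
    F = np.array([[s * cos * fx, -s * sin], [s * sin * fx, s * cos]])
    if theta == 0.0 and s == 1.0 and not flip:
        return image, {pid: Point2D(*p) for pid, p in points.items()}

    Finv = np.linalg.inv(F)
    # PIL affine takes the output→input map
    a, b = Finv[0]
    d, e = Finv[1]
    c = cx - a * cx - b * cy
    f0 = cy - d * cx - e * cy
    pil = Image.fromarray(image.astype(np.float32), mode="F")
    warped = np.asarray(pil.transform((w, h), Image.AFFINE, (a, b, c, d, e, f0), resample=Image.BILINEAR))

    new_points: dict[str, Point2D] = {}
    for pid, p in points.items():
        uv = np.array([p[0] - cx, p[1] - cy])
        q = F @ uv
        target = mirror_id(pid) if flip else pid
        new_points[target] = Point2D(q[0] + cx, q[1] + cy)
    return warped, new_points


def build_model(config: DetectorConfig, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Instantiate the conv stack + heads; output dimension is 2·K."""
    if config.n_landmarks == 0:
        raise DetectorConfigError("empty landmark set")
    rng = rng or np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    size = config.input_size
    for idx, (filters, kernel, stride) in enumerate(config.conv_specs, start=1):
        if stride != 1:
            raise DetectorConfigError("only stride-1 convolutions are supported")
        layers.append(nn.Conv2D(in_ch, filters, kernel, rng))
        layers.append(nn.BatchNorm2D(filters))
        layers.append(nn.ReLU())
        in_ch = filters
        if idx in config.pool_after:
            layers.append(nn.MaxPool2x2())
            size //= 2
    layers.append(nn.Flatten())
    n_in = in_ch * size * size
    for width in config.fc_sizes:
        layers.append(nn.Dense(n_in, width, rng))
        layers.append(nn.ReLU())
        n_in = width
    layers.append(nn.Dense(n_in, 2 * config.n_landmarks, rng))
    return nn.Sequential(layers)


def analytic_n_params(config: DetectorConfig) -> int:
    """Closed-form parameter count from the layer shapes."""
    total = 0
    in_ch = 1
    size = config.input_size
    for idx, (filters, kernel, _) in enumerate(config.conv_specs, start=1):
        total += kernel * kernel * in_ch * filters + filters  # conv w + b
        total += 2 * filters  # bn gamma + beta
        in_ch = filters
        if idx in config.pool_after:
            size //= 2
    n_in = in_ch * size * size
    for width in config.fc_sizes:
        total += n_in * width + width
        n_in = width
    total += n_in * 2 * config.n_landmarks + 2 * config.n_landmarks
    return total


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_nme: list[float] = field(default_factory=list)
    val_nme: list[float] = field(default_factory=list)


@dataclass
class Detector:
    model: nn.Sequential
    config: DetectorConfig
    history: TrainingHistory | None = None

    def save(self, path) -> None:
        arrays = self.model.state_arrays()
        cfg = asdict(self.config)
        np.savez_compressed(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Detector":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["conv_specs"] = tuple(tuple(s) for s in cfg["conv_specs"])
        for key in ("pool_after", "fc_sizes", "landmark_ids", "scale_range"):
            cfg[key] = tuple(cfg[key])
        config = DetectorConfig(**cfg)
        model = build_model(config)
        model.load_state({k: data[k] for k in data.files if k != "__config__"})
        return cls(model=model, config=config)


def _targets_from_annotation(ann: ViewAnnotation, amap: AffineMap, config: DetectorConfig) -> np.ndarray:
    missing = [pid for pid in config.landmark_ids if pid not in ann.points]
    if missing:
        raise DetectorConfigError(f"annotation lacks configured landmark(s): {missing}")
    uv = np.array([[ann.points[pid].u, ann.points[pid].v] for pid in config.landmark_ids])
    return amap.to_model(uv) / config.input_size


def _nme2d(pred_norm: np.ndarray, true_norm: np.ndarray) -> float:
    """Mean conventional NME (%) of one image, normalized by the truth bbox."""
    dims = true_norm.max(axis=0) - true_norm.min(axis=0)
    dims = np.maximum(dims, 1e-9)
    rel = (pred_norm - true_norm) / dims
    return float(np.mean(np.sqrt(np.sum(rel**2, axis=1))) * 100.0)


def train(
    dataset: Sequence[tuple[np.ndarray, ViewAnnotation]],
    config: DetectorConfig,
    progress: bool = False,
) -> Detector:
    """Train one view's landmark regressor.

    ``dataset`` is a sequence of (image, annotation) pairs for the view; an
    80/20 train/validation split is drawn from ``config.seed`` unless
    ``val_fraction`` is 0.  Returns the detector with its per-epoch history.
    """
    if len(dataset) == 0:
        raise DetectorConfigError("empty dataset")
    for _, ann in dataset:
        if View(ann.view) is not View(config.view):
            raise DetectorConfigError(f"dataset view {ann.view} does not match config view {config.view}")

    rng = np.random.default_rng(config.seed)
    pre: list[np.ndarray] = []
    pts: list[dict[str, Point2D]] = []
    for img, ann in dataset:
        x, amap = preprocess(img, config)
        pre.append(x)
        model_pts = {pid: Point2D(*amap.to_model([p.u, p.v])) for pid, p in ann.points.items() if pid in config.landmark_ids}
        missing = set(config.landmark_ids) - set(model_pts)
        if missing:
            raise DetectorConfigError(f"annotation lacks configured landmark(s): {sorted(missing)}")
        pts.append(model_pts)

    n = len(pre)
    order = rng.permutation(n)
    n_val = int(round(n * config.val_fraction))
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if len(train_idx) == 0:
        raise DetectorConfigError("no training samples left after validation split")

    model = build_model(config, rng=np.random.default_rng(config.seed + 1))
    size = config.input_size

    if config.warm_start_bias:
        # standard detection-head warm start: the output bias begins at the
        # mean training target, so the optimizer fits residual displacements
        # instead of drifting the whole coordinate scale into place
        mean_target = np.mean(
            [
                np.array([[pts[i][pid].u, pts[i][pid].v] for pid in config.landmark_ids]).ravel() / size
                for i in train_idx
            ],
            axis=0,
        )
        model.layers[-1].b[:] = mean_target.astype(np.float32)
    if config.zero_init_head:
        # zero-initialized regression head: predictions start exactly at the
        # warm-started bias and the head's weights grow from the data
        model.layers[-1].w[:] = 0.0

    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history = TrainingHistory()
    step_no = 0
    steps_per_epoch = int(np.ceil(len(train_idx) / config.batch_size))
    total_steps = config.epochs * steps_per_epoch

    def batch_arrays(indices, augment_now: bool):
        xs, ys = [], []
        for i in indices:
            img, pd = pre[i], pts[i]
            if augment_now:
                img, pd = augment(img, pd, config, rng)
            xs.append(img)
            ys.append(np.array([[pd[pid].u, pd[pid].v] for pid in config.landmark_ids]) / size)
        return np.stack(xs)[:, :, :, None].astype(np.float32), np.stack(ys).reshape(len(indices), -1).astype(np.float32)

    def evaluate(indices):
        if len(indices) == 0:
            return float("nan"), float("nan")
        losses, nmes = [], []
        for start in range(0, len(indices), config.batch_size):
            chunk = indices[start : start + config.batch_size]
            x, y = batch_arrays(chunk, augment_now=False)
            out = model.forward(x, training=False)
            loss, _ = nn.mse_loss(out, y)
            losses.append(loss * len(chunk))
            for row_pred, row_true in zip(out, y):
                nmes.append(_nme2d(row_pred.reshape(-1, 2), row_true.reshape(-1, 2)))
        return float(np.sum(losses) / len(indices)), float(np.mean(nmes))

    for epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        # training metrics accumulate over the epoch's own (pre-update)
        # batch outputs; only the validation split gets a dedicated pass
        running, running_nme, seen = 0.0, 0.0, 0
        for start in range(0, len(perm), config.batch_size):
            chunk = perm[start : start + config.batch_size]
            x, y = batch_arrays(chunk, augment_now=config.augment)
            out = model.forward(x, training=True)
            loss, dout = nn.mse_loss(out, y)
            model.backward(dout)
            step_no += 1
            if config.warmup_steps > 0 or config.lr_schedule != "constant":
                # linear warmup keeps Adam's first (sign-normalized, hence
                # full-size) steps from kicking the high-fan-in head far off
                # the warm start; cosine decay then shrinks the step-noise
                # floor so short runs can actually settle
                factor = min(1.0, step_no / config.warmup_steps) if config.warmup_steps > 0 else 1.0
                if config.lr_schedule == "cosine" and step_no > config.warmup_steps:
                    span = max(1, total_steps - config.warmup_steps)
                    progress_frac = min(1.0, (step_no - config.warmup_steps) / span)
                    factor *= 0.5 * (1.0 + math.cos(math.pi * progress_frac))
                opt.lr = config.learning_rate * factor
            opt.step(model.grads())
            running += loss * len(chunk)
            running_nme += sum(
                _nme2d(rp.reshape(-1, 2), rt.reshape(-1, 2)) for rp, rt in zip(out, y)
            )
            seen += len(chunk)
        va_loss, va_nme = evaluate(val_idx)
        history.train_loss.append(running / seen)
        history.val_loss.append(va_loss)
        history.train_nme.append(running_nme / seen)
        history.val_nme.append(va_nme)
        if progress:
            print(
                f"epoch {epoch + 1}/{config.epochs}  loss {history.train_loss[-1]:.6f}"
                f"  val {va_loss:.6f}  val NME {va_nme:.2f}%"
            )
    return Detector(model=model, config=config, history=history)


def predict(images: Sequence, detector: Detector, view: str | View | None = None) -> list[ViewAnnotation]:
    """Predict landmark positions in original pixel coordinates.

    Input order is preserved; outputs are clamped to the image bounds.
    """
    config = detector.config
    if view is not None and View(view) is not View(config.view):
        raise DetectorConfigError(f"detector was trained for {config.view}, asked to predict {View(view).value}")
    out: list[ViewAnnotation] = []
    batch_x: list[np.ndarray] = []
    maps: list[AffineMap] = []
    shapes: list[tuple[int, int]] = []
    for img in images:
        arr = _to_array(img)
        x, amap = preprocess(arr, config)
        batch_x.append(x)
        maps.append(amap)
        shapes.append((arr.shape[1], arr.shape[0]))
    for start in range(0, len(batch_x), config.batch_size):
        chunk = np.stack(batch_x[start : start + config.batch_size])[:, :, :, None].astype(np.float32)
        preds = detector.model.forward(chunk, training=False)
        for row, amap, (w, h) in zip(preds, maps[start:], shapes[start:]):
            uv_model = row.reshape(-1, 2) * config.input_size
            uv = amap.to_original(uv_model)
            uv[:, 0] = np.clip(uv[:, 0], 0, w - 1)
            uv[:, 1] = np.clip(uv[:, 1], 0, h - 1)
            points = {pid: Point2D(*uv[i]) for i, pid in enumerate(config.landmark_ids)}
            out.append(ViewAnnotation(view=View(config.view), points=points, image_size=(w, h)))
    return out
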