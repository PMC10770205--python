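"""Heatmap-based detection of the ICA-terminus and M1 arterial landmarks.

A compact convolutional encoder–decoder with skip connections maps a minIP
to two per-pixel maps, one per landmark, squashed to (0, 1) by a final
sigmoid.  Training targets are isotropic Gaussian probability maps centred
on the annotated landmark; because the sigmoid output is not itself a
distribution, each predicted map is normalized to sum to one (with
epsilon-clamping) before the loss — Kullback–Leibler or Jensen–Shannon
divergence — is evaluated.  At inference a landmark position is decoded as
either the argmax pixel or the centre of mass of the map.

Training/validation splits are always made by ``source_id`` so that two
images of the same subject (e.g. the pre and post series of one procedure)
never straddle the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import _nn

EPS = 1e-12

LANDMARK_LABELS = ("ICA", "M1")


class LossKind(str, Enum):
    KL = "kl"
    JS = "js"


class DecodeMode(str, Enum):
    ARGMAX = "argmax"
    CENTER_OF_MASS = "center_of_mass"


@dataclass
class TrainingConfig:
    """Training/architecture settings for the landmark detector.

    ``target_sigma`` is the Gaussian target width in pixels (default 4 px at
    512x512); ``depth`` counts resolution levels and ``base_channels`` the
    channel width of the first level (doubling per level).
    """

    loss: LossKind = LossKind.KL
    target_sigma: float = 4.0
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    depth: int = 4
    base_channels: int = 16
    image_size: int = 512
    val_fraction: float = 0.25

    def __post_init__(self) -> None:
        self.loss = LossKind(self.loss)
        if self.target_sigma <= 0:
            raise ValueError("target_sigma must be > 0")


# ---------------------------------------------------------------------------
# Targets, losses, decoding
# ---------------------------------------------------------------------------

def make_target_heatmap(point: tuple[float, float], shape: tuple[int, int],
                        sigma: float) -> np.ndarray:
    """Isotropic Gaussian probability map centred on ``point`` (x, y).

    Normalized to sum to exactly 1 over the grid, so it is a valid discrete
    distribution even when the point sits near a border.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    h, w = shape
    x, y = point
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError(f"point ({x}, {y}) outside {w}x{h} grid")
    yy, xx = np.mgrid[0:h, 0:w]
    g = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma ** 2))
    return g / g.sum()


def normalize_heatmap(raw: np.ndarray) -> np.ndarray:
    """Clamp a raw (sigmoid) map to >= EPS and rescale it to sum to 1."""
    p = np.clip(np.asarray(raw, dtype=float), EPS, None)
    return p / p.sum()


def heatmap_loss(pred: np.ndarray, target: np.ndarray,
                 kind: LossKind | str = LossKind.KL) -> float:
    """KL(target || pred) or JS(target, pred) between two normalized maps."""
    kind = LossKind(kind)
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, EPS, None)
    t = np.clip(target, EPS, None)
    if kind is LossKind.KL:
        return float(np.sum(target * np.log(t / p)))
    m = 0.5 * (t + p)
    return float(0.5 * np.sum(target * np.log(t / m)) + 0.5 * np.sum(pred * np.log(p / m)))


def decode_heatmap(heatmap: np.ndarray, mode: DecodeMode | str = DecodeMode.ARGMAX
                   ) -> tuple[float, float]:
    """Decode a single landmark position (x, y) from a heatmap.

    ARGMAX returns the integer location of the maximum (ties broken toward
    the lowest row, then lowest column); CENTER_OF_MASS the probability-
    weighted mean position over the full map.
    """
    mode = DecodeMode(mode)
    hm = np.asarray(heatmap, dtype=float)
    if hm.max() <= 0:
        raise ValueError("heatmap has no positive values")
    if mode is DecodeMode.ARGMAX:
        r, c = np.unravel_index(int(np.argmax(hm)), hm.shape)  # row-major: first max
        return float(c), float(r)
    total = hm.sum()
    yy, xx = np.mgrid[0:hm.shape[0], 0:hm.shape[1]]
    return float((hm * xx).sum() / total), float((hm * yy).sum() / total)


@dataclass
class LandmarkPrediction:
    """Decoded landmark positions for one image."""

    positions: dict[str, tuple[float, float]]
    decode_mode: DecodeMode
    confidence: dict[str, float]  # peak raw-map value per landmark


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class LandmarkNet:
    """Encoder–decoder with skip connections; 1 input channel, 2 output maps.

    Each level holds two 3x3 conv + ReLU pairs; levels are linked by 2x2 max
    pooling on the way down and nearest-neighbour upsampling + skip
    concatenation on the way up; a 1x1 conv head plus per-pixel sigmoid
    produces the ICA and M1 maps.  Channel widths double per level from
    ``base_channels``.  Total parameter count follows from the conv formulas
    (9*cin*cout + cout per 3x3 conv, cin*cout + cout for the head).
    """

    def __init__(self, config: TrainingConfig):
        d, b = config.depth, config.base_channels
        if d < 2 or b < 1:
            raise ValueError("depth must be >= 2 and base_channels >= 1")
        if config.image_size // (2 ** (d - 1)) < 1:
            raise ValueError(
                f"depth {d} collapses a {config.image_size}px input below 1x1"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = [b * 2 ** i for i in range(d)]
        self.ch = ch
        self.enc = []
        cin = 1
        for i in range(d - 1):
            self.enc.append([
                _nn.Conv3x3(cin, ch[i], rng), _nn.ReLU(),
                _nn.Conv3x3(ch[i], ch[i], rng), _nn.ReLU(),
            ])
            cin = ch[i]
        self.pools = [_nn.MaxPool2() for _ in range(d - 1)]
        self.bottleneck = [
            _nn.Conv3x3(ch[d - 2], ch[d - 1], rng), _nn.ReLU(),
            _nn.Conv3x3(ch[d - 1], ch[d - 1], rng), _nn.ReLU(),
        ]
        self.ups = [_nn.Upsample2() for _ in range(d - 1)]
        self.dec = []
        for i in range(d - 2, -1, -1):
            cin_dec = ch[i + 1] + ch[i]  # upsampled + skip
            self.dec.append([
                _nn.Conv3x3(cin_dec, ch[i], rng), _nn.ReLU(),
                _nn.Conv3x3(ch[i], ch[i], rng), _nn.ReLU(),
            ])
        self.head = _nn.Conv1x1(ch[0], 2, rng)

    # -- plumbing -------------------------------------------------------
    def _blocks(self):
        for block in self.enc + [self.bottleneck] + self.dec:
            yield from block
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._blocks():
            if hasattr(layer, "params"):
                out.extend(layer.params())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._blocks():
            if hasattr(layer, "grads"):
                out.extend(layer.grads())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) float32 -> logits (N, 2, H, W)."""
        skips = []
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                x = layer.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for layer in self.bottleneck:
            x = layer.forward(x)
        self._skip_ch = []
        for block, up, skip in zip(self.dec, self.ups, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            for layer in block:
                x = layer.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for block, up, up_ch in zip(reversed(self.dec), reversed(self.ups),
                                    reversed(self._skip_ch)):
            for layer in reversed(block):
                dx = layer.backward(dx)
            dskips.append(dx[:, up_ch:])
            dx = up.backward(dx[:, :up_ch])
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            dx = pool.backward(dx)
            dx = dx + dskip
            for layer in reversed(block):
                dx = layer.backward(dx)

    # -- inference ------------------------------------------------------
    def predict_heatmaps(self, image: np.ndarray) -> np.ndarray:
        """minIP (H, W) in [0, 1] -> raw sigmoid maps (2, H, W) in (0, 1)."""
        x = _prepare_input(np.asarray(getattr(image, "pixels", image)))
        logits = self.forward(x[None, None])
        return _nn.sigmoid(logits)[0].astype(float)

    def predict(self, image: np.ndarray,
                mode: DecodeMode | str = DecodeMode.CENTER_OF_MASS) -> LandmarkPrediction:
        maps = self.predict_heatmaps(image)
        mode = DecodeMode(mode)
        positions, confidence = {}, {}
        for i, label in enumerate(LANDMARK_LABELS):
            positions[label] = decode_heatmap(normalize_heatmap(maps[i]), mode)
            confidence[label] = float(maps[i].max())
        return LandmarkPrediction(positions=positions, decode_mode=mode,
                                  confidence=confidence)


def build_model(config: TrainingConfig) -> LandmarkNet:
    """Construct the landmark network with seed-deterministic initialization."""
    return LandmarkNet(config)


def _prepare_input(img: np.ndarray) -> np.ndarray:
    # vessels are dark on bright background; invert so structure is positive
    return (1.0 - np.asarray(img, dtype=np.float32))


def _loss_and_grad(logits: np.ndarray, targets: np.ndarray, kind: LossKind
                   ) -> tuple[float, np.ndarray]:
    """Divergence loss summed over maps + analytic gradient w.r.t. logits.

    Each sigmoid map s is normalized to p = s / sum(s) before the divergence
    against the Gaussian target t.  For KL(t||p) the gradient reduces to
    dL/dz = -t (1 - s) + s (1 - s) / sum(s); for JS it is obtained by
    chaining g = 0.5 log(p/m) through the normalization and the sigmoid.
    """
    n, c, h, w = logits.shape
    s = _nn.sigmoid(logits.astype(np.float64))
    s = np.clip(s, EPS, 1 - EPS)
    ssum = s.sum(axis=(2, 3), keepdims=True)
    p = s / ssum
    t = targets
    total = 0.0
    if kind is LossKind.KL:
        total = float(np.sum(t * (np.log(np.clip(t, EPS, None)) - np.log(p))))
        dz = -t * (1 - s) + s * (1 - s) / ssum
    else:
        m = 0.5 * (t + p)
        total = float(
            0.5 * np.sum(t * (np.log(np.clip(t, EPS, None)) - np.log(m)))
            + 0.5 * np.sum(p * (np.log(p) - np.log(m)))
        )
        g = 0.5 * np.log(p / m)
        gp = (g * p).sum(axis=(2, 3), keepdims=True)
        dz = (g - gp) / ssum * s * (1 - s)
    return total / (n * c), (dz / (n * c)).astype(_nn.DTYPE)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def split_by_source(source_ids: list[str], val_fraction: float, seed: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Index split keeping every source_id entirely on one side."""
    ids = np.asarray(source_ids)
    unique = np.unique(ids)
    if len(unique) < 2:
        raise ValueError("need at least two distinct source_ids to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    n_val = max(1, int(round(val_fraction * len(unique))))
    n_val = min(n_val, len(unique) - 1)
    val_ids = set(perm[:n_val])
    val_mask = np.array([i in val_ids for i in ids])
    return np.where(~val_mask)[0], np.where(val_mask)[0]


def kfold_by_source(source_ids: list[str], k: int = 3, seed: int = 0):
    """Yield (train_idx, val_idx) folds with disjoint source_ids, as in a
    cross-validation split by patient id."""
    ids = np.asarray(source_ids)
    unique = np.unique(ids)
    if len(unique) < k:
        raise ValueError(f"need >= {k} distinct source_ids for {k}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    folds = np.array_split(perm, k)
    for fold in folds:
        val_ids = set(fold)
        val_mask = np.array([i in val_ids for i in ids])
        yield np.where(~val_mask)[0], np.where(val_mask)[0]


def _com_errors(model: LandmarkNet, images: np.ndarray, landmarks: list[dict]
                ) -> np.ndarray:
    """Centre-of-mass prediction error (px) for every landmark of every image."""
    errs = []
    for img, lm in zip(images, landmarks):
        pred = model.predict(img, mode=DecodeMode.CENTER_OF_MASS)
        for label in LANDMARK_LABELS:
            errs.append(float(np.linalg.norm(
                np.asarray(pred.positions[label]) - np.asarray(lm[label])
            )))
    return np.asarray(errs)


def train_landmark_model(
    images: np.ndarray,
    landmarks: list[dict[str, tuple[float, float]]],
    source_ids: list[str],
    config: TrainingConfig,
) -> tuple[LandmarkNet, pd.DataFrame]:
    """Train the detector and return the best-validation checkpoint.

    ``images`` is (N, H, W) in [0, 1]; ``landmarks`` holds the annotated
    ICA/M1 positions per image.  The split is by source_id; optimization is
    Adam on the configured divergence; weights are kept from the epoch with
    the lowest median validation centre-of-mass error.  Returns the model
    (restored to the best epoch) and a per-epoch metrics table
    (epoch, train_loss, val_com_error_px, is_best).
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3 or len(images) == 0:
        raise ValueError("images must be a non-empty (N, H, W) array")
    if not (len(images) == len(landmarks) == len(source_ids)):
        raise ValueError("images, landmarks and source_ids must align")

    train_idx, val_idx = split_by_source(source_ids, config.val_fraction, config.seed)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty train or validation split")

    h, w = images.shape[1:]
    targets = np.empty((len(images), 2, h, w), dtype=np.float64)
    for i, lm in enumerate(landmarks):
        for j, label in enumerate(LANDMARK_LABELS):
            targets[i, j] = make_target_heatmap(lm[label], (h, w), config.target_sigma)

    model = build_model(config)
    opt = _nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    x_all = _prepare_input(images)[:, None]  # (N, 1, H, W)

    val_images = images[val_idx]
    val_landmarks = [landmarks[i] for i in val_idx]

    rows = []
    best_err, best_weights, best_epoch = np.inf, None, -1
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = model.forward(x_all[batch])
            loss, dz = _loss_and_grad(logits, targets[batch], config.loss)
            model.backward(dz)
            opt.step(model.gradients())
            epoch_loss += loss
            n_batches += 1
        val_err = float(np.median(_com_errors(model, val_images, val_landmarks)))
        if val_err < best_err:
            best_err, best_weights, best_epoch = val_err, model.get_weights(), epoch
        rows.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_com_error_px": val_err,
        })
    model.set_weights(best_weights)
    metrics = pd.DataFrame(rows)
    metrics["is_best"] = metrics["epoch"] == best_epoch
    return model, metrics


def save_model(model: LandmarkNet, path) -> None:
    """Serialize weights (npz) with the config embedded as JSON."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["loss"] = model.config.loss.value
    np.savez(path, config=json.dumps(cfg),
             **{f"p{i}": p for i, p in enumerate(model.parameters())})


def load_model(path) -> LandmarkNet:
    import json

    data = np.load(path, allow_pickle=False)
    cfg = TrainingConfig(**json.loads(str(data["config"])))
    model = build_model(cfg)
    model.set_weights([data[f"p{i}"] for i in range(len(model.parameters()))])
    return model
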