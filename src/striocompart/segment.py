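"""Striosome segmentation protocol: Otsu-assisted pre-annotation, tiling of
large sections, the two augmentation arms, cross-entropy training with
checkpoint selection at the minimum held-out loss, and tiled inference.

The model is trained striosome-vs-rest on the MOR1 reference channel.
"Training rate 0.85" is implemented as the train/held-out split fraction;
the learning rate is a separate configurable (default 1e-3).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import nn
from .types import (
    LabelMap, SectionImage, BACKGROUND, MATRIX, STRIOSOME,
)
from .unet import ResidualUNet, UNetSpec


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Otsu pre-annotation
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximizing threshold of a gray-level sample."""
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("no pixels to threshold")
    if np.all(values == values.flat[0]):
        raise ValueError("constant image: no threshold exists")
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values, nbins=nbins))


def otsu_preannotate(image: np.ndarray, tissue_mask: np.ndarray | None = None) -> LabelMap:
    """Draft striosome mask by Otsu thresholding within the tissue region.

    Striosomes are MOR1-bright, so the high class is marked striosome and
    the rest of the tissue matrix. This is an annotation aid, not final
    ground truth. Raises on constant input (no threshold exists).
    """
    img = np.asarray(image, dtype=np.float32)
    if tissue_mask is None:
        tissue_mask = np.ones(img.shape, dtype=bool)
    else:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
    thr = otsu_threshold(img[tissue_mask])
    labels = np.full(img.shape, BACKGROUND, dtype=np.uint8)
    labels[tissue_mask] = MATRIX
    labels[tissue_mask & (img > thr)] = STRIOSOME
    return LabelMap(labels)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    """Half-open crop window [r0, r1) x [c0, c1) of a tile in the section."""
    r0: int
    r1: int
    c0: int
    c1: int


def tile_grid(shape: tuple[int, int], tile_size: int) -> list[Placement]:
    """Non-overlapping grid of tile windows covering ``shape``; edge windows
    are clipped to the image (their tiles get reflection padding)."""
    h, w = shape
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    out = []
    for r0 in range(0, h, tile_size):
        for c0 in range(0, w, tile_size):
            out.append(Placement(r0, min(r0 + tile_size, h),
                                 c0, min(c0 + tile_size, w)))
    return out


def _pad_to(tile: np.ndarray, tile_size: int) -> np.ndarray:
    if tile.shape[0] >= tile_size and tile.shape[1] >= tile_size:
        return tile
    # mirror-pad in rounds: thin edge slivers may need more padding than
    # their own extent
    while tile.shape[0] < tile_size or tile.shape[1] < tile_size:
        ph = min(tile_size - tile.shape[0], tile.shape[0])
        pw = min(tile_size - tile.shape[1], tile.shape[1])
        tile = np.pad(tile, ((0, max(ph, 0)), (0, max(pw, 0))), mode="symmetric")
    return tile


def tile_image(
    section: SectionImage | np.ndarray,
    labels: LabelMap | None,
    tile_size: int,
    drop_empty: bool = False,
) -> list[tuple[np.ndarray, np.ndarray | None, Placement]]:
    """Cut the reference channel (and labels) into tile_size tiles.

    Edge tiles are padded by reflection; ``Placement`` records the half-open
    valid window so stitching is exact. ``drop_empty`` drops tiles without
    striatal tissue — legitimate for training, never for inference.
    """
    img = section.reference_channel if isinstance(section, SectionImage) else np.asarray(section)
    if tile_size > img.shape[0] and tile_size > img.shape[1]:
        raise ValueError("tile_size exceeds both image dimensions")
    out = []
    for pl in tile_grid(img.shape, tile_size):
        t = _pad_to(img[pl.r0:pl.r1, pl.c0:pl.c1], tile_size)
        tl = None
        if labels is not None:
            tl = _pad_to(labels.labels[pl.r0:pl.r1, pl.c0:pl.c1], tile_size)
            if drop_empty and not np.any((tl == STRIOSOME) | (tl == MATRIX)):
                continue
        out.append((t, tl, pl))
    return out


def stitch(tiles: Sequence[np.ndarray], placements: Sequence[Placement],
           shape: tuple[int, int], dtype=None) -> np.ndarray:
    """Inverse of tiling: paste each tile's valid window back."""
    out = np.zeros(shape, dtype=dtype if dtype is not None else np.asarray(tiles[0]).dtype)
    for t, pl in zip(tiles, placements):
        out[pl.r0:pl.r1, pl.c0:pl.c1] = t[: pl.r1 - pl.r0, : pl.c1 - pl.c0]
    return out


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

AUGMENTATION_ARMS = ("vflip_only", "vflip_plus_photometric")

#: photometric jitter defaults (fractional ranges)
BRIGHTNESS_JITTER = 0.2
SATURATION_JITTER = 0.2
HUE_JITTER = 0.05


def augment(tile: np.ndarray, tile_labels: np.ndarray | None, arm: str,
            rng: np.random.Generator, max_gray: float = 255.0):
    """One augmentation draw.

    ``vflip_only``: with probability 0.5 flip image and labels vertically.
    ``vflip_plus_photometric``: additionally jitter brightness (and, for
    color tiles, hue and saturation) of the image only — labels are never
    photometrically altered. Geometric transforms always apply identically
    to image and labels.
    """
    if arm not in AUGMENTATION_ARMS:
        raise ValueError(f"unknown augmentation arm {arm!r}")
    if rng.random() < 0.5:
        tile = tile[::-1].copy()
        if tile_labels is not None:
            tile_labels = tile_labels[::-1].copy()
    if arm == "vflip_plus_photometric":
        factor = 1.0 + rng.uniform(-BRIGHTNESS_JITTER, BRIGHTNESS_JITTER)
        if tile.ndim == 3 and tile.shape[-1] == 3:
            from skimage import color

            hsv = color.rgb2hsv(np.clip(tile / max_gray, 0, 1))
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-HUE_JITTER, HUE_JITTER)) % 1.0
            hsv[..., 1] = np.clip(
                hsv[..., 1] * (1 + rng.uniform(-SATURATION_JITTER, SATURATION_JITTER)),
                0, 1)
            hsv[..., 2] = np.clip(hsv[..., 2] * factor, 0, 1)
            tile = (color.hsv2rgb(hsv) * max_gray).astype(np.float32)
        else:
            tile = np.clip(tile * factor, 0.0, max_gray).astype(np.float32)
    return tile, tile_labels


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 32
    total_epochs: int = 160
    augmentation_arm: str = "vflip_only"
    train_fraction: float = 0.85
    seed: int = 0
    tile_size: int = 512
    learning_rate: float = 1e-3
    steps_per_epoch: int | None = None  # None = one pass over all tiles
    eval_tiles: int = 32  # held-out tiles sampled for the per-epoch loss
    max_gray: float = 255.0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.total_epochs < 1:
            raise ValueError("batch_size and total_epochs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.augmentation_arm not in AUGMENTATION_ARMS:
            raise ValueError(f"unknown augmentation arm {self.augmentation_arm!r}")


@dataclass
class TrainingCurve:
    """Per-epoch train loss, held-out loss and pixel accuracy (1-based
    epoch numbering). The selected checkpoint is the argmin of held-out
    cross-entropy (the first epoch on ties)."""

    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)

    @property
    def selected_epoch(self) -> int:
        return select_checkpoint(self.test_loss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": np.arange(1, len(self.test_loss) + 1),
            "train_loss": self.train_loss,
            "test_loss": self.test_loss,
            "test_accuracy": self.test_accuracy,
        })


def select_checkpoint(test_losses: Sequence[float]) -> int:
    """1-based epoch with the lowest held-out loss (first on ties)."""
    losses = np.asarray(list(test_losses), dtype=float)
    if losses.size == 0:
        raise ValueError("empty loss curve")
    return int(np.argmin(losses)) + 1


@dataclass
class TrainedModel:
    net: ResidualUNet
    spec: UNetSpec
    config: TrainConfig
    selected_epoch: int
    max_gray: float = 255.0

    def save(self, path) -> None:
        self.net.save(path, sidecar={
            "train_config": asdict(self.config),
            "selected_epoch": self.selected_epoch,
            "max_gray": self.max_gray,
        })

    @classmethod
    def load(cls, path) -> "TrainedModel":
        net, meta = ResidualUNet.load(path)
        cfg = TrainConfig(**meta["train_config"])
        return cls(net, net.spec, cfg, meta["selected_epoch"],
                   meta.get("max_gray", 255.0))


def _normalize(img: np.ndarray, max_gray: float) -> np.ndarray:
    """Fixed input normalization shared by training and inference."""
    return (np.asarray(img, dtype=np.float32) / max_gray) - 0.5


def _batch_arrays(tiles, labels, max_gray):
    x = np.stack([_normalize(t, max_gray) for t in tiles])[..., None]
    y = np.stack([(l == STRIOSOME).astype(np.int64) for l in labels])
    return x, y


def train(
    tiles: Sequence[tuple[np.ndarray, np.ndarray]],
    spec: UNetSpec,
    config: TrainConfig,
    test_tiles: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[TrainedModel, TrainingCurve]:
    """Train striosome-vs-rest on (image_tile, label_tile) pairs.

    When ``test_tiles`` is None, ``tiles`` is shuffled (seeded) and split at
    ``train_fraction``. Per epoch, ``steps_per_epoch`` batches are drawn
    from a seeded permutation stream (None = full pass); the held-out loss
    and pixel accuracy are evaluated on up to ``eval_tiles`` fixed held-out
    tiles, and the returned model carries the weights of the minimum-loss
    epoch, not the final one.
    """
    rng = np.random.default_rng(config.seed)
    tiles = list(tiles)
    if test_tiles is None:
        order = rng.permutation(len(tiles))
        n_train = int(round(config.train_fraction * len(tiles)))
        n_train = min(max(n_train, 1), len(tiles) - 1)
        train_set = [tiles[i] for i in order[:n_train]]
        test_set = [tiles[i] for i in order[n_train:]]
    else:
        train_set = tiles
        test_set = list(test_tiles)
    if not train_set or not test_set:
        raise ValueError("need at least one training and one held-out tile")
    if len(test_set) > config.eval_tiles:
        idx = rng.choice(len(test_set), size=config.eval_tiles, replace=False)
        eval_set = [test_set[i] for i in idx]
    else:
        eval_set = test_set

    net = ResidualUNet(spec, seed=int(rng.integers(2**31)))
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    curve = TrainingCurve()
    ex, ey = _batch_arrays([t for t, _ in eval_set], [l for _, l in eval_set],
                           config.max_gray)

    best_loss = np.inf
    best_state = net.state_dict()
    steps = config.steps_per_epoch
    if steps is None:
        steps = max(1, int(np.ceil(len(train_set) / config.batch_size)))
    stream: list[int] = []
    for epoch in range(1, config.total_epochs + 1):
        ep_losses = []
        for _ in range(steps):
            while len(stream) < config.batch_size:
                stream.extend(rng.permutation(len(train_set)).tolist())
            take, stream = stream[:config.batch_size], stream[config.batch_size:]
            batch = []
            for i in take:
                t, l = train_set[i]
                t, l = augment(t, l, config.augmentation_arm, rng,
                               max_gray=config.max_gray)
                batch.append((t, l))
            bx, by = _batch_arrays([t for t, _ in batch], [l for _, l in batch],
                                   config.max_gray)
            net.zero_grad()
            logits = net.forward(bx)
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, by)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {loss}")
            net.backward(dlogits)
            opt.step()
            ep_losses.append(loss)
        tl, acc = _evaluate(net, ex, ey)
        curve.train_loss.append(float(np.mean(ep_losses)))
        curve.test_loss.append(tl)
        curve.test_accuracy.append(acc)
        if tl < best_loss:
            best_loss = tl
            best_state = net.state_dict()
    net.load_state_dict(best_state)
    model = TrainedModel(net, spec, config, curve.selected_epoch, config.max_gray)
    return model, curve


def _evaluate(net: ResidualUNet, x: np.ndarray, y: np.ndarray,
              chunk: int = 8) -> tuple[float, float]:
    losses, hits, total = [], 0, 0
    for i in range(0, len(x), chunk):
        logits = net.forward(x[i:i + chunk])
        loss, _, probs = nn.softmax_cross_entropy(logits, y[i:i + chunk])
        losses.append(loss * (min(i + chunk, len(x)) - i))
        pred = probs[..., 1] >= 0.5
        hits += int(np.count_nonzero(pred == (y[i:i + chunk] == 1)))
        total += y[i:i + chunk].size
    return float(np.sum(losses) / len(x)), hits / total


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(
    model: TrainedModel,
    section: SectionImage | np.ndarray,
    striatal_mask: np.ndarray | None = None,
    tile_size: int | None = None,
) -> tuple[np.ndarray, LabelMap]:
    """Tiled inference on the reference (MOR1) channel.

    Probabilities are stitched over the non-overlapping tile grid and
    binarized at 0.5 — probability exactly 0.5 is assigned striosome (the
    declared tie-break). Pixels not predicted striosome are labelled matrix
    within ``striatal_mask`` (the whole frame when no mask is given) and
    background outside it. Returns (probability map, label map).
    """
    img = section.reference_channel if isinstance(section, SectionImage) else np.asarray(section)
    d = model.spec.divisor
    if tile_size is None:
        tile_size = int(min(max(model.config.tile_size, d), 512))
    if tile_size % d:
        raise ValueError(f"tile_size must be divisible by {d}")
    placements = tile_grid(img.shape, tile_size)
    probs = []
    for pl in placements:
        t = _pad_to(img[pl.r0:pl.r1, pl.c0:pl.c1], tile_size)
        x = _normalize(t, model.max_gray)[None, ..., None]
        logits = model.net.forward(x)
        z = logits[0].astype(np.float64)
        z -= z.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        probs.append((ez[..., 1] / ez.sum(axis=-1)).astype(np.float32))
    prob_map = stitch(probs, placements, img.shape, dtype=np.float32)
    striosome = prob_map >= 0.5
    labels = np.full(img.shape, BACKGROUND, dtype=np.uint8)
    if striatal_mask is None:
        labels[:] = MATRIX
    else:
        labels[np.asarray(striatal_mask, dtype=bool)] = MATRIX
        striosome = striosome & np.asarray(striatal_mask, dtype=bool)
    labels[striosome] = STRIOSOME
    return prob_map, LabelMap(labels)
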