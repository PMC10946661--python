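"""Grain-region segmentation: U-Net training, prediction, and cropping.

The segmenter separates the grain-filled dish region from the background;
its mask feeds descriptor extraction, and its bounding box provides the
dish crop consumed by the CNN classifier.  Training runs at a configurable
reduced resolution (images are resized to ``input_size`` with
nearest-neighbor mask resampling); predictions are resampled back to the
source resolution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator

from .nn import Adam, UNet, bce_with_logits, minibatches, sigmoid, soft_dice_loss

__all__ = [
    "SegmenterConfig",
    "GrainSegmenter",
    "build_segmenter",
    "train_segmenter",
    "predict_mask",
    "crop_grain_region",
    "iou_score",
    "load_pairs",
]


@dataclass
class SegmenterConfig:
    """Training configuration for the grain-region segmenter."""

    encoder_family: str = "resnet18"
    input_size: int = 128
    depth: int = 5
    base_width: int = 8
    epochs: int = 5
    batch_size: int = 1
    learning_rate: float = 1e-2
    loss_name: str = "bce_dice"  # or "bce"
    threshold: float = 0.5
    seed: int = 0


def iou_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 if both empty)."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


NET_IN_CHANNELS = 6  # RGB + HSV stack


def _to_net_input(image: np.ndarray, size: int) -> np.ndarray:
    """8-bit RGB -> float32 CHW at the network resolution.

    The networks consume a 6-channel color stack (RGB plus HSV, all in
    [0, 1]): hue and saturation make the pigment distinctions (purple
    anthocyanin vs near-achromatic melanin) directly available to the
    first layer instead of having to be synthesized from RGB.
    """
    from skimage.color import rgb2hsv

    img = resize(image.astype(np.float32) / 255.0, (size, size, 3),
                 order=1, anti_aliasing=True, preserve_range=True)
    stack = np.concatenate([img, rgb2hsv(img)], axis=2)
    return stack.transpose(2, 0, 1).astype(np.float32)


def _mask_to_net(mask: np.ndarray, size: int) -> np.ndarray:
    m = resize(np.asarray(mask).astype(np.float32), (size, size),
               order=0, anti_aliasing=False, preserve_range=True)
    return (m > 0.5).astype(np.float32)[None]


class GrainSegmenter(BaseEstimator):
    """Binary grain-region segmenter (scikit-learn style estimator).

    ``fit(images, masks)`` trains the U-Net; ``predict(images)`` returns
    binary masks at each image's native resolution.  The best epoch by
    validation loss (training loss if no validation pairs are given) is
    kept.  Fitted attributes: ``net_``, ``history_``.
    """

    def __init__(self, encoder_family: str = "resnet18", input_size: int = 128,
                 depth: int = 5, base_width: int = 8, epochs: int = 5,
                 batch_size: int = 1, learning_rate: float = 1e-2,
                 loss_name: str = "bce_dice", threshold: float = 0.5, seed: int = 0):
        self.encoder_family = encoder_family
        self.input_size = input_size
        self.depth = depth
        self.base_width = base_width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss_name = loss_name
        self.threshold = threshold
        self.seed = seed

    def _validate(self) -> None:
        if self.input_size % (1 << self.depth):
            raise ValueError(
                f"input_size {self.input_size} must be divisible by {1 << self.depth}"
            )
        if self.loss_name not in ("bce", "bce_dice"):
            raise ValueError(f"unknown loss {self.loss_name!r}")

    def build_net(self) -> UNet:
        """Freshly initialized network (deterministic in ``seed``)."""
        self._validate()
        rng = np.random.default_rng(self.seed)
        return UNet(rng, in_channels=NET_IN_CHANNELS, out_channels=1, depth=self.depth,
                    base_width=self.base_width, encoder_family=self.encoder_family)

    def _loss(self, logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        loss, dz = bce_with_logits(logits, targets)
        if self.loss_name == "bce_dice":
            dloss, ddz = soft_dice_loss(logits, targets)
            loss, dz = loss + dloss, dz + ddz
        return loss, dz

    def fit(self, images, masks, val_images=None, val_masks=None):
        if len(images) == 0:
            raise ValueError("empty training set")
        if len(images) != len(masks):
            raise ValueError("images and masks length mismatch")
        self._validate()
        size = self.input_size
        X = np.stack([_to_net_input(im, size) for im in images])
        Y = np.stack([_mask_to_net(mk, size) for mk in masks])
        Xv = Yv = None
        if val_images is not None and len(val_images):
            Xv = np.stack([_to_net_input(im, size) for im in val_images])
            Yv = np.stack([_mask_to_net(mk, size) for mk in val_masks])

        net = self.build_net()
        opt = Adam(net.params(), lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        history = {"train_loss": [], "val_loss": [], "val_iou": []}
        best = (np.inf, None)
        for _epoch in range(self.epochs):
            losses = []
            for idx in minibatches(len(X), self.batch_size, rng):
                logits = net.forward(X[idx])
                loss, dz = self._loss(logits, Y[idx])
                opt.zero_grad()
                net.backward(dz.astype(np.float32))
                opt.step()
                losses.append(loss)
            train_loss = float(np.mean(losses))
            history["train_loss"].append(train_loss)
            if Xv is not None:
                vloss, viou = self._evaluate(net, Xv, Yv)
                history["val_loss"].append(vloss)
                history["val_iou"].append(viou)
                monitor = vloss
            else:
                monitor = train_loss
            if monitor < best[0]:
                best = (monitor, [p.value.copy() for p in net.params()])
        if best[1] is not None:
            for p, v in zip(net.params(), best[1]):
                p.value[...] = v
        self.net_ = net
        self.history_ = history
        return self

    def _evaluate(self, net: UNet, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
        losses, ious = [], []
        for i in range(0, len(X), self.batch_size):
            logits = net.forward(X[i : i + self.batch_size])
            loss, _ = self._loss(logits, Y[i : i + self.batch_size])
            losses.append(loss)
            probs = sigmoid(logits)
            for p, t in zip(probs, Y[i : i + self.batch_size]):
                ious.append(iou_score(p[0] > self.threshold, t[0] > 0.5))
        return float(np.mean(losses)), float(np.mean(ious))

    def predict_proba(self, images) -> list[np.ndarray]:
        """Per-pixel grain probabilities at each image's native size."""
        out = []
        for im in images:
            x = _to_net_input(im, self.input_size)[None]
            probs = sigmoid(self.net_.forward(x))[0, 0]
            full = resize(probs.astype(np.float64), np.asarray(im).shape[:2],
                          order=1, preserve_range=True)
            out.append(full)
        return out

    def predict(self, images, threshold: float | None = None) -> list[np.ndarray]:
        thr = self.threshold if threshold is None else threshold
        return [(p > thr).astype(np.uint8) for p in self.predict_proba(images)]

    def score(self, images, masks) -> float:
        """Mean IoU against reference masks."""
        preds = self.predict(images)
        return float(np.mean([iou_score(p, m) for p, m in zip(preds, masks)]))


# -- thin operation-style wrappers ------------------------------------------

def build_segmenter(config: SegmenterConfig) -> GrainSegmenter:
    return GrainSegmenter(**asdict(config))


def load_pairs(manifest) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Load (image, mask) arrays for every record of a manifest."""
    images, masks = [], []
    for rec in manifest.records:
        images.append(iio.imread(rec.image_path))
        if not rec.mask_path:
            raise ValueError(f"record {rec.accession_id}/{rec.replicate} has no mask")
        masks.append((iio.imread(rec.mask_path) > 127).astype(np.uint8))
    return images, masks


def train_segmenter(model: GrainSegmenter, train_manifest, val_manifest=None,
                    config: SegmenterConfig | None = None) -> GrainSegmenter:
    if config is not None:
        model.set_params(**asdict(config))
    if len(train_manifest) == 0:
        raise ValueError("empty training manifest")
    images, masks = load_pairs(train_manifest)
    val_images = val_masks = None
    if val_manifest is not None and len(val_manifest):
        val_images, val_masks = load_pairs(val_manifest)
    return model.fit(images, masks, val_images, val_masks)


def predict_mask(model: GrainSegmenter, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return model.predict([image], threshold=threshold)[0]


def crop_grain_region(image: np.ndarray, mask: np.ndarray, padding: int = 0) -> np.ndarray:
    """Axis-aligned bounding-box crop of the mask foreground, expanded by
    ``padding`` pixels and clipped to the image bounds."""
    fg = np.asarray(mask).astype(bool)
    if not fg.any():
        raise ValueError("cannot crop: mask has no foreground pixels")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    r0 = max(rows[0] - padding, 0)
    r1 = min(rows[-1] + padding + 1, fg.shape[0])
    c0 = max(cols[0] - padding, 0)
    c1 = min(cols[-1] + padding + 1, fg.shape[1])
    return np.asarray(image)[r0:r1, c0:c1]
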