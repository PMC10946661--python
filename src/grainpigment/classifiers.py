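"""The four pigment-composition classifiers and the shared decision rules.

All models emit predictions through the same :class:`PigmentLabel` type via
two routes:

* score thresholding — two numbers in [0, 1] (anthocyanin, melanin
  presence); a pigment is present iff its score is strictly greater than
  the decision threshold (0.5 by default);
* pixel aggregation — for the 2-channel segmentation model, a pigment is
  present iff the fraction of frame pixels segmented as carrying it
  exceeds ``min_fraction`` (0 by default: the any-pixel rule — a single
  positive pixel flags the pigment).

Models:

* ``RF13Classifier`` — color descriptors -> filtering -> z-normalization ->
  PCA to 13 components -> random forest (4-class).
* ``CNNPigmentClassifier`` — residual CNN over the dish-region crop with a
  two-unit sigmoid output.
* ``MultiTaskClassifier`` — U-Net that jointly segments the grain region
  and classifies via a pooled head on the encoder bottleneck
  (EfficientNet-B0-style encoder); joint loss = segmentation + lambda x
  classification.
* ``TwoChannelClassifier`` — U-Net (ResNet-34-style encoder) whose two
  output channels segment anthocyanin- and melanin-carrying pixels; image
  labels come from pixel aggregation.  Pixel supervision is label-broadcast
  (all grain pixels inherit the accession's pigment flags) — a deliberate
  weak-label scheme, since per-pixel chemical truth does not exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler

from .features import FeatureFilter
from .labels import CLASS_CODES, PigmentLabel
from .nn import Adam, ResNetClassifier, UNet, bce_with_logits, minibatches, sigmoid, soft_dice_loss
from .segmentation import NET_IN_CHANNELS, _mask_to_net, _to_net_input

__all__ = [
    "PigmentScores",
    "decide_label",
    "aggregate_pixels",
    "RF13Classifier",
    "CNNPigmentClassifier",
    "MultiTaskClassifier",
    "TwoChannelClassifier",
    "train_rf13",
    "train_cnn_classifier",
    "train_multitask",
    "train_twochannel",
]


@dataclass(frozen=True)
class PigmentScores:
    p_anthocyanin: float
    p_melanin: float

    def __post_init__(self):
        for v in (self.p_anthocyanin, self.p_melanin):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"scores must lie in [0, 1], got {v}")


def decide_label(scores: PigmentScores | tuple[float, float], threshold: float = 0.5) -> PigmentLabel:
    """Map pigment scores to a label: present iff score > threshold (strict).

    Both scores at or below the threshold give NP.
    """
    if isinstance(scores, PigmentScores):
        pa, pm = scores.p_anthocyanin, scores.p_melanin
    else:
        pa, pm = scores
    return PigmentLabel(anthocyanin=pa > threshold, melanin=pm > threshold)


def aggregate_pixels(two_channel_mask: np.ndarray, min_fraction: float = 0.0) -> PigmentLabel:
    """Image label from a 2-channel per-pixel pigment mask.

    A pigment is present iff its channel's positive-pixel fraction of the
    frame is strictly greater than ``min_fraction``; the default 0
    implements the any-pixel rule (one positive pixel suffices).
    """
    m = np.asarray(two_channel_mask)
    if m.ndim != 3 or m.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) mask, got shape {m.shape}")
    frac = m.astype(bool).mean(axis=(1, 2))
    return PigmentLabel(anthocyanin=frac[0] > min_fraction, melanin=frac[1] > min_fraction)


def _as_labels(labels) -> list[PigmentLabel]:
    out = []
    for lab in labels:
        out.append(lab if isinstance(lab, PigmentLabel) else PigmentLabel.from_code(str(lab)))
    return out


# ---------------------------------------------------------------------------
# RF13
# ---------------------------------------------------------------------------

class RF13Classifier(BaseEstimator, ClassifierMixin):
    """Random forest over filtered, normalized, PCA-13 color descriptors.

    The filter mask, normalization statistics, and PCA basis are fitted on
    the training matrix only and stored for transforming new rows.  The
    forest sees exactly ``n_components`` (13) inputs and predicts one of
    the four pigment classes.
    """

    def __init__(self, n_trees: int = 500, n_components: int = 13, seed: int = 0):
        self.n_trees = n_trees
        self.n_components = n_components
        self.seed = seed

    def fit(self, X, y):
        X = pd.DataFrame(X)
        labels = _as_labels(y)
        codes = [lab.code for lab in labels]
        present = set(codes)
        missing = [c for c in CLASS_CODES if c not in present]
        if missing:
            warnings.warn(f"classes absent from training labels: {missing}")
        self.filter_ = FeatureFilter().fit(X)
        Xf = self.filter_.transform(X).to_numpy(dtype=np.float64)
        self.scaler_ = StandardScaler().fit(Xf)
        Xn = self.scaler_.transform(Xf)
        k = min(self.n_components, Xn.shape[0] - 1, Xn.shape[1])
        if k < self.n_components:
            warnings.warn(
                f"training matrix supports only {k} principal components "
                f"(requested {self.n_components})"
            )
        self.pca_ = PCA(n_components=k, svd_solver="full").fit(Xn)
        Z = self.pca_.transform(Xn)
        self.reduced_dim_ = Z.shape[1]
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed
        ).fit(Z, codes)
        return self

    def transform(self, X) -> np.ndarray:
        """The reduced representation actually fed to the forest."""
        Xf = self.filter_.transform(pd.DataFrame(X)).to_numpy(dtype=np.float64)
        return self.pca_.transform(self.scaler_.transform(Xf))

    def predict(self, X) -> list[PigmentLabel]:
        codes = self.forest_.predict(self.transform(X))
        return [PigmentLabel.from_code(c) for c in codes]

    def score(self, X, y) -> float:
        preds = self.predict(X)
        truth = _as_labels(y)
        return float(np.mean([p == t for p, t in zip(preds, truth)]))


# ---------------------------------------------------------------------------
# shared network-training helper
# ---------------------------------------------------------------------------

def _label_targets(labels) -> np.ndarray:
    return np.asarray([lab.as_pair() for lab in _as_labels(labels)], dtype=np.float32)


class _NetClassifierBase(BaseEstimator, ClassifierMixin):
    """Common predict/score plumbing for the score-emitting networks."""

    def predict_scores(self, images) -> np.ndarray:
        """(N, 2) array of (anthocyanin, melanin) scores in [0, 1]."""
        out = []
        for i in range(0, len(images), 8):
            batch = np.stack([_to_net_input(im, self.input_size) for im in images[i : i + 8]])
            out.append(sigmoid(self._class_logits(batch)))
        return np.concatenate(out, axis=0)

    def predict(self, images) -> list[PigmentLabel]:
        return [decide_label(tuple(s), self.threshold) for s in self.predict_scores(images)]

    def score(self, images, y) -> float:
        truth = _as_labels(y)
        preds = self.predict(images)
        return float(np.mean([p == t for p, t in zip(preds, truth)]))


class CNNPigmentClassifier(_NetClassifierBase):
    """Residual CNN classifying dish-region crops by pigment presence.

    Inputs are the rectangular dish crops produced by segmentation, resized
    to ``input_size``; the output layer is two sigmoid units (anthocyanin,
    melanin presence scores).
    """

    def __init__(self, input_size: int = 64, base_width: int = 8, n_stages: int = 3,
                 blocks_per_stage: int = 1, epochs: int = 20, batch_size: int = 8,
                 learning_rate: float = 1e-2, threshold: float = 0.5, seed: int = 0):
        self.input_size = input_size
        self.base_width = base_width
        self.n_stages = n_stages
        self.blocks_per_stage = blocks_per_stage
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.seed = seed

    def build_net(self) -> ResNetClassifier:
        rng = np.random.default_rng(self.seed)
        return ResNetClassifier(rng, in_channels=NET_IN_CHANNELS, base_width=self.base_width,
                                n_stages=self.n_stages,
                                blocks_per_stage=self.blocks_per_stage)

    def fit(self, images, y):
        if len(images) == 0:
            raise ValueError("empty training set")
        T = _label_targets(y)
        X = np.stack([_to_net_input(im, self.input_size) for im in images])
        net = self.build_net()
        opt = Adam(net.params(), lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        history = []
        for _epoch in range(self.epochs):
            losses = []
            for idx in minibatches(len(X), self.batch_size, rng):
                logits = net.forward(X[idx])
                loss, dz = bce_with_logits(logits, T[idx])
                opt.zero_grad()
                net.backward(dz.astype(np.float32))
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.net_ = net
        self.history_ = {"train_loss": history}
        return self

    def _class_logits(self, batch: np.ndarray) -> np.ndarray:
        return self.net_.forward(batch)


class MultiTaskClassifier(_NetClassifierBase):
    """U-Net with a pooled classification head: one forward pass yields both
    a grain mask and the two pigment scores.

    Joint loss = segmentation (BCE + soft Dice) + ``lambda_cls`` x
    classification BCE; ``lambda_cls = 0`` degenerates to pure segmentation
    (the head receives no gradient).  Requires both supervision signals.
    """

    def __init__(self, encoder_family: str = "efficientnet-b0", input_size: int = 64,
                 depth: int = 4, base_width: int = 8, epochs: int = 15,
                 batch_size: int = 1, learning_rate: float = 1e-2,
                 lambda_cls: float = 1.0, threshold: float = 0.5, seed: int = 0):
        self.encoder_family = encoder_family
        self.input_size = input_size
        self.depth = depth
        self.base_width = base_width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lambda_cls = lambda_cls
        self.threshold = threshold
        self.seed = seed

    def build_net(self) -> UNet:
        rng = np.random.default_rng(self.seed)
        return UNet(rng, in_channels=NET_IN_CHANNELS, out_channels=1, depth=self.depth,
                    base_width=self.base_width, encoder_family=self.encoder_family,
                    with_head=True)

    def fit(self, images, masks, y):
        if len(images) == 0:
            raise ValueError("empty training set")
        if masks is None or len(masks) != len(images):
            raise ValueError("the multi-task model requires a region mask per image")
        T = _label_targets(y)
        X = np.stack([_to_net_input(im, self.input_size) for im in images])
        M = np.stack([_mask_to_net(mk, self.input_size) for mk in masks])
        net = self.build_net()
        opt = Adam(net.params(), lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        history = []
        for _epoch in range(self.epochs):
            losses = []
            for idx in minibatches(len(X), self.batch_size, rng):
                seg_logits, cls_logits = net.forward(X[idx])
                l_bce, d_seg = bce_with_logits(seg_logits, M[idx])
                l_dice, d_dice = soft_dice_loss(seg_logits, M[idx])
                l_cls, d_cls = bce_with_logits(cls_logits, T[idx])
                loss = l_bce + l_dice + self.lambda_cls * l_cls
                opt.zero_grad()
                net.backward((d_seg + d_dice).astype(np.float32),
                             (self.lambda_cls * d_cls).astype(np.float32))
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.net_ = net
        self.history_ = {"train_loss": history}
        return self

    def _class_logits(self, batch: np.ndarray) -> np.ndarray:
        _seg, cls = self.net_.forward(batch)
        return cls

    def predict_mask(self, images, threshold: float | None = None) -> list[np.ndarray]:
        from skimage.transform import resize

        thr = self.threshold if threshold is None else threshold
        out = []
        for im in images:
            seg, _cls = self.net_.forward(_to_net_input(im, self.input_size)[None])
            probs = sigmoid(seg)[0, 0]
            full = resize(probs.astype(np.float64), np.asarray(im).shape[:2],
                          order=1, preserve_range=True)
            out.append((full > thr).astype(np.uint8))
        return out

    def forward_pair(self, image) -> tuple[np.ndarray, PigmentScores]:
        """One forward pass: (probability mask at input size, scores)."""
        seg, cls = self.net_.forward(_to_net_input(image, self.input_size)[None])
        s = sigmoid(cls)[0]
        return sigmoid(seg)[0, 0], PigmentScores(float(s[0]), float(s[1]))


class TwoChannelClassifier(BaseEstimator, ClassifierMixin):
    """2-channel pigment segmentation with pixel-aggregation labeling.

    Each output channel segments the pixels carrying one pigment; the image
    label is derived with :func:`aggregate_pixels` (any-pixel rule by
    default).  Supervision is label-broadcast: channel 1 target = grain
    pixels of anthocyanin-containing accessions, channel 2 = grain pixels
    of melanin-containing accessions.
    """

    def __init__(self, encoder_family: str = "resnet34", input_size: int = 64,
                 depth: int = 4, base_width: int = 8, epochs: int = 25,
                 batch_size: int = 1, learning_rate: float = 1e-2,
                 threshold: float = 0.5, min_fraction: float = 0.0, seed: int = 0):
        self.encoder_family = encoder_family
        self.input_size = input_size
        self.depth = depth
        self.base_width = base_width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.min_fraction = min_fraction
        self.seed = seed

    def build_net(self) -> UNet:
        rng = np.random.default_rng(self.seed)
        return UNet(rng, in_channels=NET_IN_CHANNELS, out_channels=2, depth=self.depth,
                    base_width=self.base_width, encoder_family=self.encoder_family)

    @staticmethod
    def make_pixel_targets(region_mask: np.ndarray, label: PigmentLabel, size: int) -> np.ndarray:
        """(2, size, size) weak-label supervision from region mask x label."""
        m = _mask_to_net(region_mask, size)[0]
        return np.stack([m * float(label.anthocyanin), m * float(label.melanin)]).astype(np.float32)

    def fit(self, images, region_masks, y):
        if len(images) == 0:
            raise ValueError("empty training set")
        if region_masks is None or len(region_masks) != len(images):
            raise ValueError("the 2-channel model requires a region mask per image")
        labels = _as_labels(y)
        X = np.stack([_to_net_input(im, self.input_size) for im in images])
        M = np.stack([
            self.make_pixel_targets(mk, lab, self.input_size)
            for mk, lab in zip(region_masks, labels)
        ])
        net = self.build_net()
        opt = Adam(net.params(), lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        history = []
        for _epoch in range(self.epochs):
            losses = []
            for idx in minibatches(len(X), self.batch_size, rng):
                logits = net.forward(X[idx])
                l_bce, d_bce = bce_with_logits(logits, M[idx])
                l_dice, d_dice = soft_dice_loss(logits, M[idx])
                opt.zero_grad()
                net.backward((d_bce + d_dice).astype(np.float32))
                opt.step()
                losses.append(l_bce + l_dice)
            history.append(float(np.mean(losses)))
        self.net_ = net
        self.history_ = {"train_loss": history}
        return self

    def predict_pixel_masks(self, images) -> list[np.ndarray]:
        """Binary (2, input_size, input_size) pigment masks per image."""
        out = []
        for i in range(0, len(images), 8):
            batch = np.stack([_to_net_input(im, self.input_size) for im in images[i : i + 8]])
            probs = sigmoid(self.net_.forward(batch))
            out.extend((p > self.threshold).astype(np.uint8) for p in probs)
        return out

    def predict(self, images) -> list[PigmentLabel]:
        return [aggregate_pixels(m, self.min_fraction) for m in self.predict_pixel_masks(images)]

    def score(self, images, y) -> float:
        truth = _as_labels(y)
        preds = self.predict(images)
        return float(np.mean([p == t for p, t in zip(preds, truth)]))


# -- thin operation-style wrappers ------------------------------------------

def train_rf13(features_train, labels_train, config: dict | None = None) -> RF13Classifier:
    return RF13Classifier(**(config or {})).fit(features_train, labels_train)


def train_cnn_classifier(images_train_cropped, labels, config: dict | None = None) -> CNNPigmentClassifier:
    return CNNPigmentClassifier(**(config or {})).fit(images_train_cropped, labels)


def train_multitask(images, masks, labels, config: dict | None = None) -> MultiTaskClassifier:
    return MultiTaskClassifier(**(config or {})).fit(images, masks, labels)


def train_twochannel(images, pigment_masks, labels, config: dict | None = None) -> TwoChannelClassifier:
    return TwoChannelClassifier(**(config or {})).fit(images, pigment_masks, labels)
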