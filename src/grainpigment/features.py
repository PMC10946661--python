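"""Color descriptors over the masked grain region, filtering, and reduction.

Each image is summarized by 2,380 color descriptors computed over its
grain-region pixels only: for each of the 12 channels of four color spaces
(RGB, HSV, Lab, YCrCb) the channel mean, channel standard deviation, and a
196-bin normalized intensity histogram (198 per channel, 2,376 total), plus
4 whole-region grayscale descriptors (grayscale mean, grayscale SD, the
fraction of pixels darker than 0.1, and the grain-region fraction of the
frame).  All channels are rescaled to [0, 1] before statistics so
thresholds are comparable across color spaces.

Three filtering rules remove uninformative and redundant descriptors, in
fixed order: (1) columns identical across all images; (2) columns whose
value is at most 0.01 in more than 20 % of images; (3) a greedy scan in
descriptor order dropping any column whose |Spearman rank correlation| with
an already-retained column is at least 0.97.  Retained columns are
z-normalized (training statistics only) and, for the RF13 model, projected
onto the leading 13 principal components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import color as skcolor
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "DescriptorExtractor",
    "FeatureFilter",
    "extract_descriptors",
    "filter_features",
    "normalize",
    "pca_reduce",
]

_SPACES = (("rgb", "rgb"), ("hsv", "hsv"), ("lab", "lab"), ("ycrcb", "ycc"))
_CHANNELS = {
    "rgb": ("r", "g", "b"),
    "hsv": ("h", "s", "v"),
    "lab": ("l", "a", "b"),
    "ycrcb": ("y", "cr", "cb"),
}


def _channel_stack(image: np.ndarray) -> dict[str, np.ndarray]:
    """All 12 channels of an 8-bit RGB image, each rescaled to [0, 1]."""
    rgb01 = image.astype(np.float64) / 255.0
    hsv = skcolor.rgb2hsv(rgb01)
    lab = skcolor.rgb2lab(rgb01)
    ycbcr = skcolor.rgb2ycbcr(rgb01)  # Y in [16, 235], Cb/Cr in [16, 240]
    out = {}
    for i, ch in enumerate(_CHANNELS["rgb"]):
        out[f"rgb.{ch}"] = rgb01[..., i]
    for i, ch in enumerate(_CHANNELS["hsv"]):
        out[f"hsv.{ch}"] = hsv[..., i]
    out["lab.l"] = lab[..., 0] / 100.0
    out["lab.a"] = (lab[..., 1] + 128.0) / 255.0
    out["lab.b"] = (lab[..., 2] + 128.0) / 255.0
    out["ycrcb.y"] = ycbcr[..., 0] / 255.0
    out["ycrcb.cr"] = ycbcr[..., 2] / 255.0
    out["ycrcb.cb"] = ycbcr[..., 1] / 255.0
    return out


class DescriptorExtractor:
    """Compute the ordered color-descriptor vector of a masked image.

    Parameters
    ----------
    hist_bins : bins per channel histogram (196 by default, for a total of
        ``12 * (2 + hist_bins) + 4`` descriptors = 2,380).
    dark_threshold : grayscale level below which a pixel counts as dark.
    """

    def __init__(self, hist_bins: int = 196, dark_threshold: float = 0.1):
        self.hist_bins = hist_bins
        self.dark_threshold = dark_threshold

    @property
    def n_features(self) -> int:
        return 12 * (2 + self.hist_bins) + 4

    @property
    def feature_names(self) -> list[str]:
        names = []
        for space, _ in _SPACES:
            for ch in _CHANNELS[space]:
                key = f"{space}.{ch}"
                names.append(f"{key}.mean")
                names.append(f"{key}.sd")
                names.extend(f"{key}.hist_{k:03d}" for k in range(self.hist_bins))
        names += ["gray.mean", "gray.sd", "gray.dark_fraction", "region.area_fraction"]
        return names

    def extract(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Descriptor vector over the mask-foreground pixels of one image.

        ``image`` must be 8-bit RGB ``(H, W, 3)``; ``mask`` a same-size
        boolean/0-1 array with at least one foreground pixel.  Background
        pixels never influence the result.
        """
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError(f"expected an RGB (H, W, 3) image, got shape {image.shape}")
        if image.dtype != np.uint8:
            raise ValueError(f"expected 8-bit RGB input, got dtype {image.dtype}")
        fg = np.asarray(mask).astype(bool)
        if fg.shape != image.shape[:2]:
            raise ValueError("mask shape does not match image")
        if not fg.any():
            raise ValueError("mask has no foreground pixels")

        channels = _channel_stack(image)
        values = np.empty(self.n_features)
        i = 0
        for space, _ in _SPACES:
            for ch in _CHANNELS[space]:
                vals = channels[f"{space}.{ch}"][fg]
                values[i] = vals.mean()
                values[i + 1] = vals.std()
                hist, _edges = np.histogram(vals, bins=self.hist_bins, range=(0.0, 1.0))
                values[i + 2 : i + 2 + self.hist_bins] = hist / hist.sum()
                i += 2 + self.hist_bins
        gray = skcolor.rgb2gray(image.astype(np.float64) / 255.0)[fg]
        values[i] = gray.mean()
        values[i + 1] = gray.std()
        values[i + 2] = (gray < self.dark_threshold).mean()
        values[i + 3] = fg.mean()
        return values

    def extract_batch(self, images, masks, index=None) -> pd.DataFrame:
        rows = [self.extract(im, mk) for im, mk in zip(images, masks)]
        return pd.DataFrame(rows, columns=self.feature_names, index=index)


def extract_descriptors(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Default-configuration descriptor vector and its names."""
    ex = DescriptorExtractor()
    return ex.extract(image, mask), ex.feature_names


class FeatureFilter(BaseEstimator, TransformerMixin):
    """Drop constant, near-zero, and rank-redundant descriptor columns.

    The three rules run in fixed order on the training matrix; the fitted
    column mask is then applied unchanged to any matrix.  Rule 3 scans
    surviving columns in their given order and keeps a column only if its
    absolute Spearman correlation with every already-retained column is
    below ``corr_threshold`` (first-retained-wins), so the retained set is a
    deterministic function of column order and data.

    Fitted attributes: ``support_mask_`` (boolean per input column),
    ``report_`` (DataFrame of dropped columns with the rule that removed
    each and the deciding statistic).
    """

    def __init__(
        self,
        low_value: float = 0.01,
        low_value_fraction: float = 0.20,
        corr_threshold: float = 0.97,
    ):
        self.low_value = low_value
        self.low_value_fraction = low_value_fraction
        self.corr_threshold = corr_threshold

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("feature filtering needs at least 2 rows")
        values = X.to_numpy(dtype=np.float64)
        names = [str(c) for c in X.columns]
        n_rows, n_cols = values.shape
        keep = np.ones(n_cols, dtype=bool)
        dropped: list[tuple[str, str, float]] = []

        # rule 1: identical for all images
        const = values.min(axis=0) == values.max(axis=0)
        for j in np.flatnonzero(const):
            dropped.append((names[j], "constant", float(values[0, j])))
        keep &= ~const

        # rule 2: value <= low_value in (strictly) more than 20 % of images
        low_frac = (values <= self.low_value).mean(axis=0)
        rule2 = keep & (low_frac > self.low_value_fraction)
        for j in np.flatnonzero(rule2):
            dropped.append((names[j], "near_zero", float(low_frac[j])))
        keep &= ~rule2

        # rule 3: greedy Spearman redundancy scan, first-retained-wins
        surv = np.flatnonzero(keep)
        if surv.size > 1:
            from scipy.stats import rankdata

            ranks = rankdata(values[:, surv], axis=0)  # average ranks for ties
            ranks = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0)
            corr = np.abs(ranks.T @ ranks) / n_rows
            retained: list[int] = []
            for local_j in range(surv.size):
                rho = corr[local_j, retained].max(initial=0.0)
                if rho >= self.corr_threshold:
                    dropped.append((names[surv[local_j]], "spearman", float(rho)))
                    keep[surv[local_j]] = False
                else:
                    retained.append(local_j)

        self.support_mask_ = keep
        self.feature_names_in_ = np.asarray(names)
        self.report_ = pd.DataFrame(dropped, columns=["column", "rule", "statistic"])
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        if X.shape[1] != self.support_mask_.size:
            raise ValueError(
                f"expected {self.support_mask_.size} columns, got {X.shape[1]}"
            )
        return X.loc[:, self.support_mask_]

    def get_support(self) -> np.ndarray:
        return self.support_mask_


def filter_features(matrix) -> tuple[pd.DataFrame, FeatureFilter]:
    """Apply the three filtering rules; return the reduced matrix and the
    fitted filter (whose ``report_`` lists every dropped column)."""
    f = FeatureFilter().fit(matrix)
    return f.transform(matrix), f


def normalize(matrix) -> tuple[pd.DataFrame, StandardScaler]:
    """Column-wise z-scores; the fitted scaler re-applies the training
    transform to validation/test/holdout rows."""
    matrix = pd.DataFrame(matrix)
    scaler = StandardScaler().fit(matrix.to_numpy(dtype=np.float64))
    out = pd.DataFrame(
        scaler.transform(matrix.to_numpy(dtype=np.float64)),
        index=matrix.index,
        columns=matrix.columns,
    )
    return out, scaler


def pca_reduce(matrix, k: int = 13) -> tuple[np.ndarray, PCA]:
    """Project onto the leading ``k`` principal components of the matrix."""
    matrix = pd.DataFrame(matrix)
    n, p = matrix.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(rows - 1, columns) = {min(n - 1, p)}")
    pca = PCA(n_components=k, svd_solver="full").fit(matrix.to_numpy(dtype=np.float64))
    return pca.transform(matrix.to_numpy(dtype=np.float64)), pca
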