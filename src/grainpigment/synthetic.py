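"""Synthetic dish-image generator.

Emulates the acquisition protocol the pipeline was designed for: a circular
Petri dish densely packed with 100-160 convex grains, photographed from
above on a light background, with 9 replicate images per accession obtained
by re-randomizing grain placement.  The four pigment classes (NP / A / M /
AM) are realized as distinct but partially overlapping HSV color palettes
(tan-yellow; purple-blue; gray-black; dark purple-black), and a
hulled/hulless factor shifts color within each class.  Because the
generator paints the grains itself, it emits exact ground-truth region
masks, so every downstream stage (segmentation, descriptor extraction,
classification) is trainable and testable offline.

Everything is a pure function of its parameters and seed: identical
arguments yield byte-identical specs, images, and manifests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .labels import CLASS_CODES, PigmentLabel

__all__ = [
    "Palette",
    "AccessionSpec",
    "RenderConfig",
    "PackingError",
    "make_accession",
    "render_replicate",
    "generate_dataset",
]


class PackingError(RuntimeError):
    """Raised when the requested grain count cannot be placed in the dish."""


@dataclass(frozen=True)
class Palette:
    """Per-accession HSV color distribution (all channels in [0, 1]).

    Grain colors are drawn as independent Gaussians around the three means,
    clipped to the valid range; hue wraps.
    """

    hue_mean: float
    hue_sd: float
    sat_mean: float
    sat_sd: float
    val_mean: float
    val_sd: float

    def sample_hsv(self, rng: np.random.Generator) -> tuple[float, float, float]:
        h = (self.hue_mean + rng.normal(0.0, self.hue_sd)) % 1.0
        s = float(np.clip(self.sat_mean + rng.normal(0.0, self.sat_sd), 0.0, 1.0))
        v = float(np.clip(self.val_mean + rng.normal(0.0, self.val_sd), 0.0, 1.0))
        return h, s, v

    def mean_rgb(self) -> np.ndarray:
        return _hsv_to_rgb(self.hue_mean, self.sat_mean, self.val_mean)


# Base palettes: (hue, sat, value) means per pigment class.  NP is
# tan-yellow; A purple-blue; M near-achromatic dark; AM shares A's hue
# support at M's dark value range, so AM overlaps both parents.
_BASE_HSV: dict[str, tuple[float, float, float]] = {
    "NP": (0.12, 0.38, 0.82),
    "A": (0.70, 0.55, 0.45),
    "M": (0.66, 0.10, 0.20),
    "AM": (0.72, 0.45, 0.18),
}

# "Hard mode" narrows the A-vs-AM and M-vs-AM palette gaps to reproduce the
# confusion structure observed on real grains (AM vs M is hardest).
_HARD_HSV: dict[str, tuple[float, float, float]] = {
    "NP": (0.12, 0.38, 0.82),
    "A": (0.70, 0.50, 0.42),
    "M": (0.69, 0.22, 0.26),
    "AM": (0.70, 0.38, 0.30),
}

_WITHIN_GRAIN_SD = (0.015, 0.05, 0.04)  # hue, sat, val spread across grains
_ACCESSION_JITTER = (0.010, 0.03, 0.03)  # accession-level palette offset
_HULLED_SHIFT = (0.0, -0.08, 0.08)  # hull raises value, lowers saturation


@dataclass(frozen=True)
class AccessionSpec:
    """Everything needed to render replicate images of one accession."""

    accession_id: str
    pigment_label: PigmentLabel
    hulled: bool
    palette: Palette
    grain_count_range: tuple[int, int] = (100, 160)
    # grain geometry: aspect = minor/major axis ratio; size jitter is the
    # relative SD of the per-grain area around the packing-derived mean
    aspect_mean: float = 0.55
    aspect_sd: float = 0.06
    size_jitter: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.grain_count_range
        if not (100 <= lo <= hi <= 160):
            raise ValueError(
                f"grain_count_range {self.grain_count_range} must lie within [100, 160]"
            )


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters shared across accessions."""

    image_size: int = 256
    dish_radius_fraction: float = 0.45  # dish radius / image side
    background_color: tuple[int, int, int] = (235, 233, 228)
    noise_sigma: float = 3.0  # per-pixel Gaussian, 8-bit units
    lighting_amplitude: float = 0.08  # per-grain linear shading, fractional
    replicates_per_accession: int = 9
    fill_fraction: float = 0.55  # target grain area / dish area
    max_overlap: float = 0.15  # allowed overlap fraction per placed grain
    hard_mode: bool = False

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if not (0.0 < self.dish_radius_fraction <= 0.5):
            raise ValueError("dish must fit fully inside the frame")
        if self.replicates_per_accession < 1:
            raise ValueError("replicates_per_accession must be >= 1")


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    """Scalar HSV -> RGB in [0, 1]."""
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.asarray(rgb, dtype=np.float64)


def _stable_seed(*parts: object) -> int:
    """Deterministic 31-bit seed from a tuple of printable parts."""
    return zlib.crc32("|".join(repr(p) for p in parts).encode()) & 0x7FFFFFFF


def make_accession(
    pigment_label: PigmentLabel | str,
    hulled: bool,
    seed: int,
    *,
    accession_id: str | None = None,
    grain_count_range: tuple[int, int] = (100, 160),
    hard_mode: bool = False,
) -> AccessionSpec:
    """Create a fully populated accession spec.

    The palette is a deterministic function of (pigment_label, hulled,
    seed): the class base palette, shifted by the hull factor, plus a small
    accession-level jitter drawn from a seed-derived generator.
    """
    if isinstance(pigment_label, str):
        pigment_label = PigmentLabel.from_code(pigment_label)
    code = pigment_label.code
    base = (_HARD_HSV if hard_mode else _BASE_HSV)[code]
    rng = np.random.default_rng(_stable_seed("palette", code, hulled, seed))
    jit = rng.normal(0.0, 1.0, size=3) * np.asarray(_ACCESSION_JITTER)
    h = (base[0] + jit[0]) % 1.0
    s = float(np.clip(base[1] + jit[1] + (_HULLED_SHIFT[1] if hulled else 0.0), 0.02, 1.0))
    v = float(np.clip(base[2] + jit[2] + (_HULLED_SHIFT[2] if hulled else 0.0), 0.02, 1.0))
    palette = Palette(h, _WITHIN_GRAIN_SD[0], s, _WITHIN_GRAIN_SD[1], v, _WITHIN_GRAIN_SD[2])
    if accession_id is None:
        accession_id = f"{code}{'H' if hulled else 'U'}{seed:05d}"
    return AccessionSpec(
        accession_id=accession_id,
        pigment_label=pigment_label,
        hulled=hulled,
        palette=palette,
        grain_count_range=grain_count_range,
        seed=seed,
    )


def render_replicate(
    spec: AccessionSpec,
    config: RenderConfig,
    replicate_seed: int,
) -> tuple[np.ndarray, np.ndarray, PigmentLabel]:
    """Render one replicate image of an accession.

    Grains are filled ellipses with jittered orientation, placed by
    rejection sampling inside the dish circle with bounded overlap against
    already-placed grains (near-tiling packing, not physical simulation).
    Different replicate seeds permute grain placement but not the palette.

    Returns ``(image, mask, label)``: an ``(H, W, 3)`` uint8 RGB image, an
    ``(H, W)`` uint8 mask (1 = grain), and the accession's pigment label.

    Raises
    ------
    PackingError
        If the drawn grain count cannot be placed within the overlap bound
        (count too high for the dish area).
    """
    size = config.image_size
    rng = np.random.default_rng(_stable_seed("render", spec.accession_id, spec.seed, replicate_seed))
    dish_r = config.dish_radius_fraction * size
    center = (size / 2.0, size / 2.0)

    canvas = np.empty((size, size, 3), dtype=np.float64)
    canvas[:] = np.asarray(config.background_color, dtype=np.float64)
    # faint dish disk so the dish region is visible against the paper
    rr, cc = draw_disk(center, dish_r, shape=(size, size))
    canvas[rr, cc] *= 0.985

    mask = np.zeros((size, size), dtype=bool)

    lo, hi = spec.grain_count_range
    count = int(rng.integers(lo, hi + 1))
    dish_area = np.pi * dish_r * dish_r
    mean_area = config.fill_fraction * dish_area / count

    # draw all grain sizes up front and place the largest first: late
    # placements are then the easiest, which keeps rejection sampling
    # feasible at dense packing
    areas = mean_area * np.clip(
        1.0 + rng.normal(0.0, spec.size_jitter, size=count), 0.5, 1.6
    )
    aspects = np.clip(
        rng.normal(spec.aspect_mean, spec.aspect_sd, size=count), 0.35, 0.9
    )
    order = np.argsort(-areas)

    placed = 0
    for gi in order:
        area, aspect = areas[gi], aspects[gi]
        a = np.sqrt(area / (np.pi * aspect))  # major semi-axis
        b = a * aspect
        ok = False
        for attempt in range(300):
            if attempt and attempt % 100 == 0:
                # crowded dish: let the grain settle smaller (bounded shrink,
                # never dropped silently)
                a *= 0.85
                b *= 0.85
            theta = rng.uniform(0.0, np.pi)
            # keep the whole ellipse inside the dish circle
            rad = rng.uniform(0.0, max(dish_r - a, 1.0))
            ang = rng.uniform(0.0, 2 * np.pi)
            cy = center[0] + rad * np.sin(ang)
            cx = center[1] + rad * np.cos(ang)
            gr, gc = draw_ellipse(cy, cx, a, b, rotation=theta, shape=(size, size))
            if gr.size < 3:
                continue
            overlap = mask[gr, gc].mean()
            if overlap <= config.max_overlap:
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place grain {placed + 1}/{count} of "
                f"{spec.accession_id!r}: count too high for dish area at "
                f"overlap bound {config.max_overlap}"
            )
        hsv = spec.palette.sample_hsv(rng)
        color = _hsv_to_rgb(*hsv) * 255.0
        shade = np.ones(gr.size)
        if config.lighting_amplitude > 0:
            # linear shading across the grain along a random direction
            direction = rng.uniform(0.0, 2 * np.pi)
            proj = (gr - cy) * np.sin(direction) + (gc - cx) * np.cos(direction)
            span = max(float(np.abs(proj).max()), 1e-9)
            shade = 1.0 + config.lighting_amplitude * proj / span
        canvas[gr, gc] = color[None, :] * shade[:, None]
        mask[gr, gc] = True
        placed += 1

    if config.noise_sigma > 0:
        canvas += rng.normal(0.0, config.noise_sigma, size=canvas.shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)
    return image, mask.astype(np.uint8), spec.pigment_label


def _normalize_counts(
    counts: dict, hulled_fraction: float
) -> list[tuple[str, bool, int]]:
    """Expand class counts into (code, hulled, n) triples.

    ``counts`` maps either class code -> n (split by ``hulled_fraction``,
    hulled count rounded to nearest) or (code, hulled) -> n.
    """
    out: list[tuple[str, bool, int]] = []
    for key, n in counts.items():
        if n < 0:
            raise ValueError("accession counts must be >= 0")
        if isinstance(key, tuple):
            code, hulled = key
            out.append((PigmentLabel.from_code(code).code, bool(hulled), int(n)))
        else:
            code = PigmentLabel.from_code(key).code
            n_h = int(round(hulled_fraction * n))
            out.append((code, True, n_h))
            out.append((code, False, int(n) - n_h))
    return [(c, h, n) for c, h, n in out if n > 0]


def generate_dataset(
    counts: dict,
    config: RenderConfig,
    seed: int,
    out_dir,
    *,
    hulled_fraction: float = 0.73,
):
    """Generate a full synthetic dataset and write it to ``out_dir``.

    Renders ``replicates_per_accession`` images per accession, writes
    ``images/<accession>/<replicate>.png`` and 0/255 masks under
    ``masks/``, and returns a :class:`~grainpigment.manifest.DatasetManifest`
    (also saved as ``manifest.csv``).

    ``counts`` maps pigment class code -> number of accessions (split into
    hulled/hulless by ``hulled_fraction``) or (code, hulled) -> number.
    Generation is a pure function of (counts, config, seed).
    """
    from pathlib import Path

    import imageio.v3 as iio

    from .manifest import DatasetManifest, ManifestRecord

    triples = _normalize_counts(counts, hulled_fraction)
    if sum(n for _, _, n in triples) == 0:
        raise ValueError("zero total accessions requested")

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    records: list[ManifestRecord] = []
    acc_index = 0
    for code, hulled, n in sorted(triples):
        for i in range(n):
            acc_seed = _stable_seed("accession", seed, code, hulled, i)
            spec = make_accession(
                code,
                hulled,
                acc_seed,
                accession_id=f"{code}{'H' if hulled else 'U'}{acc_index:03d}",
                hard_mode=config.hard_mode,
            )
            img_dir = out_dir / "images" / spec.accession_id
            msk_dir = out_dir / "masks" / spec.accession_id
            img_dir.mkdir(exist_ok=True)
            msk_dir.mkdir(exist_ok=True)
            for rep in range(config.replicates_per_accession):
                image, mask, label = render_replicate(spec, config, replicate_seed=rep)
                img_path = img_dir / f"{rep}.png"
                msk_path = msk_dir / f"{rep}.png"
                iio.imwrite(img_path, image)
                iio.imwrite(msk_path, (mask * 255).astype(np.uint8))
                records.append(
                    ManifestRecord(
                        accession_id=spec.accession_id,
                        pigment_label=label,
                        hulled=hulled,
                        replicate=rep,
                        image_path=str(img_path),
                        mask_path=str(msk_path),
                    )
                )
            acc_index += 1

    manifest = DatasetManifest(records)
    manifest.save(out_dir / "manifest.csv")
    return manifest
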