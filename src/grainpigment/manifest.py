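"""Dataset manifests, LabelMe annotations, and accession-level splitting.

The accession (a distinct germplasm line) is the unit of labeling and of
train/validation/test partitioning: all 9 replicate images of an accession
share one pigment label, one hull flag, and one split, so no accession ever
leaks across splits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import PigmentLabel

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "parse_labelme",
    "rasterize_polygon",
    "stratified_split",
    "load_manifest",
    "save_manifest",
]

REQUIRED_COLUMNS = (
    "accession_id",
    "pigment_label",
    "hulled",
    "replicate",
    "image_path",
    "mask_path",
)

SPLITS = ("train", "val", "test", "holdout")


@dataclass(frozen=True)
class ManifestRecord:
    accession_id: str
    pigment_label: PigmentLabel
    hulled: bool
    replicate: int
    image_path: str
    mask_path: str = ""


class DatasetManifest:
    """Accession records plus an optional accession -> split assignment.

    Invariants checked at construction: all replicates of one accession
    share one pigment label and hull flag, and replicate indices are unique
    within an accession.
    """

    def __init__(
        self,
        records: list[ManifestRecord],
        split_assignment: dict[str, str] | None = None,
    ):
        seen: dict[tuple[str, int], None] = {}
        meta: dict[str, tuple[PigmentLabel, bool]] = {}
        for rec in records:
            key = (rec.accession_id, rec.replicate)
            if key in seen:
                raise ValueError(f"duplicate (accession, replicate) record: {key}")
            seen[key] = None
            prev = meta.get(rec.accession_id)
            if prev is None:
                meta[rec.accession_id] = (rec.pigment_label, rec.hulled)
            elif prev != (rec.pigment_label, rec.hulled):
                raise ValueError(
                    f"inconsistent label/hull flag within accession {rec.accession_id!r}"
                )
        if split_assignment:
            for acc, split in split_assignment.items():
                if split not in SPLITS:
                    raise ValueError(f"unknown split {split!r} for accession {acc!r}")
        self.records = list(records)
        self.split_assignment = dict(split_assignment or {})

    # -- views ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def accession_ids(self) -> list[str]:
        out, seen = [], set()
        for rec in self.records:
            if rec.accession_id not in seen:
                seen.add(rec.accession_id)
                out.append(rec.accession_id)
        return out

    def accession_meta(self) -> dict[str, tuple[PigmentLabel, bool]]:
        return {rec.accession_id: (rec.pigment_label, rec.hulled) for rec in self.records}

    def subset(self, split: str) -> "DatasetManifest":
        recs = [
            r for r in self.records if self.split_assignment.get(r.accession_id) == split
        ]
        return DatasetManifest(recs, {r.accession_id: split for r in recs})

    def with_holdout(self, accession_ids) -> "DatasetManifest":
        """Designate accessions as holdout (an input list, not a random bin)."""
        ids = set(accession_ids)
        missing = ids - set(self.accession_ids())
        if missing:
            raise ValueError(f"holdout accessions not in manifest: {sorted(missing)}")
        assignment = dict(self.split_assignment)
        assignment.update({a: "holdout" for a in ids})
        return DatasetManifest(self.records, assignment)

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "accession_id": rec.accession_id,
                    "pigment_label": rec.pigment_label.code,
                    "hulled": rec.hulled,
                    "replicate": rec.replicate,
                    "image_path": rec.image_path,
                    "mask_path": rec.mask_path,
                    "split": self.split_assignment.get(rec.accession_id, ""),
                }
            )
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DatasetManifest":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest is missing required columns: {missing}")
        records = []
        assignment: dict[str, str] = {}
        for row in df.itertuples(index=False):
            records.append(
                ManifestRecord(
                    accession_id=str(row.accession_id),
                    pigment_label=PigmentLabel.from_code(str(row.pigment_label)),
                    hulled=_as_bool(row.hulled),
                    replicate=int(row.replicate),
                    image_path=str(row.image_path),
                    mask_path="" if pd.isna(row.mask_path) else str(row.mask_path),
                )
            )
            split = getattr(row, "split", "")
            if isinstance(split, str) and split:
                assignment[str(row.accession_id)] = split
        return cls(records, assignment)

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        return cls.from_frame(pd.read_csv(path))


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return bool(x)


def load_manifest(path) -> DatasetManifest:
    return DatasetManifest.load(path)


def save_manifest(manifest: DatasetManifest, path) -> None:
    manifest.save(path)


# ---------------------------------------------------------------------------
# LabelMe polygon annotations
# ---------------------------------------------------------------------------

def rasterize_polygon(points, image_size: tuple[int, int]) -> np.ndarray:
    """Rasterize one polygon to a boolean mask.

    ``points`` are LabelMe ``(x, y)`` vertices in image coordinates.  Pixel
    ``(r, c)`` is foreground iff its center ``(x=c, y=r)`` lies inside the
    polygon under the even-odd rule with half-open edge semantics (an
    axis-aligned square of side ``s`` covers exactly ``s * s`` pixels).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError(f"polygon needs >= 3 (x, y) vertices, got shape {pts.shape}")
    h, w = image_size
    X, Y = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    inside = np.zeros((h, w), dtype=bool)
    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ax1, ay1, ax2, ay2 in zip(x1, y1, x2, y2):
        if ay1 == ay2:
            continue
        crosses = (ay1 <= Y) != (ay2 <= Y)
        x_int = ax1 + (Y - ay1) * (ax2 - ax1) / (ay2 - ay1)
        inside ^= crosses & (X < x_int)
    return inside


def parse_labelme(
    doc,
    image_size: tuple[int, int],
    *,
    label: str = "grain",
    known_labels: tuple[str, ...] = ("grain", "dish"),
) -> np.ndarray:
    """Rasterize the polygons of one LabelMe annotation document.

    ``doc`` may be a path to a LabelMe JSON file or an already-parsed dict
    with a ``shapes`` list of ``{"label": ..., "points": [[x, y], ...]}``.
    All polygons carrying ``label`` are unioned into one boolean mask of
    shape ``image_size``.  Unknown shape labels produce a warning and are
    skipped; a polygon with fewer than 3 vertices is an error.
    """
    if isinstance(doc, (str, Path)):
        with open(doc) as fh:
            doc = json.load(fh)
    mask = np.zeros(image_size, dtype=bool)
    for shape in doc.get("shapes", []):
        shape_label = shape.get("label", "")
        if shape_label not in known_labels:
            warnings.warn(f"skipping shape with unknown label {shape_label!r}")
            continue
        if shape_label != label:
            continue
        pts = shape.get("points", [])
        if len(pts) < 3:
            raise ValueError(
                f"polygon for label {shape_label!r} has {len(pts)} vertices (< 3)"
            )
        mask |= rasterize_polygon(pts, image_size)
    return mask


# ---------------------------------------------------------------------------
# Accession-level stratified splitting
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    quota = total * fractions
    base = np.floor(quota).astype(int)
    rem = quota - base
    extra = total - base.sum()
    order = np.argsort(-rem, kind="stable")
    base[order[:extra]] += 1
    return base


def stratified_split(
    manifest: DatasetManifest,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetManifest:
    """Assign accessions to train/val/test, stratified by class x hull.

    The splitting unit is the accession — never the image — so all
    replicates follow their accession.  Global bin sizes follow
    largest-remainder apportionment of the accession total (79 accessions at
    60/20/20 give exactly 47/16/16); within that constraint seats are dealt
    to strata (pigment class x hull status) by largest remainder, and
    accessions are shuffled within each stratum by ``seed``.  Accessions
    already designated ``holdout`` keep that designation and are excluded.
    """
    fracs = np.asarray(fractions, dtype=np.float64)
    if fracs.ndim != 1 or len(fracs) != 3 or (fracs < 0).any():
        raise ValueError("fractions must be three non-negative numbers")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fracs.sum()}")

    meta = manifest.accession_meta()
    holdout = {a for a, s in manifest.split_assignment.items() if s == "holdout"}
    accessions = [a for a in manifest.accession_ids() if a not in holdout]
    if not accessions:
        raise ValueError("no accessions to split")

    strata: dict[tuple[str, bool], list[str]] = {}
    for acc in accessions:
        label, hulled = meta[acc]
        strata.setdefault((label.code, hulled), []).append(acc)

    n_bins_nonzero = int((fracs > 0).sum())
    for key, members in strata.items():
        if len(members) < n_bins_nonzero:
            warnings.warn(
                f"stratum {key} has {len(members)} accessions, fewer than the "
                f"{n_bins_nonzero} nonzero split bins; assigning by rounding priority"
            )

    bin_targets = _largest_remainder(len(accessions), fracs)

    # per-stratum floors, then deal the remaining seats by remainder size
    # under the global per-bin targets
    keys = sorted(strata)
    counts = {k: np.zeros(3, dtype=int) for k in keys}
    bin_totals = np.zeros(3, dtype=int)
    remainders: list[tuple[float, str, int]] = []  # (-rem, stratum, bin)
    for k in keys:
        quota = len(strata[k]) * fracs
        base = np.floor(quota).astype(int)
        counts[k] = base
        bin_totals += base
        for b in range(3):
            remainders.append((-(quota[b] - base[b]), k, b))
    remainders.sort(key=lambda t: (t[0], str(t[1]), t[2]))
    need = {k: len(strata[k]) - counts[k].sum() for k in keys}
    for _negrem, k, b in remainders:
        if need[k] > 0 and bin_totals[b] < bin_targets[b]:
            counts[k][b] += 1
            bin_totals[b] += 1
            need[k] -= 1
    # any seats still owed (bin already at target): place in bins with slack
    for k in keys:
        while need[k] > 0:
            b = int(np.argmax(bin_targets - bin_totals))
            counts[k][b] += 1
            bin_totals[b] += 1
            need[k] -= 1

    rng = np.random.default_rng(seed)
    assignment = {a: "holdout" for a in holdout}
    for k in keys:
        members = list(strata[k])
        rng.shuffle(members)
        i = 0
        for b, name in enumerate(("train", "val", "test")):
            for acc in members[i : i + counts[k][b]]:
                assignment[acc] = name
            i += counts[k][b]
    return DatasetManifest(manifest.records, assignment)
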