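"""Manifest round trips, LabelMe rasterization, and stratified splitting."""

import numpy as np
import pandas as pd
import pytest

from grainpigment.labels import PigmentLabel
from grainpigment.manifest import (
    DatasetManifest,
    ManifestRecord,
    parse_labelme,
    rasterize_polygon,
    stratified_split,
)

from conftest import build_manifest


# ---------------------------------------------------------------------------
# LabelMe parsing
# ---------------------------------------------------------------------------

def _point_in_polygon(x: float, y: float, pts) -> bool:
    """Scalar even-odd ray cast with half-open edges (independent oracle)."""
    inside = False
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 <= y) != (y2 <= y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


def test_empty_document_gives_all_background():
    mask = parse_labelme({"shapes": []}, (16, 16))
    assert mask.shape == (16, 16) and not mask.any()


@pytest.mark.parametrize("pts", [
    [(2, 2), (7, 2), (7, 7), (2, 7)],                      # axis-aligned square
    [(1.5, 3.2), (12.7, 1.1), (10.3, 11.8), (3.0, 9.5)],    # irregular quad
    [(8, 1), (14, 8), (8, 15), (2, 8)],                     # diamond
])
def test_rasterization_matches_pixel_scan_oracle(pts):
    mask = rasterize_polygon(pts, (16, 16))
    oracle = np.array([[_point_in_polygon(c, r, pts) for c in range(16)]
                       for r in range(16)])
    assert np.array_equal(mask, oracle)


def test_axis_aligned_square_covers_side_squared_pixels():
    mask = rasterize_polygon([(2, 2), (7, 2), (7, 7), (2, 7)], (16, 16))
    assert mask.sum() == 25


def test_overlapping_polygons_union_counted_once():
    doc = {"shapes": [
        {"label": "grain", "points": [[0, 0], [6, 0], [6, 6], [0, 6]]},
        {"label": "grain", "points": [[3, 3], [9, 3], [9, 9], [3, 9]]},
    ]}
    mask = parse_labelme(doc, (12, 12))
    a = rasterize_polygon([(0, 0), (6, 0), (6, 6), (0, 6)], (12, 12))
    b = rasterize_polygon([(3, 3), (9, 3), (9, 9), (3, 9)], (12, 12))
    assert np.array_equal(mask, a | b)


def test_degenerate_polygon_rejected_and_unknown_label_skipped():
    with pytest.raises(ValueError, match="< 3"):
        parse_labelme({"shapes": [{"label": "grain", "points": [[0, 0], [1, 1]]}]}, (8, 8))
    with pytest.warns(UserWarning, match="unknown label"):
        mask = parse_labelme(
            {"shapes": [{"label": "stone", "points": [[0, 0], [4, 0], [4, 4]]}]}, (8, 8)
        )
    assert not mask.any()


def test_dish_polygons_do_not_enter_grain_mask():
    doc = {"shapes": [{"label": "dish", "points": [[0, 0], [7, 0], [7, 7], [0, 7]]}]}
    assert not parse_labelme(doc, (8, 8)).any()


def test_labelme_file_round_trip(tmp_path):
    import json

    doc = {"shapes": [{"label": "grain", "points": [[1, 1], [5, 1], [5, 5], [1, 5]]}]}
    path = tmp_path / "ann.json"
    path.write_text(json.dumps(doc))
    assert parse_labelme(path, (8, 8)).sum() == 16


# ---------------------------------------------------------------------------
# Manifest container and CSV round trip
# ---------------------------------------------------------------------------

def test_manifest_round_trip(tmp_path, manifest_79):
    split = stratified_split(manifest_79, seed=3)
    path = tmp_path / "m.csv"
    split.save(path)
    loaded = DatasetManifest.load(path)
    assert loaded.to_frame().equals(split.to_frame())
    assert loaded.split_assignment == split.split_assignment


def test_duplicate_replicate_rejected_with_key():
    rec = ManifestRecord("ACC1", PigmentLabel(False, False), False, 0, "a.png")
    with pytest.raises(ValueError, match=r"\('ACC1', 0\)"):
        DatasetManifest([rec, rec])


def test_inconsistent_accession_metadata_rejected():
    recs = [
        ManifestRecord("ACC1", PigmentLabel(False, False), False, 0, "a.png"),
        ManifestRecord("ACC1", PigmentLabel(True, False), False, 1, "b.png"),
    ]
    with pytest.raises(ValueError, match="inconsistent"):
        DatasetManifest(recs)


def test_missing_column_rejected(tmp_path):
    df = pd.DataFrame({"accession_id": ["a"], "pigment_label": ["NP"]})
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="missing required columns"):
        DatasetManifest.load(path)


def test_29_accessions_by_9_replicates_is_261_images():
    manifest = build_manifest({("NP", True): 10, ("A", False): 10, ("M", True): 9})
    assert len(manifest.accession_ids()) == 29
    assert len(manifest) == 261


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 17])
def test_split_arithmetic_79_accessions(manifest_79, seed):
    split = stratified_split(manifest_79, (0.6, 0.2, 0.2), seed)
    assert [len(split.subset(s).accession_ids()) for s in ("train", "val", "test")] == [47, 16, 16]
    assert [len(split.subset(s)) for s in ("train", "val", "test")] == [423, 144, 144]


def test_no_accession_leaks_and_replicates_follow(manifest_79):
    split = stratified_split(manifest_79, seed=5)
    seen = {}
    for s in ("train", "val", "test"):
        for rec in split.subset(s).records:
            assert seen.setdefault(rec.accession_id, s) == s
    # split image counts are 9 x accession counts (complete replicates)
    for s in ("train", "val", "test"):
        assert len(split.subset(s)) == 9 * len(split.subset(s).accession_ids())


def test_degenerate_fraction_puts_everything_in_train(manifest_79):
    split = stratified_split(manifest_79, (1.0, 0.0, 0.0), seed=0)
    assert len(split.subset("train").accession_ids()) == 79


def test_split_is_deterministic(manifest_79):
    a = stratified_split(manifest_79, seed=9).split_assignment
    b = stratified_split(manifest_79, seed=9).split_assignment
    assert a == b
    assert a != stratified_split(manifest_79, seed=10).split_assignment


def test_tiny_stratum_warns_but_assigns():
    manifest = build_manifest({("NP", True): 2, ("A", False): 10, ("M", True): 10})
    with pytest.warns(UserWarning, match="fewer than"):
        split = stratified_split(manifest, seed=0)
    assert set(split.split_assignment) == set(manifest.accession_ids())


def test_holdout_designation_is_preserved(manifest_79):
    ids = manifest_79.accession_ids()[:5]
    withheld = manifest_79.with_holdout(ids)
    split = stratified_split(withheld, seed=2)
    assert all(split.split_assignment[a] == "holdout" for a in ids)
    assert len(split.subset("train").accession_ids()) + len(
        split.subset("val").accession_ids()
    ) + len(split.subset("test").accession_ids()) == 74


def test_bad_fractions_rejected(manifest_79):
    with pytest.raises(ValueError, match="sum to 1"):
        stratified_split(manifest_79, (0.5, 0.2, 0.2), seed=0)
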