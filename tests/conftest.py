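"""Shared fixtures: in-memory synthetic datasets used across test modules.

All fixtures are generated programmatically from the synthetic renderer, so
the suite carries no stored image data.
"""

from __future__ import annotations

import numpy as np
import pytest

from grainpigment.labels import CLASS_CODES
from grainpigment.manifest import DatasetManifest, ManifestRecord
from grainpigment.labels import PigmentLabel
from grainpigment.synthetic import RenderConfig, make_accession, render_replicate


@pytest.fixture(scope="session")
def small_dataset():
    """In-memory classification benchmark: 4 classes x 6 accessions x 3
    replicates at 96 px (alternating hull status), split by accession into
    60 training and 12 test images."""
    cfg = RenderConfig(image_size=96)
    data = {"train": ([], [], []), "test": ([], [], [])}
    for code in CLASS_CODES:
        for s in range(6):
            spec = make_accession(code, s % 2 == 0, s)
            part = "train" if s < 5 else "test"
            for rep in range(3):
                image, mask, label = render_replicate(spec, cfg, rep)
                data[part][0].append(image)
                data[part][1].append(mask)
                data[part][2].append(label)
    return {
        "train_images": data["train"][0],
        "train_masks": data["train"][1],
        "train_labels": data["train"][2],
        "test_images": data["test"][0],
        "test_masks": data["test"][1],
        "test_labels": data["test"][2],
    }


@pytest.fixture(scope="session")
def seg_dataset():
    """24 dish images at 128 px for segmentation training/validation/test."""
    cfg = RenderConfig(image_size=128)
    images, masks = [], []
    for s in range(6):  # class-interleaved so any prefix covers all classes
        for code in CLASS_CODES:
            spec = make_accession(code, s % 2 == 0, s)
            image, mask, _ = render_replicate(spec, cfg, 0)
            images.append(image)
            masks.append(mask)
    return images, masks


@pytest.fixture(scope="session")
def one_render():
    """A single rendered (image, mask, label) triple at 96 px."""
    cfg = RenderConfig(image_size=96)
    spec = make_accession("A", True, 7)
    return render_replicate(spec, cfg, 0)


def build_manifest(strata: dict[tuple[str, bool], int], replicates: int = 9) -> DatasetManifest:
    """Path-only manifest with given (class, hulled) -> accession counts."""
    records = []
    i = 0
    for (code, hulled), n in strata.items():
        for _ in range(n):
            acc = f"{code}{'H' if hulled else 'U'}{i:03d}"
            i += 1
            for rep in range(replicates):
                records.append(
                    ManifestRecord(acc, PigmentLabel.from_code(code), hulled, rep,
                                   f"images/{acc}/{rep}.png", f"masks/{acc}/{rep}.png")
                )
    return DatasetManifest(records)


@pytest.fixture()
def manifest_79():
    """79 accessions x 9 replicates across all 8 strata."""
    return build_manifest({
        ("NP", True): 12, ("NP", False): 8, ("A", True): 10, ("A", False): 9,
        ("M", True): 10, ("M", False): 10, ("AM", True): 10, ("AM", False): 10,
    })
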