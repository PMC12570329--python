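"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import spinemorph as sm

SPACING = sm.SPINNING_DISK_SPACING


@pytest.fixture(scope="session")
def straight_scene():
    """A seeded 10-spine scene on a straight shaft with soma (session-wide)."""
    spec = sm.straight_scene_spec(n_spines=10, shape=(48, 160, 256), seed=3)
    v, m, inst, gt = sm.generate_scene(spec)
    return spec, v, m, inst, gt


@pytest.fixture(scope="session")
def analysed_scene(straight_scene):
    """The straight scene pushed through extraction, filtering, morphometry."""
    spec, v, m, inst, gt = straight_scene
    instances = sm.attach_all(sm.extract_spine_instances(m), m)
    kept, rejected = sm.filter_spines(instances, sm.FilterSpec(), m.spacing)
    records = sm.measure_spines(kept, m, v)
    tree = sm.skeletonize_dendrite(m)
    return spec, v, m, inst, gt, kept, records, tree


def label_map(labels: np.ndarray, spacing=SPACING) -> sm.SemanticLabelMap:
    return sm.SemanticLabelMap(np.asarray(labels, dtype=np.uint8), spacing)


def random_mask(rng: np.random.Generator, shape, p=0.3) -> np.ndarray:
    return rng.random(shape) < p


def random_blob_labels(rng: np.random.Generator, shape, n_seeds=4) -> np.ndarray:
    """A few dilated random blobs as an instance map (0 = background)."""
    from scipy import ndimage as ndi

    mask = np.zeros(shape, dtype=bool)
    seeds = rng.integers(0, np.array(shape), size=(n_seeds, 3))
    mask[tuple(seeds.T)] = True
    mask = ndi.binary_dilation(mask, iterations=int(rng.integers(1, 3)))
    lab, _ = ndi.label(mask)
    return lab
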