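"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities from first principles
(explicit loops, all-pairs distances) so they stay independent of the
library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import meisoquant as mq


# ---------------------------------------------------------------------------
# independent oracles


def brute_feret(pixels: np.ndarray, pixel_size_um: float) -> float:
    """Max pairwise distance over all pixel-corner points (no hull)."""
    corners = set()
    for r, c in np.atleast_2d(pixels):
        for dr in (0, 1):
            for dc in (0, 1):
                corners.add((r + dr, c + dc))
    pts = np.array(sorted(corners), dtype=float) * pixel_size_um
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def brute_remove_outliers(values: np.ndarray, radius: int, threshold: float) -> np.ndarray:
    """Literal restatement: disc median with reflective padding, per pixel.

    Edge-including reflection (numpy 'symmetric') is the boundary rule the
    filter documents.
    """
    padded = np.pad(values, radius, mode="symmetric")
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    out = values.astype(float).copy()
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            nb = [padded[i + radius + dy, j + radius + dx] for dy, dx in offsets]
            med = float(np.median(nb))
            if values[i, j] - med > threshold:
                out[i, j] = med
    return out


def recompute_ground_truth(gt: mq.GroundTruth) -> dict:
    """Recompute all GroundTruth records from the label image alone."""
    s = gt.pixel_size_um
    labels = np.unique(gt.label_image)
    labels = labels[labels > 0]
    rows = {}
    for lab in labels:
        rr, cc = np.nonzero(gt.label_image == lab)
        px = np.column_stack([rr, cc])
        rows[int(lab)] = {
            "area_um2": len(px) * s**2,
            "feret_um": brute_feret(px, s),
            "centroid_x_um": (cc.mean() + 0.5) * s,
            "centroid_y_um": (rr.mean() + 0.5) * s,
        }
    return rows


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_scene_spec() -> mq.SceneSpec:
    """A quick-to-segment scene used by many tests."""
    return mq.SceneSpec(roi_width_um=15.0, roi_height_um=10.0, n_objects=10, seed=1)


@pytest.fixture(scope="session")
def small_scene(small_scene_spec):
    return mq.generate_reticulated_image(small_scene_spec)


@pytest.fixture(scope="session")
def small_pipeline(small_scene):
    img, _ = small_scene
    return mq.run_pipeline(img)


@pytest.fixture(scope="session")
def fragmented_scene(small_scene):
    _, gt = small_scene
    return mq.fragment_scene(gt, 3, seed=2)
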