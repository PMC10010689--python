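"""Object-based two-channel co-localisation.

The statistic is the percentage of segmented objects in one channel whose
centroid lies on (any pixel of) an object of the other channel, computed
per image and then averaged across images, each image representing one
animal. Centroids are unweighted pixel-centre means rounded to the nearest
pixel; membership means landing on a nonzero label of the other channel —
a centroid inside the other channel's convex hull but outside its mask is
a miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["ColocResult", "ColocSummary", "centroid_in_mask_pct", "coloc_summary"]


@dataclass
class ColocResult:
    """Single-image co-localisation: percentages and the raw counts.

    A direction with zero objects has no defined percentage; it is NaN and
    the corresponding ``defined`` flag is False.
    """

    pct_A_in_B: float
    pct_B_in_A: float
    n_A: int
    n_B: int
    n_A_hits: int
    n_B_hits: int
    a_defined: bool = True
    b_defined: bool = True


@dataclass
class ColocSummary:
    """Across-image (one image per animal) mean ± sd per direction."""

    mean_pct_A_in_B: float
    sd_pct_A_in_B: float
    mean_pct_B_in_A: float
    sd_pct_B_in_A: float
    n_images: int


def _centroid_hits(labels_src: np.ndarray, labels_ref: np.ndarray) -> tuple[int, int]:
    ids = np.unique(labels_src)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return 0, 0
    centroids = ndi.center_of_mass(labels_src > 0, labels_src, ids)
    hits = 0
    for cy, cx in centroids:
        r = int(round(cy))
        c = int(round(cx))
        r = min(max(r, 0), labels_ref.shape[0] - 1)
        c = min(max(c, 0), labels_ref.shape[1] - 1)
        if labels_ref[r, c] > 0:
            hits += 1
    return len(ids), hits


def centroid_in_mask_pct(labels_A: np.ndarray, labels_B: np.ndarray) -> ColocResult:
    """Percentage of A-object centroids inside B objects, and vice versa."""
    labels_A = np.asarray(labels_A)
    labels_B = np.asarray(labels_B)
    if labels_A.shape != labels_B.shape:
        raise ValueError(
            f"label grids must be congruent: {labels_A.shape} vs {labels_B.shape}"
        )
    n_a, hits_a = _centroid_hits(labels_A, labels_B)
    n_b, hits_b = _centroid_hits(labels_B, labels_A)
    return ColocResult(
        pct_A_in_B=100.0 * hits_a / n_a if n_a else float("nan"),
        pct_B_in_A=100.0 * hits_b / n_b if n_b else float("nan"),
        n_A=n_a,
        n_B=n_b,
        n_A_hits=hits_a,
        n_B_hits=hits_b,
        a_defined=n_a > 0,
        b_defined=n_b > 0,
    )


def coloc_summary(results: list[ColocResult]) -> ColocSummary:
    """Unweighted mean ± sd of per-image percentages, per direction.

    Images with an undefined direction are excluded from that direction's
    average only.
    """
    if not results:
        raise ValueError("need at least one per-image result")
    a = np.array([r.pct_A_in_B for r in results if r.a_defined])
    b = np.array([r.pct_B_in_A for r in results if r.b_defined])

    def _stats(x: np.ndarray) -> tuple[float, float]:
        if len(x) == 0:
            return float("nan"), float("nan")
        return float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0

    ma, sa = _stats(a)
    mb, sb = _stats(b)
    return ColocSummary(ma, sa, mb, sb, len(results))
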