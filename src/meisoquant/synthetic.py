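"""Ground-truth-labelled synthetic inputs for every downstream stage.

The generator emulates the statistical structure the analyses assume rather
than the biology itself: a wild-type-like field of irregular bright objects
(rotated ellipses, ~0.15–4 µm²) over an autofluorescent background; a
"fragmented" mutant-like counterpart obtained by cutting each object into
disjoint pieces; paired-channel label images with an exactly planted
co-localisation fraction; and spherical-indenter Hertz force curves with a
known Young's modulus.

Default intensities (background 25, object amplitude +100, noise sd 5,
pixel 0.05 µm) are calibrated so that the default segmentation parameters
place the binarisation threshold at the half-height of blurred object
edges, making area recovery unbiased. Intensities are quantised to integer
grey levels as an acquisition camera would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import IntensityImage
from .blobs import measure_labels

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "HertzCurveSpec",
    "PlacementError",
    "FragmentationError",
    "generate_reticulated_image",
    "fragment_scene",
    "generate_coloc_pair",
    "generate_force_curve",
    "hertz_force_nN",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails."""


class FragmentationError(RuntimeError):
    """Raised when an object cannot be split as requested."""


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, intensity and noise model of one synthetic scene.

    ``area_range_um2`` bounds the per-object area before rasterisation;
    ``elongation_range`` is the (min, max) aspect ratio of the rotated
    ellipses; ``min_separation_um`` is the minimum edge-to-edge clearance
    enforced between objects. Objects are drawn additively at
    ``intensity_bg + intensity_fg`` over the background, Gaussian noise of
    scale ``noise_sd`` is added, and the result is clipped at 0 and rounded
    to integer grey levels.
    """

    roi_width_um: float = 40.0
    roi_height_um: float = 25.0
    pixel_size_um: float = 0.05
    n_objects: int = 40
    area_range_um2: tuple[float, float] = (0.3, 1.5)
    elongation_range: tuple[float, float] = (1.0, 3.0)
    intensity_fg: float = 100.0
    intensity_bg: float = 25.0
    noise_sd: float = 5.0
    min_separation_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("roi_width_um", "roi_height_um", "pixel_size_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        lo, hi = self.area_range_um2
        if not (0 < lo <= hi):
            raise ValueError("area_range_um2 must satisfy 0 < low <= high")
        elo, ehi = self.elongation_range
        if not (1.0 <= elo <= ehi):
            raise ValueError("elongation_range must satisfy 1 <= min <= max")
        if self.intensity_fg <= 0 or self.intensity_bg < 0:
            raise ValueError("intensities must be positive (fg) / non-negative (bg)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.roi_height_um / self.pixel_size_um)),
            int(round(self.roi_width_um / self.pixel_size_um)),
        )

    @property
    def roi_area_um2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size_um**2


@dataclass
class GroundTruth:
    """Planted geometry of a synthetic scene: the acceptance oracle.

    ``records`` carries one row per object (label, area_um2, feret_um,
    centroid_x_um, centroid_y_um) where the area is exactly pixel count ×
    pixel size²; ``density_per_um2`` is count / ROI area.
    """

    label_image: np.ndarray
    records: pd.DataFrame
    density_per_um2: float
    pixel_size_um: float
    roi_area_um2: float
    scene: SceneSpec | None = None

    @property
    def n_objects(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class HertzCurveSpec:
    """Forward model of an AFM force–piezo-height curve on a soft sample.

    A spherical indenter of radius ``R_um`` (a 10 µm bead ⇒ R = 5 µm) on a
    cantilever of stiffness ``k_n_per_m`` indents a half-space of modulus
    ``E_pa`` and Poisson ratio ``nu``. The piezo is ramped uniformly over
    ``z_range_nm``; contact starts at ``z0_nm``. Defaults approach a 450 nN
    setpoint at roughly 1 µm indentation, as in stiff-cantilever force
    spectroscopy on the worm cuticle.
    """

    E_pa: float = 100e3
    nu: float = 0.5
    R_um: float = 5.0
    k_n_per_m: float = 7.5
    z0_nm: float = 2000.0
    z_range_nm: float = 3200.0
    n_samples: int = 640
    noise_sd_nN: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.E_pa > 0:
            raise ValueError("E_pa must be > 0")
        if not 0 <= self.nu <= 0.5:
            raise ValueError("nu must be in [0, 0.5]")
        if not self.R_um > 0:
            raise ValueError("R_um must be > 0")
        if not self.k_n_per_m > 0:
            raise ValueError("k_n_per_m must be > 0")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not self.z_range_nm > 0:
            raise ValueError("z_range_nm must be > 0")
        if self.noise_sd_nN < 0:
            raise ValueError("noise_sd_nN must be >= 0")


def hertz_force_nN(delta_nm, E_pa: float, nu: float, R_um: float):
    """Hertz sphere law F = (4/3)·(E/(1−ν²))·√R·δ^{3/2}, returned in nN."""
    delta_nm = np.asarray(delta_nm, dtype=np.float64)
    if np.any(delta_nm < 0):
        raise ValueError("indentation must be >= 0")
    force_N = (
        (4.0 / 3.0)
        * (E_pa / (1.0 - nu**2))
        * math.sqrt(R_um * 1e-6)
        * (delta_nm * 1e-9) ** 1.5
    )
    out = force_N * 1e9
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# scene generation


def _rasterize_ellipse(shape, center_um, a_um, b_um, theta, pixel_size_um):
    """Pixel (row, col) indices whose centres fall inside a rotated ellipse."""
    cy, cx = center_um
    s = pixel_size_um
    r0 = max(int((cy - a_um) / s) - 1, 0)
    r1 = min(int((cy + a_um) / s) + 2, shape[0])
    c0 = max(int((cx - a_um) / s) - 1, 0)
    c1 = min(int((cx + a_um) / s) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    y = (rr + 0.5) * s - cy
    x = (cc + 0.5) * s - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    inside = (u / a_um) ** 2 + (v / b_um) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _render(label_image: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> IntensityImage:
    """Background + additive objects + clipped Gaussian noise, quantised."""
    img = np.full(label_image.shape, spec.intensity_bg, dtype=np.float64)
    img[label_image > 0] += spec.intensity_fg
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0.0, None)
    return IntensityImage(img, spec.pixel_size_um, bit_depth=16)


def _ground_truth(label_image: np.ndarray, spec: SceneSpec) -> GroundTruth:
    records = measure_labels(label_image, spec.pixel_size_um)
    n = len(records)
    return GroundTruth(
        label_image=label_image,
        records=records,
        density_per_um2=n / spec.roi_area_um2,
        pixel_size_um=spec.pixel_size_um,
        roi_area_um2=spec.roi_area_um2,
        scene=spec,
    )


def generate_reticulated_image(
    spec: SceneSpec, max_tries_per_object: int = 200
) -> tuple[IntensityImage, GroundTruth]:
    """Generate a wild-type-like scene of bright elliptical objects.

    Objects are placed by rejection sampling with an edge-to-edge clearance
    of at least ``min_separation_um``; placement failure after bounded
    retries raises :class:`PlacementError`. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    s = spec.pixel_size_um
    label_image = np.zeros(shape, dtype=np.int32)

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    placed = 0
    for i in range(spec.n_objects):
        for _ in range(max_tries_per_object):
            area = rng.uniform(*spec.area_range_um2)
            q = rng.uniform(*spec.elongation_range)
            theta = rng.uniform(0.0, math.pi)
            a = math.sqrt(area * q / math.pi)  # semi-major, µm
            b = math.sqrt(area / (q * math.pi))  # semi-minor, µm
            margin = a + s
            cy = rng.uniform(margin, spec.roi_height_um - margin)
            cx = rng.uniform(margin, spec.roi_width_um - margin)
            ok = all(
                math.hypot(cy - py, cx - px) >= a + pr + spec.min_separation_um
                for (py, px), pr in zip(centers, radii)
            )
            if not ok:
                continue
            rr, cc = _rasterize_ellipse(shape, (cy, cx), a, b, theta, s)
            if len(rr) == 0:
                continue
            label_image[rr, cc] = placed + 1
            centers.append((cy, cx))
            radii.append(a)
            placed += 1
            break
        else:
            raise PlacementError(
                f"could not place object {i + 1} of {spec.n_objects} in a "
                f"{spec.roi_width_um} x {spec.roi_height_um} um ROI after "
                f"{max_tries_per_object} tries"
            )
    img = _render(label_image, spec, rng)
    return img, _ground_truth(label_image, spec)


def fragment_scene(
    gt: GroundTruth,
    k_fragments: int,
    gap_um: float = 0.15,
    seed: int = 0,
    min_fragment_area_um2: float | None = None,
) -> tuple[IntensityImage, GroundTruth]:
    """Split every planted object into ``k_fragments`` disjoint pieces.

    Each object is cut perpendicular to its principal axis at equal-count
    quantiles of the pixel projections; pixels within ``gap_um/2`` of a cut
    are erased, so pieces are separated by at least ``gap_um``
    (centre-to-centre along the axis). The scene is re-rendered with the
    intensity model of the original spec. ``k_fragments = 1`` is the
    identity on the geometry.

    If ``min_fragment_area_um2`` is given, any piece below it raises
    :class:`FragmentationError` naming the offending object — small pieces
    are disallowed, never silently dropped.
    """
    if k_fragments < 1:
        raise ValueError("k_fragments must be >= 1")
    if not gap_um > 0:
        raise ValueError("gap_um must be > 0")
    if gt.scene is None:
        raise ValueError("GroundTruth carries no SceneSpec; cannot re-render")
    spec = gt.scene
    s = gt.pixel_size_um
    rng = np.random.default_rng(seed)

    if k_fragments == 1:
        img = _render(gt.label_image, spec, rng)
        return img, _ground_truth(gt.label_image.copy(), spec)

    new_labels = np.zeros_like(gt.label_image)
    next_label = 1
    half_gap = gap_um / 2.0
    for lab in gt.records["label"]:
        rr, cc = np.nonzero(gt.label_image == lab)
        pts = np.column_stack([rr, cc]).astype(np.float64)
        centred = (pts + 0.5) * s
        centred -= centred.mean(axis=0)
        # principal axis of the pixel cloud
        cov = np.cov(centred.T) if len(pts) > 1 else np.eye(2)
        w, v = np.linalg.eigh(cov)
        axis = v[:, np.argmax(w)]
        t = centred @ axis
        order = np.argsort(t)
        cuts = [t[order[int(round(j * len(t) / k_fragments))]] for j in range(1, k_fragments)]
        piece_idx = np.searchsorted(cuts, t, side="right")
        in_gap = np.zeros(len(t), dtype=bool)
        for cut in cuts:
            in_gap |= np.abs(t - cut) < half_gap
        for j in range(k_fragments):
            sel = (piece_idx == j) & ~in_gap
            area = sel.sum() * s**2
            if sel.sum() == 0 or (
                min_fragment_area_um2 is not None and area < min_fragment_area_um2
            ):
                raise FragmentationError(
                    f"object {int(lab)} (area {len(t) * s ** 2:.3f} um^2) cannot "
                    f"yield {k_fragments} pieces"
                    + (
                        f" of >= {min_fragment_area_um2} um^2"
                        if min_fragment_area_um2 is not None
                        else f" with gap {gap_um} um"
                    )
                )
            new_labels[rr[sel], cc[sel]] = next_label
            next_label += 1

    img = _render(new_labels, spec, rng)
    return img, _ground_truth(new_labels, spec)


# ---------------------------------------------------------------------------
# co-localisation pairs


def generate_coloc_pair(
    n_a: int,
    n_b: int,
    planted_fraction: float,
    spec: SceneSpec | None = None,
    seed: int = 0,
    radius_b_um: float = 0.6,
    radius_a_um: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two label images with an exactly planted co-localisation fraction.

    ``round(planted_fraction * n_a)`` objects of channel A are discs centred
    on (distinct) channel-B disc centres, so their centroids fall inside B
    by construction; the remaining A objects are placed with clearance from
    every B object. Returns ``(labels_A, labels_B, expected_pct_A_in_B)``
    where the expected percentage is exact by construction.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    if n_a < 1 or n_b < 1:
        raise ValueError("both channels need at least one object")
    n_hits = int(round(planted_fraction * n_a))
    if n_hits > n_b:
        raise ValueError(
            f"cannot centre {n_hits} A objects in only {n_b} B objects"
        )
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed)
    shape = spec.shape
    s = spec.pixel_size_um

    clearance = radius_a_um + radius_b_um + 3 * s
    centers_b: list[tuple[float, float]] = []
    labels_b = np.zeros(shape, dtype=np.int32)
    margin = radius_b_um + clearance
    for i in range(n_b):
        for _ in range(500):
            cy = rng.uniform(margin, spec.roi_height_um - margin)
            cx = rng.uniform(margin, spec.roi_width_um - margin)
            if all(math.hypot(cy - py, cx - px) >= 2 * radius_b_um + clearance for py, px in centers_b):
                break
        else:
            raise PlacementError(f"could not place B object {i + 1} of {n_b}")
        rr, cc = _rasterize_ellipse(shape, (cy, cx), radius_b_um, radius_b_um, 0.0, s)
        labels_b[rr, cc] = i + 1
        centers_b.append((cy, cx))

    labels_a = np.zeros(shape, dtype=np.int32)
    hit_targets = rng.choice(n_b, size=n_hits, replace=False)
    for i, j in enumerate(hit_targets):
        rr, cc = _rasterize_ellipse(shape, centers_b[j], radius_a_um, radius_a_um, 0.0, s)
        labels_a[rr, cc] = i + 1
    centers_a = [centers_b[j] for j in hit_targets]
    for i in range(n_hits, n_a):
        for _ in range(500):
            cy = rng.uniform(radius_a_um + s, spec.roi_height_um - radius_a_um - s)
            cx = rng.uniform(radius_a_um + s, spec.roi_width_um - radius_a_um - s)
            far_from_b = all(
                math.hypot(cy - py, cx - px) >= clearance for py, px in centers_b
            )
            far_from_a = all(
                math.hypot(cy - py, cx - px) >= 2 * radius_a_um + 3 * s
                for py, px in centers_a
            )
            if far_from_b and far_from_a:
                break
        else:
            raise PlacementError(f"could not place miss A object {i + 1} of {n_a}")
        rr, cc = _rasterize_ellipse(shape, (cy, cx), radius_a_um, radius_a_um, 0.0, s)
        labels_a[rr, cc] = i + 1
        centers_a.append((cy, cx))

    expected_pct = 100.0 * n_hits / n_a
    return labels_a, labels_b, expected_pct


# ---------------------------------------------------------------------------
# force curves


def generate_force_curve(spec: HertzCurveSpec):
    """Forward-simulate a spherical-indenter force curve.

    The piezo height z is sampled uniformly on [0, z_range]. For z > z0 the
    indentation is obtained self-consistently from the piezo travel minus
    the cantilever bending, δ = (z − z0) − F(δ)/k, by fixed-point iteration
    to 1e-6 nm; below contact the force is baseline noise only. The true
    per-sample indentation is kept in the curve metadata for round-trip
    verification. Deterministic given the seed.
    """
    from .afm import ForceCurve  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    z = np.linspace(0.0, spec.z_range_nm, spec.n_samples)
    travel = np.clip(z - spec.z0_nm, 0.0, None)
    delta = travel.copy()
    for _ in range(500):
        f = hertz_force_nN(delta, spec.E_pa, spec.nu, spec.R_um)
        new = np.clip(travel - f / spec.k_n_per_m, 0.0, None)
        if np.max(np.abs(new - delta)) < 1e-6:
            delta = new
            break
        delta = new
    force = hertz_force_nN(delta, spec.E_pa, spec.nu, spec.R_um)
    true_force = force.copy()
    if spec.noise_sd_nN > 0:
        force = force + rng.normal(0.0, spec.noise_sd_nN, size=force.shape)
    return ForceCurve(
        z_nm=z,
        force_nN=force,
        k_n_per_m=spec.k_n_per_m,
        meta={
            "spec": spec,
            "true_delta_nm": delta,
            "true_force_nN": true_force,
        },
    )
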