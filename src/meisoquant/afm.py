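"""AFM force-curve processing and Hertz spherical-indenter fitting.

An approach curve records cantilever force (or deflection) against piezo
height z. Processing follows standard force-spectroscopy practice: zero the
baseline with a line fit to the far-from-contact portion, locate the
contact point z0 where the force leaves the noise band, convert to an
indentation curve by subtracting cantilever bending (δ = (z − z0) − F/k),
and estimate the Young's modulus E by least squares against the Hertz
sphere law F = (4/3)·(E/(1−ν²))·√R·δ^{3/2}.

Units: z and δ in nm, forces in nN, cantilever stiffness in N/m (so that
bending in nm is simply F[nN]/k[N/m]), moduli in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .synthetic import hertz_force_nN

__all__ = [
    "ForceCurve",
    "IndentationCurve",
    "HertzFit",
    "ContactPointError",
    "zero_baseline",
    "find_contact_point",
    "to_indentation",
    "hertz_force",
    "fit_hertz_sphere",
    "process_curve",
]


class ContactPointError(RuntimeError):
    """No tip–sample contact detectable in the curve."""


@dataclass
class ForceCurve:
    """Raw approach curve: piezo height vs force.

    ``z_nm`` must be strictly monotone (increasing toward the sample).
    Construct from deflection data with :meth:`from_deflection` (F = k·d).
    """

    z_nm: np.ndarray
    force_nN: np.ndarray
    k_n_per_m: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=np.float64)
        self.force_nN = np.asarray(self.force_nN, dtype=np.float64)
        if self.z_nm.ndim != 1 or self.z_nm.shape != self.force_nN.shape:
            raise ValueError("z and force must be 1D arrays of equal length")
        if len(self.z_nm) < 10:
            raise ValueError("a force curve needs at least 10 samples")
        dz = np.diff(self.z_nm)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z_nm must be strictly monotone")
        if not (np.all(np.isfinite(self.z_nm)) and np.all(np.isfinite(self.force_nN))):
            raise ValueError("curve contains non-finite samples")
        if np.all(dz < 0):  # store in approach order: z increasing
            self.z_nm = self.z_nm[::-1].copy()
            self.force_nN = self.force_nN[::-1].copy()

    @classmethod
    def from_deflection(
        cls, z_nm, deflection_nm, k_n_per_m: float, meta: dict | None = None
    ) -> "ForceCurve":
        if not k_n_per_m > 0:
            raise ValueError("cantilever stiffness must be > 0")
        d = np.asarray(deflection_nm, dtype=np.float64)
        return cls(z_nm, k_n_per_m * d, k_n_per_m, meta or {})

    @property
    def spacing_nm(self) -> float:
        return float(np.median(np.diff(self.z_nm)))


@dataclass
class IndentationCurve:
    """Contact-referenced curve: indentation δ vs force, with z0 recorded."""

    delta_nm: np.ndarray
    force_nN: np.ndarray
    z0_nm: float

    def __post_init__(self) -> None:
        self.delta_nm = np.asarray(self.delta_nm, dtype=np.float64)
        self.force_nN = np.asarray(self.force_nN, dtype=np.float64)
        if self.delta_nm.shape != self.force_nN.shape:
            raise ValueError("delta and force must have equal length")


@dataclass
class HertzFit:
    """Result of a Hertz sphere fit.

    ``E_pa`` is the Young's modulus; ``z0_shift_nm`` is the contact-point
    refinement applied during the fit (0 when refinement is off);
    ``rms_residual_nN`` is always reported. ``converged`` is False for
    degenerate inputs (e.g. all-zero force) instead of failing silently.
    """

    E_pa: float
    nu: float
    R_um: float
    z0_nm: float
    z0_shift_nm: float
    rms_residual_nN: float
    n_samples: int
    fit_window: tuple[float, float]
    converged: bool


def zero_baseline(curve: ForceCurve, baseline_fraction: float = 0.3) -> ForceCurve:
    """Subtract a line fitted to the far (non-contact) portion of the curve.

    The first ``baseline_fraction`` of samples (lowest z, farthest from the
    sample) define the baseline; a first-degree polynomial in z is removed
    from the whole curve so constant offsets and linear drift vanish.
    """
    if not 0 < baseline_fraction <= 0.8:
        raise ValueError("baseline_fraction must be in (0, 0.8]")
    n = int(len(curve.z_nm) * baseline_fraction)
    if n < 3:
        raise ValueError(
            f"baseline fit needs >= 3 samples, got {n} from fraction {baseline_fraction}"
        )
    coef = np.polyfit(curve.z_nm[:n], curve.force_nN[:n], 1)
    corrected = curve.force_nN - np.polyval(coef, curve.z_nm)
    return ForceCurve(curve.z_nm.copy(), corrected, curve.k_n_per_m, dict(curve.meta))


def find_contact_point(
    curve: ForceCurve,
    noise_sd_estimate: float | None = None,
    n_sigma: float = 3.0,
    min_run: int = 5,
    baseline_fraction: float = 0.3,
) -> float:
    """Piezo height z0 at which force leaves the baseline noise band.

    Contact is the first sample whose force exceeds ``n_sigma`` × the
    baseline noise sd and stays above it for at least ``min_run``
    consecutive samples; z0 is the preceding sample's height (the last
    point still at baseline). When no noise estimate is supplied it is
    taken from the first ``baseline_fraction`` of the (already zeroed)
    curve. On noiseless curves the threshold floor is a tiny fraction of
    the peak force, so z0 is recovered within one sample spacing.
    """
    f = curve.force_nN
    if noise_sd_estimate is None:
        n = max(int(len(f) * baseline_fraction), 3)
        noise_sd_estimate = float(np.std(f[:n]))
    fmax = float(np.max(f)) if np.max(f) > 0 else 0.0
    thr = max(n_sigma * noise_sd_estimate, 1e-9 * fmax, 1e-12)
    above = f > thr
    # first index from which min_run consecutive samples all exceed thr
    run = 0
    start = None
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run:
            start = i - min_run + 1
            break
    if start is None:
        raise ContactPointError(
            f"no contact: force never exceeds {thr:.3g} nN for {min_run} samples"
        )
    return float(curve.z_nm[start - 1] if start > 0 else curve.z_nm[start])


def to_indentation(
    curve: ForceCurve, k_n_per_m: float, z0_nm: float
) -> IndentationCurve:
    """Subtract cantilever bending: δ = (z − z0) − F/k for z > z0."""
    if not k_n_per_m > 0:
        raise ValueError("cantilever stiffness must be > 0")
    sel = curve.z_nm > z0_nm
    z = curve.z_nm[sel]
    f = curve.force_nN[sel]
    delta = (z - z0_nm) - f / k_n_per_m
    return IndentationCurve(delta, f, z0_nm)


def hertz_force(delta_nm, E_pa: float, nu: float = 0.5, R_um: float = 5.0):
    """Hertz sphere force (nN) at indentation δ (nm); errors on δ < 0."""
    return hertz_force_nN(delta_nm, E_pa, nu, R_um)


def fit_hertz_sphere(
    ind: IndentationCurve,
    nu: float = 0.5,
    R_um: float = 5.0,
    fit_window: tuple[float, float] = (0.1, 0.9),
    refine_z0: bool = True,
) -> HertzFit:
    """Least-squares Young's modulus from an indentation curve.

    Samples with δ in ``fit_window`` (fractions of the maximum indentation)
    enter the fit. The model is linear in E, so the base estimate is the
    normal-equation solution; when ``refine_z0`` is set, a small
    contact-point shift dz is co-fitted with E (δ → δ − dz, clipped at 0),
    absorbing residual contact-detection error. Fit quality is reported as
    the rms residual; degenerate inputs yield ``converged=False``.
    """
    lo, hi = fit_window
    if not 0 <= lo < hi <= 1:
        raise ValueError("fit_window fractions must satisfy 0 <= lo < hi <= 1")
    dmax = float(np.max(ind.delta_nm)) if len(ind.delta_nm) else 0.0
    sel = (ind.delta_nm >= lo * dmax) & (ind.delta_nm <= hi * dmax)
    delta = np.clip(ind.delta_nm[sel], 0.0, None)
    force = ind.force_nN[sel]
    if len(delta) < 5:
        raise ValueError(f"need >= 5 samples in fit window, got {len(delta)}")

    basis = hertz_force_nN(delta, 1.0, nu, R_um)  # force per unit E
    denom = float(basis @ basis)
    if denom == 0 or not np.any(force > 0):
        return HertzFit(0.0, nu, R_um, ind.z0_nm, 0.0,
                        float(np.sqrt(np.mean(force**2))), len(delta), fit_window, False)
    E0 = float(basis @ force / denom)
    if E0 <= 0:
        return HertzFit(E0, nu, R_um, ind.z0_nm, 0.0,
                        float(np.sqrt(np.mean((force - E0 * basis) ** 2))),
                        len(delta), fit_window, False)

    dz = 0.0
    E = E0
    if refine_z0:
        # noise-band contact detection is systematically late by up to the
        # depth where the force clears the band, so allow a generous shift
        span = max(0.3 * dmax, 1.0)

        def resid(p):
            e, d = p
            return hertz_force_nN(np.clip(delta - d, 0.0, None), e, nu, R_um) - force

        sol = least_squares(
            resid, x0=[E0, 0.0],
            bounds=([1e-12, -span], [np.inf, span]),
        )
        if sol.success and sol.x[0] > 0:
            E, dz = float(sol.x[0]), float(sol.x[1])

    residual = hertz_force_nN(np.clip(delta - dz, 0.0, None), E, nu, R_um) - force
    return HertzFit(
        E_pa=E,
        nu=nu,
        R_um=R_um,
        z0_nm=ind.z0_nm + dz,
        z0_shift_nm=dz,
        rms_residual_nN=float(np.sqrt(np.mean(residual**2))),
        n_samples=len(delta),
        fit_window=fit_window,
        converged=True,
    )


def process_curve(
    curve: ForceCurve,
    k_n_per_m: float | None = None,
    nu: float = 0.5,
    R_um: float = 5.0,
    baseline_fraction: float = 0.3,
    fit_window: tuple[float, float] = (0.1, 0.9),
    noise_sd_estimate: float | None = None,
) -> HertzFit:
    """Full pipeline: zero baseline → contact point → indentation → fit."""
    k = k_n_per_m if k_n_per_m is not None else curve.k_n_per_m
    if k is None:
        raise ValueError("cantilever stiffness required (curve carries none)")
    zeroed = zero_baseline(curve, baseline_fraction)
    z0 = find_contact_point(zeroed, noise_sd_estimate, baseline_fraction=baseline_fraction)
    ind = to_indentation(zeroed, k, z0)
    return fit_hertz_sphere(ind, nu=nu, R_um=R_um, fit_window=fit_window)
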