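"""Fiber orientation and anisotropy from normalized azimuthal profiles.

Scattering from fibrous tissue is centrosymmetric, so ordinary circular
statistics on I_norm(φ) would yield a vanishing resultant; the standard
axial-data treatment doubles the angles.  With weights w(φ) = I_norm(φ)
on valid bins the axial resultant is

    z = Σ_φ w(φ)·(e^{i2φ} − c̄),   c̄ = mean of e^{i2φ} over valid bins,

anisotropy = |z|, circular variance Var = 1 − |z| and the scattering
mean angle φ₀ = ½·arg(z) mod 180°.  The c̄ term corrects the coverage
bias introduced when the beamstop removes φ bins; with full angular
coverage c̄ = 0 exactly and the estimator reduces to the plain weighted
resultant.  The fiber (cardiomyocyte chain) orientation is φ₀ rotated by
90°, since equatorial scattering is perpendicular to the filament axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reduction import AzimuthalProfile

#: resultant lengths below this are treated as orientation-undefined
RESULTANT_FLOOR = 1e-3


@dataclass
class OrientationResult:
    """Axial circular statistics of one azimuthal profile."""

    phi0_scatter: float       # degrees mod 180; NaN when undefined
    fiber_orientation: float  # degrees mod 180 (= phi0 + 90); NaN when undefined
    circ_variance: float
    anisotropy: float
    defined: bool


def _axial_stats(phi_deg: np.ndarray, weights: np.ndarray) -> OrientationResult:
    phase = np.exp(2j * np.radians(phi_deg))
    z = np.sum(weights * (phase - phase.mean()))
    r = float(np.abs(z))
    anisotropy = min(r, 1.0)
    defined = r >= RESULTANT_FLOOR
    if defined:
        phi0 = (np.degrees(np.angle(z)) / 2.0) % 180.0
        fiber = (phi0 + 90.0) % 180.0
    else:
        phi0 = fiber = np.nan
    return OrientationResult(phi0_scatter=phi0, fiber_orientation=fiber,
                             circ_variance=1.0 - anisotropy,
                             anisotropy=anisotropy, defined=defined)


def circular_stats(profile: AzimuthalProfile) -> OrientationResult:
    """Orientation and anisotropy of one normalized azimuthal profile."""
    valid = profile.valid & np.isfinite(profile.normalized)
    if valid.sum() < 8:
        raise ValueError(f"need at least 8 valid φ bins, got {int(valid.sum())}")
    weights = profile.normalized[valid]
    if not np.any(weights != 0):
        raise ValueError("degenerate all-zero normalized profile")
    return _axial_stats(profile.phi[valid], weights)


def orientation_map(inorm: np.ndarray, phi_centers: np.ndarray,
                    phi_valid: np.ndarray | None = None):
    """Per-point circular statistics over a (ny, nx, nphi) profile grid.

    Returns (phi0, fiber, anisotropy, defined) arrays; points with an
    undefined orientation are flagged (NaN angles), never interpolated.
    """
    ny, nx, nphi = inorm.shape
    if phi_valid is None:
        phi_valid = np.ones(nphi, dtype=bool)
    phi0 = np.full((ny, nx), np.nan)
    fiber = np.full((ny, nx), np.nan)
    anisotropy = np.full((ny, nx), np.nan)
    defined = np.zeros((ny, nx), dtype=bool)
    phase = np.exp(2j * np.radians(phi_centers[phi_valid]))
    centered = phase - phase.mean()
    for iy in range(ny):
        for ix in range(nx):
            w = inorm[iy, ix, phi_valid]
            ok = np.isfinite(w)
            if ok.sum() < 8 or not np.any(w[ok] != 0):
                continue
            z = np.sum(w[ok] * centered[ok])
            r = float(np.abs(z))
            anisotropy[iy, ix] = min(r, 1.0)
            if r >= RESULTANT_FLOOR:
                defined[iy, ix] = True
                phi0[iy, ix] = (np.degrees(np.angle(z)) / 2.0) % 180.0
                fiber[iy, ix] = (phi0[iy, ix] + 90.0) % 180.0
    return phi0, fiber, anisotropy, defined


def angular_difference(a: np.ndarray, b: np.ndarray, period: float = 180.0) -> np.ndarray:
    """Smallest absolute difference between angles modulo ``period``."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % period
    return np.minimum(d, period - d)
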