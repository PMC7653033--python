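"""Beam/detector geometry, reciprocal-space coordinate maps and dosimetry.

A scanning small-angle diffraction experiment is described by the photon
energy E (keV), the focal spot (FWHM Δx × Δy, µm), the photon flux I₀, the
per-point exposure τ, and the sample–detector geometry (distance, pixel
pitch, beam center).  From these the per-pixel wavevector transfer

    q = (4π/λ)·sin(θ/2),    θ = atan(r/L)

is computed, where r is the in-plane distance of a pixel from the beam
center and L the sample–detector distance.  The absorbed dose of a single
exposure is estimated as

    D = I₀·τ·E·(μ/ρ) / (Δx·Δy)

with μ/ρ the mass absorption coefficient of the tissue and Δx·Δy the focal
FWHM area (not a Gaussian-integral area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: hc in keV·nm — converts photon energy to wavelength.
HC_KEV_NM = 1.23984
#: one keV in joule.
KEV_TO_J = 1.602176634e-16


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in nm for an energy in keV (λ = hc/E)."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_NM / energy_kev


@dataclass(frozen=True)
class BeamGeometry:
    """Beam and detector parameters of one scanning-diffraction run.

    Defaults correspond to a 13 keV micro-focus setup with a 2.9 × 1.4 µm
    focal spot and a 256 × 256 pixel detector placed so that the acto-myosin
    (1,1) ring (q ≈ 0.32 nm⁻¹) falls at roughly half the detector radius.
    """

    photon_energy: float = 13.0          # keV
    flux_i0: float = 1.57e12             # photons / s
    exposure_tau: float = 0.010          # s
    beam_fwhm_h: float = 2.9             # µm (Δx)
    beam_fwhm_v: float = 1.4             # µm (Δy)
    mass_abs_coeff: float = 3.1582       # cm² / g (μ/ρ)
    detector_distance: float = 2000.0    # mm
    pixel_size: float = 150.0            # µm
    beam_center: tuple[float, float] = (127.5, 127.5)   # (row, col), px
    detector_shape: tuple[int, int] = (256, 256)        # (rows, cols)

    def __post_init__(self) -> None:
        for name in ("photon_energy", "flux_i0", "exposure_tau", "beam_fwhm_h",
                     "beam_fwhm_v", "mass_abs_coeff", "detector_distance",
                     "pixel_size"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        rows, cols = self.detector_shape
        r0, c0 = self.beam_center
        if not (0 <= r0 < rows and 0 <= c0 < cols):
            raise ValueError(
                f"beam center {self.beam_center} outside detector {self.detector_shape}")

    @property
    def wavelength(self) -> float:
        """Wavelength in nm, derived from the photon energy."""
        return wavelength_from_energy(self.photon_energy)


@dataclass(frozen=True)
class CoordinateMaps:
    """Per-pixel reciprocal-space coordinates of a detector.

    ``q`` in nm⁻¹, ``phi`` (azimuth, counter-clockwise from the +column
    axis) in degrees [0, 360), ``theta`` (scattering angle) in rad.
    """

    q: np.ndarray
    phi: np.ndarray
    theta: np.ndarray


def coordinate_maps(geom: BeamGeometry) -> CoordinateMaps:
    """Compute q/φ/θ maps for every pixel of the detector.

    φ is measured from the +x (column) axis with the row offset as the
    second cartesian component, so diametrically opposite pixels differ by
    180° as required for a centrosymmetric scattering pattern.
    """
    if geom.detector_distance <= 0:
        raise ValueError("detector distance must be positive")
    rows, cols = geom.detector_shape
    r0, c0 = geom.beam_center
    drow = (np.arange(rows, dtype=float) - r0)[:, None]
    dcol = (np.arange(cols, dtype=float) - c0)[None, :]
    r_mm = np.hypot(drow, dcol) * geom.pixel_size * 1e-3
    theta = np.arctan(r_mm / geom.detector_distance)
    q = (4.0 * np.pi / geom.wavelength) * np.sin(theta / 2.0)
    phi = np.degrees(np.arctan2(np.broadcast_to(drow, (rows, cols)),
                                np.broadcast_to(dcol, (rows, cols)))) % 360.0
    return CoordinateMaps(q=q, phi=phi, theta=theta)


def dose(geom: BeamGeometry) -> float:
    """Absorbed dose (Gy) of a single exposure, D = I₀·τ·E·(μ/ρ)/(Δx·Δy).

    Unit conversions: E keV→J, μ/ρ cm²·g⁻¹→m²·kg⁻¹, FWHM µm→m.  With the
    default geometry this evaluates to ≈ 2.54 MGy.
    """
    area_m2 = (geom.beam_fwhm_h * 1e-6) * (geom.beam_fwhm_v * 1e-6)
    if area_m2 <= 0:
        raise ValueError("beam FWHM area must be positive")
    energy_j = geom.photon_energy * KEV_TO_J
    mu_rho_m2_kg = geom.mass_abs_coeff * 0.1   # cm²/g → m²/kg
    return geom.flux_i0 * geom.exposure_tau * energy_j * mu_rho_m2_kg / area_m2
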