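"""Frame reduction: background subtraction and 1D radial/azimuthal profiles.

Per scan line, the empty frames (beam off the sample) are averaged and
subtracted pixel-wise from every sample frame of that line.  Subtracted
frames are angularly averaged to I(q) for peak fitting, and radially
averaged within a q window (default 0.2–0.5 nm⁻¹) to the azimuthal
profile I(φ), which is normalized as printed:

    I_norm(φ) = (I(φ) − min I(φ)) / Σ_φ I(φ)

with the minimum and the sum taken over valid (non-empty) φ bins only.
Negative post-subtraction values are kept — clipping would bias the flat
background term of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import CoordinateMaps
from .synthetic import ScanStack

DEFAULT_N_QBINS = 200
DEFAULT_N_PHIBINS = 180          # 2° bins
DEFAULT_PHI_Q_RANGE = (0.2, 0.5)  # nm⁻¹


@dataclass
class RadialProfile:
    """Angularly averaged intensity I(q); bins without pixels are invalid."""

    q: np.ndarray           # bin centers, nm⁻¹, ascending
    intensity: np.ndarray   # counts/exposure (NaN where invalid)
    n_pixels: np.ndarray    # contributing unmasked pixels per bin

    @property
    def valid(self) -> np.ndarray:
        return self.n_pixels > 0


@dataclass
class AzimuthalProfile:
    """Radially averaged intensity I(φ) and its normalized form I_norm."""

    phi: np.ndarray         # bin centers, degrees in [0, 360)
    intensity: np.ndarray   # counts/exposure (NaN where invalid)
    n_pixels: np.ndarray
    normalized: np.ndarray  # I_norm (NaN where invalid)

    @property
    def valid(self) -> np.ndarray:
        return self.n_pixels > 0


def line_background(stack: ScanStack, line_index: int) -> np.ndarray:
    """Pixel-wise mean over the empty frames of one scan line."""
    flags = stack.empty_flags[line_index]
    if not flags.any():
        raise ValueError(f"scan line {line_index} has no empty frames")
    return stack.frames[line_index, flags].mean(axis=0)


def subtract_background(frame: np.ndarray, background: np.ndarray,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """frame − background with masked pixels set to NaN; negatives kept."""
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}")
    out = frame - background
    if mask is not None:
        if mask.shape != frame.shape:
            raise ValueError("mask shape does not match frame")
        out = out.copy()
        out[mask] = np.nan
    return out


def _valid_pixels(frame: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    ok = np.isfinite(frame)
    if mask is not None:
        ok &= ~mask
    return ok


def azimuthal_average(frame: np.ndarray, maps: CoordinateMaps,
                      mask: np.ndarray | None, q_bins: np.ndarray) -> RadialProfile:
    """Mean unmasked intensity per q bin (the angular average I(q))."""
    q_bins = np.asarray(q_bins, dtype=float)
    if q_bins.size < 9 or np.any(np.diff(q_bins) <= 0):
        raise ValueError("q_bins must be ascending with at least 8 bins")
    ok = _valid_pixels(frame, mask)
    q = maps.q[ok]
    vals = np.asarray(frame, dtype=float)[ok]
    counts, _ = np.histogram(q, bins=q_bins)
    sums, _ = np.histogram(q, bins=q_bins, weights=vals)
    if counts.sum() == 0:
        raise ValueError("no unmasked pixels in the requested q range")
    with np.errstate(invalid="ignore"):
        intensity = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (q_bins[:-1] + q_bins[1:])
    return RadialProfile(q=centers, intensity=intensity, n_pixels=counts)


def default_q_bins(maps: CoordinateMaps, n_bins: int = DEFAULT_N_QBINS) -> np.ndarray:
    """Linear q bins spanning the detector's q coverage."""
    return np.linspace(0.0, float(maps.q.max()), n_bins + 1)


def azimuthal_profile(frame: np.ndarray, maps: CoordinateMaps,
                      mask: np.ndarray | None,
                      q_range: tuple[float, float] = DEFAULT_PHI_Q_RANGE,
                      n_phi_bins: int = DEFAULT_N_PHIBINS,
                      coverage_fraction: float = 0.5) -> AzimuthalProfile:
    """Radial average within ``q_range`` per φ bin, then I_norm normalization.

    φ bins left empty by the beamstop are flagged invalid and excluded
    from both the minimum and the normalization sum.  Bins whose pixel
    count falls below ``coverage_fraction`` of the median bin count are
    treated the same: they sample only part of the annulus's radial
    extent, so their mean is not comparable to fully covered bins.
    """
    qlo, qhi = q_range
    if not (0 <= qlo < qhi):
        raise ValueError(f"invalid q range {q_range}")
    if qhi > maps.q.max():
        raise ValueError(
            f"q range {q_range} exceeds detector coverage (q_max={maps.q.max():.3g})")
    ok = _valid_pixels(frame, mask) & (maps.q >= qlo) & (maps.q <= qhi)
    phi = maps.phi[ok]
    vals = np.asarray(frame, dtype=float)[ok]
    edges = np.linspace(0.0, 360.0, n_phi_bins + 1)
    counts, _ = np.histogram(phi, bins=edges)
    sums, _ = np.histogram(phi, bins=edges, weights=vals)
    occupied = counts > 0
    floor = coverage_fraction * np.median(counts[occupied]) if occupied.any() else 0
    valid = counts >= max(floor, 1)
    counts = np.where(valid, counts, 0)
    with np.errstate(invalid="ignore"):
        intensity = np.where(valid, sums / np.maximum(counts, 1), np.nan)
    normalized = np.full(n_phi_bins, np.nan)
    if valid.any():
        total = intensity[valid].sum()
        if total != 0:
            normalized[valid] = (intensity[valid] - intensity[valid].min()) / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AzimuthalProfile(phi=centers, intensity=intensity,
                            n_pixels=counts, normalized=normalized)


def total_intensity(frame: np.ndarray, mask: np.ndarray | None = None,
                    maps: CoordinateMaps | None = None,
                    q_range: tuple[float, float] | None = None) -> float:
    """Sum of unmasked (optionally q-restricted) pixel values."""
    ok = _valid_pixels(frame, mask)
    if q_range is not None:
        if maps is None:
            raise ValueError("q_range restriction requires coordinate maps")
        ok &= (maps.q >= q_range[0]) & (maps.q <= q_range[1])
    return float(np.asarray(frame, dtype=float)[ok].sum())


@dataclass
class ReducedScan:
    """Per-point 1D profiles and totals for a whole scan grid."""

    q: np.ndarray             # (nq,)
    iq: np.ndarray            # (ny, nx, nq), NaN where invalid
    iq_npix: np.ndarray       # (nq,) pixel count per q bin (mask-constant)
    phi: np.ndarray           # (nphi,)
    iphi: np.ndarray          # (ny, nx, nphi)
    inorm: np.ndarray         # (ny, nx, nphi)
    phi_valid: np.ndarray     # (nphi,) bool
    totals: np.ndarray        # (ny, nx)


def reduce_scan(stack: ScanStack, maps: CoordinateMaps,
                n_q_bins: int = DEFAULT_N_QBINS,
                n_phi_bins: int = DEFAULT_N_PHIBINS,
                phi_q_range: tuple[float, float] = DEFAULT_PHI_Q_RANGE) -> ReducedScan:
    """Background-subtract and reduce every sample point of a scan stack."""
    ny, nx = stack.sample_shape
    q_bins = default_q_bins(maps, n_q_bins)
    iq = np.full((ny, nx, n_q_bins), np.nan)
    iphi = np.full((ny, nx, n_phi_bins), np.nan)
    inorm = np.full((ny, nx, n_phi_bins), np.nan)
    totals = np.zeros((ny, nx))
    q_centers = phi_centers = iq_npix = phi_valid = None
    for iy in range(ny):
        background = line_background(stack, iy)
        for ix in range(nx):
            sub = subtract_background(stack.sample_frame(iy, ix), background,
                                      stack.mask)
            rad = azimuthal_average(sub, maps, stack.mask, q_bins)
            azi = azimuthal_profile(sub, maps, stack.mask, phi_q_range,
                                    n_phi_bins)
            iq[iy, ix] = rad.intensity
            iphi[iy, ix] = azi.intensity
            inorm[iy, ix] = azi.normalized
            totals[iy, ix] = total_intensity(sub, stack.mask)
            if q_centers is None:
                q_centers, iq_npix = rad.q, rad.n_pixels
                phi_centers, phi_valid = azi.phi, azi.valid
    return ReducedScan(q=q_centers, iq=iq, iq_npix=iq_npix, phi=phi_centers,
                       iphi=iphi, inorm=inorm, phi_valid=phi_valid,
                       totals=totals)


def save_reduced(reduced: ReducedScan, path) -> None:
    """Write per-point profiles to HDF5 (/profiles/q, Iq, phi, Iphi, ...)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("profiles")
        g.create_dataset("q", data=reduced.q)
        g.create_dataset("Iq", data=reduced.iq, compression="gzip")
        g.create_dataset("Iq_npix", data=reduced.iq_npix)
        g.create_dataset("phi", data=reduced.phi)
        g.create_dataset("Iphi", data=reduced.iphi, compression="gzip")
        g.create_dataset("Inorm", data=reduced.inorm, compression="gzip")
        g.create_dataset("phi_valid", data=reduced.phi_valid)
        f.create_dataset("totals", data=reduced.totals)


def load_reduced(path) -> ReducedScan:
    with h5py.File(path, "r") as f:
        g = f["profiles"]
        return ReducedScan(q=g["q"][()], iq=g["Iq"][()], iq_npix=g["Iq_npix"][()],
                           phi=g["phi"][()], iphi=g["Iphi"][()],
                           inorm=g["Inorm"][()],
                           phi_valid=g["phi_valid"][()].astype(bool),
                           totals=f["totals"][()])
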