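"""Parameter maps, k-means segmentation, histogram models and lesion masks.

Per-point fit results, orientation statistics and totals are joined into
2D parameter maps.  Tissue regions are segmented by k-means (k = 3) on
the z-scored five-dimensional fit-parameter vector (S, d, I_p, q₀,
I_bgr), with clusters relabeled in ascending order of mean filament
spacing so labels are deterministic.  Spacing distributions are
summarized by the mode of a Gaussian kernel density estimate and modeled
with a pseudo-Voigt profile.  Fibrotic lesions are masked by
thresholding the spacing map (default 46.0 nm) OR-combined with the
at-bound flag of diverged fits, followed by small-component cleanup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

FIT_FEATURES = ("S", "d", "Ip", "q0", "Ibgr")
DEFAULT_LESION_THRESHOLD = 46.0   # nm
DEFAULT_MIN_REGION_PX = 4


@dataclass
class ParameterMaps:
    """Per-scan-point 2D maps of the fitted and derived quantities."""

    spacing: np.ndarray
    peak_intensity: np.ndarray
    anisotropy: np.ndarray
    orientation: np.ndarray
    total_intensity: np.ndarray
    valid: np.ndarray
    at_bound: np.ndarray
    fit_params: pd.DataFrame       # tidy per-point table incl. S, d, Ip, q0, Ibgr
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.spacing.shape


def assemble_maps(fit_table: pd.DataFrame, phi0: np.ndarray, fiber: np.ndarray,
                  anisotropy: np.ndarray, totals: np.ndarray,
                  provenance: dict | None = None) -> ParameterMaps:
    """Join per-point results into maps with a shared validity mask.

    A point is valid when its fit converged; invalid points stay NaN in
    every map and are never zero-filled.
    """
    ny = int(fit_table["iy"].max()) + 1
    nx = int(fit_table["ix"].max()) + 1
    for name, arr in (("anisotropy", anisotropy), ("totals", totals),
                      ("fiber", fiber)):
        if arr.shape != (ny, nx):
            raise ValueError(f"{name} grid {arr.shape} does not match fits ({ny}, {nx})")
    spacing = np.full((ny, nx), np.nan)
    peak = np.full((ny, nx), np.nan)
    at_bound = np.zeros((ny, nx), dtype=bool)
    valid = np.zeros((ny, nx), dtype=bool)
    iy = fit_table["iy"].to_numpy()
    ix = fit_table["ix"].to_numpy()
    spacing[iy, ix] = fit_table["a"].to_numpy()
    peak[iy, ix] = fit_table["Ip"].to_numpy()
    at_bound[iy, ix] = fit_table["at_bound"].to_numpy().astype(bool)
    valid[iy, ix] = fit_table["converged"].to_numpy().astype(bool)
    return ParameterMaps(spacing=spacing, peak_intensity=peak,
                         anisotropy=anisotropy, orientation=fiber,
                         total_intensity=totals, valid=valid,
                         at_bound=at_bound, fit_params=fit_table,
                         provenance=provenance or {})


@dataclass
class ClusterResult:
    """k-means segmentation of the fit-parameter maps."""

    labels: np.ndarray             # grid, 1..k; 0 = invalid
    centroids: np.ndarray          # (k, n_features) in standardized space
    feature_names: tuple[str, ...]
    spacing_histograms: dict       # label -> (bin_edges, counts)
    inertia: float


def kmeans_segment(maps: ParameterMaps, k: int = 3, seed: int = 0,
                   n_init: int = 10, n_hist_bins: int = 40) -> ClusterResult:
    """Cluster valid points on the z-scored five fit parameters.

    Features with zero variance carry no information and are dropped
    with a warning; labels are reassigned so cluster 1 has the lowest
    mean spacing, ascending.
    """
    table = maps.fit_params
    valid = table["converged"].to_numpy().astype(bool)
    if valid.sum() < k * 10:
        raise ValueError(f"need at least {k * 10} valid points, got {int(valid.sum())}")
    feats = table.loc[valid, list(FIT_FEATURES)].to_numpy(dtype=float)
    std = feats.std(axis=0)
    keep = std > 0
    if not keep.all():
        dropped = [n for n, k_ in zip(FIT_FEATURES, keep) if not k_]
        warnings.warn(f"dropping zero-variance features: {dropped}")
    if not keep.any():
        raise ValueError("all features are degenerate")
    z = (feats[:, keep] - feats[:, keep].mean(axis=0)) / std[keep]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)

    spacing = table.loc[valid, "a"].to_numpy()
    order = np.argsort([spacing[km.labels_ == c].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    new_labels = relabel[km.labels_]

    labels = np.zeros(maps.shape, dtype=int)
    iy = table.loc[valid, "iy"].to_numpy()
    ix = table.loc[valid, "ix"].to_numpy()
    labels[iy, ix] = new_labels

    histograms = {}
    edges = np.histogram_bin_edges(spacing, bins=n_hist_bins)
    for lab in range(1, k + 1):
        counts, _ = np.histogram(spacing[new_labels == lab], bins=edges)
        histograms[lab] = (edges, counts)
    return ClusterResult(labels=labels, centroids=km.cluster_centers_[order],
                         feature_names=tuple(n for n, k_ in zip(FIT_FEATURES, keep) if k_),
                         spacing_histograms=histograms,
                         inertia=float(km.inertia_))


def kde_mode(values: np.ndarray, bandwidth: float | str = "silverman",
             n_grid: int = 512) -> float:
    """Mode of a Gaussian kernel density estimate of the values.

    The density is evaluated on a 512-point grid spanning the data range
    padded by three bandwidths; a constant sample returns that constant.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 30:
        raise ValueError(f"need at least 30 values for a KDE mode, got {values.size}")
    if np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method=bandwidth if bandwidth != "silverman"
                       else "silverman")
    h = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, n_grid)
    return float(grid[int(np.argmax(kde(grid)))])


def _pseudo_voigt(x, amplitude, center, width, eta):
    gauss = np.exp(-4.0 * np.log(2.0) * (x - center) ** 2 / width ** 2)
    lorentz = 1.0 / (1.0 + 4.0 * (x - center) ** 2 / width ** 2)
    return amplitude * (eta * lorentz + (1.0 - eta) * gauss)


@dataclass
class PseudoVoigtFit:
    amplitude: float
    center: float
    width: float     # FWHM, shared between the two components
    eta: float       # Lorentzian fraction in [0, 1]
    converged: bool


def pseudo_voigt_fit(bin_centers: np.ndarray, counts: np.ndarray) -> PseudoVoigtFit:
    """Fit A·[η·Lorentzian + (1−η)·Gaussian] to a histogram."""
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(counts, dtype=float)
    if np.count_nonzero(y) < 10:
        raise ValueError("need at least 10 nonzero histogram bins")
    x0 = float(x[int(np.argmax(y))])
    above = x[y >= 0.5 * y.max()]
    w0 = max(float(above.max() - above.min()), float(np.diff(x).mean()))
    p0 = [float(y.max()), x0, w0, 0.5]
    bounds = ([0.0, x.min(), 1e-9, 0.0], [np.inf, x.max(), np.inf, 1.0])
    try:
        popt, _ = curve_fit(_pseudo_voigt, x, y, p0=p0, bounds=bounds,
                            maxfev=20000)
        return PseudoVoigtFit(*map(float, popt), converged=True)
    except RuntimeError:
        return PseudoVoigtFit(*map(float, p0), converged=False)


@dataclass
class RegionStats:
    """Summary statistics of a masked region of the parameter maps."""

    mask: np.ndarray
    n_points: int
    area_fraction: float
    mean_anisotropy: float
    median_anisotropy: float
    mean_peak_intensity: float
    modal_spacing: float


def region_average(maps: ParameterMaps, mask: np.ndarray) -> RegionStats:
    """Means/medians/modal spacing over the valid points of a region."""
    if mask.shape != maps.shape:
        raise ValueError("mask shape does not match maps")
    sel = mask & maps.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError("region contains no valid points")
    spacing = maps.spacing[sel]
    try:
        modal = kde_mode(spacing)
    except ValueError:
        modal = float(np.median(spacing))
    return RegionStats(mask=mask, n_points=n,
                       area_fraction=float(mask.sum() / mask.size),
                       mean_anisotropy=float(np.nanmean(maps.anisotropy[sel])),
                       median_anisotropy=float(np.nanmedian(maps.anisotropy[sel])),
                       mean_peak_intensity=float(np.nanmean(maps.peak_intensity[sel])),
                       modal_spacing=modal)


@dataclass
class LesionResult:
    mask: np.ndarray
    inside: RegionStats | None
    outside: RegionStats | None


def threshold_lesion(maps: ParameterMaps,
                     threshold: float = DEFAULT_LESION_THRESHOLD,
                     min_region_px: int = DEFAULT_MIN_REGION_PX) -> LesionResult:
    """Mask lesions where spacing ≥ threshold or the fit diverged to a bound.

    Connected components smaller than ``min_region_px`` are removed as
    speckle.  An empty mask is a valid (lesion-free) outcome.
    """
    with np.errstate(invalid="ignore"):
        mask = (maps.spacing >= threshold) | maps.at_bound
    mask &= maps.valid
    labeled, n_comp = cc_label(mask)
    for comp in range(1, n_comp + 1):
        if (labeled == comp).sum() < min_region_px:
            mask[labeled == comp] = False
    inside = region_average(maps, mask) if mask.any() else None
    complement = ~mask
    outside = region_average(maps, complement) if (complement & maps.valid).any() else None
    return LesionResult(mask=mask, inside=inside, outside=outside)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)
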