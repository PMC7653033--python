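# Methods

## Scattering model and geometry

Each scan point's detector frame is treated as a radially decaying
matrix-scattering background plus the (1,1) equatorial reflection of the
acto-myosin lattice:

    I(q, φ) = S·q⁻ᵈ + I_p·exp(−(q − q₀)²/σ²)·A(φ) + I_bgr

with the wavevector transfer q = (4π/λ)·sin(θ/2), θ = atan(r/L). The
Gaussian width σ is fixed at 0.034 nm⁻¹ and the exponent is written with
σ² (not 2σ²) in the denominator; `FitConfig(conventional_width=True)`
switches to the 2σ² convention, in which case the effective width is
σ·√2 so both conventions describe the same physical ring. The filament
spacing is a = 4π/q₀.

The per-exposure dose is D = I₀·τ·E·(μ/ρ)/(Δx·Δy) with the beam area
taken as the product of the horizontal and vertical FWHM — not a
Gaussian-integral area — because the dose figure this formula is meant
to reproduce is defined on the focal FWHM. Defaults: E = 13.0 keV,
I₀ = 1.57 × 10¹² ph/s, τ = 10 ms, μ/ρ = 3.1582 cm²/g (muscle),
2.9 × 1.4 µm focus → D ≈ 2.54 MGy.

Detector distance and pixel pitch are not physically constrained by the
analysis and default to 2 m and 150 µm on a 256 × 256 grid, chosen so
the acto-myosin ring (q₀ ≈ 0.32 nm⁻¹) falls at about half the detector
radius and the 1 mm beamstop wire subtends a small azimuth at the
analysis annulus. A wider angular shadow (e.g. the same wire on a
detector half as far away) truncates azimuthal peaks near the wire and
biases orientation estimates by a few degrees; real multi-megapixel
detectors are far less affected than this deliberately small synthetic
one.

## Synthetic data

**Azimuthal modulation and its calibration.** The ring modulation A(φ)
is a 180°-periodic von Mises density, exp(κ·cos 2(φ − φ_c))/I₀(κ),
normalized to unit circular mean so that I_p remains the azimuthally
averaged peak amplitude. For this family the anisotropy measured by the
downstream estimator (see below) is exactly I₁(κ)/I₀(κ), so the
generator inverts that ratio numerically to realize a requested
anisotropy; the inversion is exact for full angular coverage and holds
within ±0.05 through the masked detector at the anisotropy levels the
phantoms use (≤ 0.6). At very high anisotropy (≳ 0.8) the wire shadow
can clip the narrow azimuthal peak and the realized value may fall short
by slightly more; the phantoms do not operate there.

**Phantoms.** The sham phantom fills the scan grid with tissue at
39.5 nm spacing, anisotropy 0.5 and tangential (concentric) fiber
orientation, wrapped by a higher-spacing outer myocardial layer
(41.2 nm) and a low-spacing epicardial rim (38.0 nm) whose peak
intensity (0.6) lies below the bulk level (1.0), as observed for the
epicardial layer in real sections. The *ring* scenario lowers an inner
annulus by a configurable Δ (default 2.0 nm, bracketing observed
1.7–2.4 nm differences). The *tac_lesion* scenario inserts a compact
off-center disc with spacing 47.2 nm — above both the 46.0 nm lesion
threshold and the 45 nm fit bound — anisotropy 0.10, and a
zero-peak-intensity core emulating replacement fibrosis; the truth
lesion mask is the whole disc. Because the lesion's true q₀ lies below
the allowed fit range, fits inside it are driven to the spacing bound
and flagged, which is exactly how diverged fits manifest on real
lesions.

**Backgrounds and noise.** Background parameters (S = 0.033, d = 3,
I_bgr = 0.1 counts/exposure) are spatially constant so the per-line
empty frames (20 per line, rendered from the same background model)
subtract the background exactly in expectation. Counts are Poisson with
peak intensity ~1 count/exposure, the intensity scale of real scans.
Simulated stacks store the ground truth and round-trip losslessly
through HDF5.

**SHG micrographs.** Striation is rendered as
B + A·cos²(π·(u + U·sin(2π·v/Λ))/p) along a chosen orientation with
additive Gaussian noise; p defaults to 2 µm (sarcomere period) at
0.328 µm/px. The undulation wavelength defaults to Λ = 50 µm ≈ 25
periods. This matters: a sinusoidal undulation concentrates spectral
power in discrete angular sidebands at atan(n·p/Λ), and only for
Λ ≳ 25·p does the first sideband remain inside the narrow (5°) cake
while successive orders populate the wide (20°) cake — the regime in
which the cake-ratio indicator responds smoothly and monotonically to
increasing undulation amplitude. Shorter wavelengths throw the sideband
ladder across or beyond the wide cake and the single-sinusoid model then
produces non-monotonic ratio overshoots that real, irregularly undulated
tissue (with its broad, smooth orientation spread) does not show. The
generator does not emulate intercalated discs, out-of-plane fiber tilt,
collagen SHG, photon shot noise, or tile stitching, so passing tests
demonstrate correctness of the estimator on the stated banding model,
not robustness to every real-micrograph artifact.

## Reduction

Empty frames of each scan line are averaged and subtracted pixel-wise
from that line's sample frames; negative residuals are kept, since
clipping would bias the fitted flat background. I(q) is the mean of
unmasked pixels in 200 linear q bins over the detector's coverage; bins
without pixels are flagged invalid, never interpolated. I(φ) uses 2°
bins restricted to 0.2–0.5 nm⁻¹ and is normalized exactly as
I_norm(φ) = (I(φ) − min I(φ)) / Σ_φ I(φ), with the minimum and sum over
valid bins. Two kinds of φ bins are invalid: bins fully shadowed by the
beamstop, and bins whose pixel count falls below half the median bin
count — the latter sample only part of the annulus's radial extent, so
their mean is not comparable to fully covered bins and would leak a
spurious dip into the profile.

## Orientation and anisotropy

Scattering from fibrous tissue is centrosymmetric, so the ordinary
circular resultant of I(φ) vanishes identically; angles are therefore
doubled (standard axial statistics) before the weighted resultant is
taken, and the mean angle is halved back. This is the single most
consequential choice not pinned down by the printed anisotropy
definition, and it is required for the definition to be non-degenerate.
With weights w(φ) = I_norm(φ) on valid bins:

    z = Σ w(φ)·(e^{i2φ} − c̄),  c̄ = mean of e^{i2φ} over valid bins
    anisotropy = |z|,  Var = 1 − |z|,  φ₀ = ½·arg(z) mod 180°

The c̄ term corrects the coverage bias introduced when the beamstop
removes bins (for full coverage c̄ = 0 exactly and the estimator is the
plain weighted resultant). Fiber orientation is φ₀ + 90°, since the
equatorial reflection is perpendicular to the filament axis. Resultants
below 10⁻³ leave the orientation flagged undefined rather than reported
as noise.

## Peak fitting

Fits run on the 0.15–0.60 nm⁻¹ window (covering the ring, excluding the
beamstop edge) with bounds S, I_p, I_bgr ≥ 0, d ∈ [0, 6], and q₀
restricted so a = 4π/q₀ ∈ [30, 45] nm; the 30 nm lower bound is a
package choice (only the 45 nm boundary is physically motivated by where
diverged fits accumulate). Because the residual surface has a local
minimum in which the Gaussian collapses (I_p → 0) and q₀ drifts to a
bound, initialization scans a coarse q₀ × d grid, solving the three
linear amplitudes by non-negative least squares at each node, and starts
the trust-region optimizer in the best basin; a brute-force grid search
over (q₀, d) serves as an independent optimality oracle in the tests.
Fits are unweighted by default (Poisson weights behind a flag).
Optimizer failure is reported as `converged=False` with the last
iterate, never an exception. The `at_bound` flag uses a 0.01 nm
tolerance to the spacing bounds because trust-region iterates stop
asymptotically close to, not exactly on, a bound.

## Maps, clustering, lesions

k-means (k = 3, ≥ 10 restarts, fixed seed) runs on the z-scored five
fit parameters (S, d, I_p, q₀, I_bgr) over valid points; standardization
is necessary because the raw scales differ by orders of magnitude.
Features with zero variance are dropped with a warning. Clusters are
relabeled so mean spacing ascends with the label, making labels
deterministic and comparable across runs. Note that on *noise-free*
synthetic scans the fitted I_bgr is numerically degenerate (~10⁻¹⁵) and
z-scoring amplifies pure float noise into the cluster metric; clustering
is therefore meaningful on noisy (realistic) data, and the tests
exercise it there.

Spacing histograms are summarized by the mode of a Gaussian KDE
(Silverman bandwidth, 512-point grid over the data range ± 3 bandwidths)
and modeled by a pseudo-Voigt profile with shared FWHM and mixing
η ∈ [0, 1]. Lesions are masked where spacing ≥ 46.0 nm OR the fit ended
at a bound — both criteria are honored because real lesions show fits at
the 45 nm boundary while the stated threshold is 46.0 nm — and connected
components smaller than 4 points are discarded as speckle.

## SHG undulation indicator

The PSD is |FFT|²/N of the mean-subtracted, Hann-windowed (default),
re-centered image, so the PSD sum equals the sum of squared processed
pixels (Parseval) and the DC bin is exactly zero. Windowing is on by
default because edge leakage is anisotropic and would bias the principal
axes. The two symmetry axes come from the eigenvectors of the
PSD-weighted second-moment tensor of frequency coordinates (DC
excluded); eigenvalue ratios below 1.05 flag the axes unstable. Cake
curves average the PSD in 32 radial bins over four sectors centered on
both directions of both axes; the stated opening angle is the full
sector width (half-angle = angle/2) — at 45° the four sectors tile
exactly half the plane. Before binning, the periodogram is smoothed with
a σ = 3 px Gaussian kernel (Daniell-type smoothing): the raw
periodogram has 100% relative variance per pixel, which would put a
large sampling floor under the wide/narrow ratio; smoothing leaves its
expectation unchanged and lowers the isotropic-noise floor of the scalar
to ~0.07–0.09 (the scalar's "≈ 0" endpoint is this sampling floor, not
machine zero). The indicator curve is cake(20°)/cake(5°) per radial bin,
and the scalar is the RMS of (curve − 1) from two radial bins above DC
to 0.8 × Nyquist. The scalar is exactly invariant to image rescaling and
decreases from ~0.27 (straight striation) toward the floor as undulation
grows. Indicators are computed on central 512 × 512 crops by default for
comparability across image sizes. Cohorts are compared by per-heart
means and a two-tailed paired Student's t-test (pairing by heart rank
within group; n and dof are reported explicitly).

## Problem sizes and determinism

The test suite and the acceptance script run the diffraction pipeline on
16 × 16 (sham/isotropic) and 24 × 24 (lesion) scan grids with 256 × 256
frames and 20 empty frames per line, and the SHG cohort as 3 + 3 hearts
× 20 images of 512 × 512 — sizes at which every stage behaves as at
scale while a full run stays in the minutes range on one CPU. All
stochastic stages (Poisson draws, SHG noise, k-means restarts) take
explicit seeds; identical inputs and seeds reproduce outputs
byte-identically, and the CLI echoes the effective configuration and its
hash into a provenance sidecar next to every artifact.

## Known limitations

- Only the (1,1) ring is modeled; meridional reflections and the (1,0)
  peak (absorbed by the beamstop in practice) are not rendered.
- No polarization, solid-angle or flat-field detector corrections.
- The anisotropy calibration degrades near anisotropy 1 behind a wide
  beamstop shadow (peak truncation).
- Orientation is 2D (in-plane); out-of-plane fiber tilt is not modeled.
- The undulation indicator's absolute scale depends on the radial
  binning, smoothing and band choices; comparisons are meaningful within
  one configuration (which the provenance sidecar records), not across
  configurations.
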