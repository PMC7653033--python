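# myoscan

Quantitative analysis of scanning micro-focus X-ray diffraction and
second-harmonic-generation (SHG) imaging of cardiac tissue sections.

Striated muscle diffracts X-rays from its hexagonal acto-myosin filament
lattice. Raster-scanning a micro-focused beam over a whole heart cross
section yields one 2D scattering pattern per scan point, and from each
pattern four structural parameters can be mapped across the tissue: the
filament lattice spacing, the strength of the (1,1) equatorial
reflection, the cardiomyocyte chain orientation, and the degree of
orientational order (anisotropy). In pressure-overload disease models,
regions of replacement fibrosis lose the acto-myosin reflection, show
reduced anisotropy, and are surrounded by tissue with increased lattice
spacing — so these maps localize and quantify pathological remodeling
label-free. SHG microscopy complements this at the sub-cellular scale:
healthy myofibrils produce a straight, periodic striation pattern, while
remodeled tissue shows undulated, distorted fibers, which this package
quantifies with a spectral indicator.

`myoscan` implements the full analysis chain plus a synthetic-data
generator with known ground truth, so every stage is testable without
beamline data:

1. **geometry** — detector q/φ maps from q = (4π/λ)·sin(θ/2), and the
   per-exposure dose D = I₀·τ·E·(μ/ρ)/(Δx·Δy).
2. **synthetic** — scan stacks rendered from the forward model
   I(q, φ) = S·q⁻ᵈ + I_p·exp(−(q−q₀)²/σ²)·A(φ) + I_bgr with Poisson
   noise, a beamstop-wire mask, per-line empty frames, and phantoms with
   sham / low-spacing-ring / fibrotic-lesion scenarios; plus striated
   SHG micrographs with controllable undulation.
3. **reduction** — per-line empty-frame background subtraction, angular
   averaging to I(q), radial averaging (0.2–0.5 nm⁻¹) to I(φ) and its
   normalization I_norm(φ) = (I(φ) − min I(φ)) / Σ_φ I(φ).
4. **peakfit** — nonlinear least squares of the power-law + Gaussian
   model (σ fixed at 0.034 nm⁻¹) and the spacing conversion a = 4π/q₀,
   with bounded q₀ so diverged fits land flagged at the 45 nm bound.
5. **orientation** — axial circular statistics on I_norm (angle
   doubling): anisotropy = 1 − Var, fiber orientation = φ₀ + 90°.
6. **segmentation** — parameter maps, k-means (k = 3) on the z-scored
   five fit parameters with ascending-spacing labels, KDE modes and
   pseudo-Voigt fits of spacing histograms, and lesion masks from the
   46.0 nm spacing threshold OR-combined with the at-bound flag.
7. **shg** — 2D power spectral density, PCA principal axes, cake
   integration at 5°/20° opening angles, the wide/narrow ratio curve and
   its RMS deviation from 1 as a scalar undulation indicator, and paired
   two-tailed t-tests of per-heart indicator means.

## Worked example

```python
import myoscan as ms
from myoscan.reduction import reduce_scan
from myoscan.peakfit import fit_scan
from myoscan.orientation import orientation_map
from myoscan.segmentation import assemble_maps, kde_mode, threshold_lesion

geom = ms.BeamGeometry()                       # 13 keV, 2.9 × 1.4 µm focus
print(f"dose per exposure: {ms.dose(geom)/1e6:.2f} MGy")

truth = ms.make_default_phantom((24, 24), "tac_lesion")
stack = ms.simulate_scan(truth, geom, noise_seed=0)
maps = ms.coordinate_maps(geom)
reduced = reduce_scan(stack, maps)
fits = fit_scan(reduced)
phi0, fiber, anis, ok = orientation_map(reduced.inorm, reduced.phi,
                                        reduced.phi_valid)
pmaps = assemble_maps(fits, phi0, fiber, anis, reduced.totals)
print(f"modal spacing (whole section): "
      f"{kde_mode(pmaps.spacing[pmaps.valid]):.1f} nm")
lesion = threshold_lesion(pmaps, threshold=46.0)
print(f"lesion area fraction: {lesion.mask.mean():.3f}")
print(f"mean anisotropy inside lesion: {lesion.inside.mean_anisotropy:.2f}, "
      f"outside: {lesion.outside.mean_anisotropy:.2f}")
```

prints

```
dose per exposure: 2.54 MGy
modal spacing (whole section): 39.4 nm
lesion area fraction: 0.069
mean anisotropy inside lesion: 0.17, outside: 0.51
```

The 2.54 MGy is the absorbed dose of one 10 ms exposure at the default
beam parameters. The modal lattice spacing of the simulated section sits
at the healthy ~39 nm level, while thresholding the spacing map at
46.0 nm isolates the simulated fibrotic lesion, whose orientational
order (0.17) is far below the surrounding myocardium (0.51) — the
signature of replacement fibrosis.

The same stages are available from the shell:

```sh
myoscan all --out-dir run/            # simulate → reduce → fit → ... → dose
myoscan dose                          # prints the 2.54 MGy worked example
myoscan shg-indicator --manifest images.csv --out-dir shg/
```

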