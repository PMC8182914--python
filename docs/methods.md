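# Methods

This note documents the models, parameter choices and limitations of
`mar-evalkit` in the order data flows through the pipeline.

## Synthetic anatomy

Each case is a seeded head-and-neck phantom on a 512×512 grid (configurable
down to 64 for tests) with a field of view drawn per case from 350–400 mm
and a slice thickness of 1–3 mm (default 2 mm, 24 slices). Tissue classes
are air (−1000 HU), soft tissue (40 HU), bone (700 HU) and tooth (1200 HU).

Geometry, all in millimetres and jittered per seed:

* an elliptical soft-tissue **body** (half-axes ≈ 95 × 80) in air;
* a U-shaped **mandible/maxilla** bone band above and below the dental
  slices; the posterior wedge is open, as in real jaws, so no bone crosses
  the tongue base;
* sixteen **teeth** — ellipsoids of radius ≈ 4 mm (molar-scale) spaced over
  the anterior 240° of an elliptical dental arch, spanning 3–8 axial slices
  depending on slice thickness;
* an **oral air cavity** inside the arch above the tongue;
* a **CTV** — a seeded superellipsoid (exponent 2.5, ≈ 90–160 ml) at the
  tongue base *inside the arch concavity*. This placement matters: the
  dental dark bands form between fillings, i.e. exactly across the tongue
  base, which is why dental artifacts are a problem for this treatment site
  at all;
* placeholder spinal-cord and parotid masks (generated, not scored).

Two realism choices that affect everything downstream:

* **Bandlimiting.** The anatomy HU image is blurred with an in-plane
  Gaussian PSF (σ = 0.7 px) before noise. Clinical CT is bandlimited by the
  scanner reconstruction kernel; a binary-rasterized phantom would carry
  super-Nyquist edges that no projector/reconstructor pair can round-trip,
  and that error floor would mask the artifact signal being studied.
* **Body ROI semantics.** The body mask is the full-density tissue region:
  the partial-volume rim at air interfaces (outer contour, oral cavity) is
  excluded (erosion by ⌈4σ⌉ px in-plane). HU-threshold artifact detection
  inside the body therefore cannot trigger on anatomy edges.

Additive white Gaussian noise (sd 10 HU) is applied inside tissue only; air
stays exactly −1000 HU, so a zero-noise config reproduces tissue HU exactly.

**Filling schemes.** Pseudo-dental fillings are made by assigning exactly
4000 HU to selected whole teeth. Per case a seeded draw selects eight teeth
(m8); the first four of the draw are the m4 scheme, so m4 ⊂ m8 always and
the two schemes form a paired design. The draw is weighted toward posterior
teeth (molars 3.0, premolars 1.5, incisors/canines 0.5) because dental
restorations cluster in molars; uniform selection occasionally yields
all-anterior m4 sets whose artifacts barely reach the target region.

## Acquisition and artifact model

**Geometry.** Equiangular fan beam: 984 views over 360°, 920 bins,
source-to-isocenter 595 mm, source-to-detector 1190 mm. The fan angle is
derived so the detector covers a 400 mm FOV with a 10% margin at isocenter
(coverage radius 220 mm); objects outside that radius raise a truncation
error. The default *desk-scale* profile halves the sampling
(492 × 460) and pairs it with a 128 matrix so a 13-case study runs in
minutes on one CPU; the clinical 512/984/920 profile is
`StudyConfig.paper_profile()`.

**Forward projection** marches each source→bin ray across the slice with a
step of half the pixel pitch and bilinear interpolation, integrating
μ = μ_w(1 + HU/1000) floored at 0, μ_w = 0.0193 mm⁻¹ (≈ 70 keV effective).
The inner loops are numba-compiled. The test suite holds the projector to
< 0.5% relative RMS against a 10×-oversampled brute-force integrator.

**Corruption.** Per ray, the detected intensity is
`I = I₀ Σ_k w_k exp(−p_k)` with `p_k = p + (c_k − 1)·p_metal`, where
`p_metal` is the metal-only line integral (obtained by forward-projecting
the metal-masked attenuation image) and

* `c_low = metal_density_scale × metal_mu_scale` in the low-energy bin,
* `c_high = metal_density_scale` in the high-energy bin.

Defaults: I₀ = 2·10⁵ photons/ray, spectrum {50 keV: 0.7, 80 keV: 0.3},
`metal_mu_scale` = 2.5, `metal_density_scale` = 8. The rationale:

* The stored 4000 HU of a filling is a 12-bit-clamped value; physical
  amalgam attenuation is several-fold higher. `metal_density_scale`
  restores a credible bulk attenuation and is what drives photon
  starvation (rays through two fillings drop to ~10²–10³ photons).
* A 120 kVp beam is low-energy-dominant; the dark-band depth attainable by
  a two-bin beam-hardening model is capped by −ln(w_high), so the weights
  carry physical meaning. With w_high = 0.3 the cap is ≈ 1.2 in line
  integral, producing dark bands of a few hundred HU between fillings.
* These values were fixed once, by matching the study's operating point
  (overlap ratios of the corrected region with the PTV in the single-digit
  to low-double-digit percent range, artifacts visible but not saturating),
  and are surfaced in the YAML config, not buried.

Poisson noise is seeded per slice from the model seed; intensities below
one photon are clamped (photon starvation). With no metal and I₀ → ∞ the
corruption is exactly the identity, a property the tests exercise.

**Reconstruction.** Fan data are rebinned to a parallel (θ, s) grid
(bilinear, 360° with half weight for the two-fold redundancy), ramp-filtered
with the band-limited discrete kernel under a Hann window, and
backprojected with linear interpolation. Pixels outside the fan coverage
circle are reported as air. On a smooth (σ = 1.5 px) metal-free head slice
the FBP∘FP round trip is < 30 HU RMSE inside the body at the desk profile
(≈ 6 HU measured); sharp metal edges reconstruct with the expected Gibbs
overshoot, which is part of the simulated artifact, not an error term.

Slices without metal pass through the artifact stage unchanged; the
difference image between Artifacts and Reference is therefore exactly zero
off the dental slices, which the streak-signature tests rely on.

## Correction strategies

**Water override** (surrogate for the clinical manual correction): voxels
inside the body ROI, outside metal, on metal-bearing slices, with
HU < −200 or > 300, are morphologically closed (radius 1) and set to
exactly 0 HU (water, 1.0 g/cm³). The thresholds are configurable; a manual
observer is neither deterministic nor reproducible, which is the point of
the surrogate. The resulting *corrected region* is also the numerator of
the overlap-ratio analysis.

**Sinogram inpainting MAR**: per metal-bearing slice, the Artifacts image
is re-projected, bins whose metal line integral exceeds 0.5 mm of metal
(trace segmentation — bins merely grazing a filling carry mostly valid
data) are replaced by 1D linear interpolation along the detector axis per
view, the slice is reconstructed, and the original metal voxels are pasted
back. A trace spanning an entire view falls back to view-axis interpolation
(logged). This classical baseline exhibits the known residual
blur/secondary-shading failure mode near metals; it stands in for a learned
MAR model in the pipeline's plug-in slot.

**Plug-ins.** Any corrector implementing
`correct(artifacts, metal_mask) -> volume` can occupy the MAR slot,
including an external-command adapter that exchanges NIfTI files — the
integration path for a trained network. Outputs are validated for
alignment and finiteness; violations raise an error naming the plugin.

## Evaluation

* **PTV** = CTV expanded by a 5 mm Euclidean margin (distance transform
  with physical sampling; voxel-center semantics, anisotropy honored).
* **RMSE** and **SSIM** are computed within the PTV against the Reference.
  SSIM uses 2D slice-wise maps (the corruption is slice-wise), Gaussian
  window σ = 1.5 truncated at 11×11, k₁ = 0.01, k₂ = 0.03 and a *fixed*
  2000 HU data range, so per-volume rescaling can never contaminate
  cross-condition comparisons; the reported value is the mean of the local
  map over PTV voxels ("within the PTV" read literally, not as a bounding
  box crop). ROIs transfer between conditions by identity — all volumes of
  a case share one grid, enforced by alignment assertions rather than
  resampling.
* **Overlap ratio** = |corrected region ∩ PTV| / |PTV|, shared by all three
  conditions of a case/scheme (it is a property of the detected region).
* **Statistics**: one-way ANOVA across the three conditions per scheme
  (α = 0.05, mirroring a single p per scheme and metric); OLS slope of
  SSIM on overlap ratio per condition and scheme; two-sided Mann–Whitney U
  (exact when n ≤ 12 without ties, else normal approximation with tie and
  continuity corrections) comparing m4 vs m8 SSIM.

## Orchestration and reproducibility

`run_study` is a pure function of (config, master seed): per-case seeds are
spawned via `numpy.random.SeedSequence([master_seed, case_index])`, the FOV
is drawn per case from the 350–400 mm envelope, and per-slice corruption
streams are children of the case's corruption seed. Reruns produce
byte-identical metric CSVs. The resolved config, per-stage wall times and
failures (failed cases are skipped and listed) are recorded in the output
directory alongside `metrics.csv` and `summary.json`.

Problem sizes: tests and `scripts/acceptance.py` run the 128-matrix,
16-slice, 492×460 profile (13 cases ≈ 4 minutes on one CPU); the library
default study profile uses 24 slices; the clinical profile is a config
switch.

## What the synthetic study does and does not show

The generator reproduces the *structure* of the clinical problem: paired
filling schemes with nested severity, artifacts that are strongest across
the tongue base, corrections that act where artifacts are visible, and the
negative coupling between target-region similarity and the extent of the
corrected region. Passing tests demonstrate the pipeline's internal
correctness and these directional relationships.

They do not demonstrate performance on real patients: the phantom has no
soft-tissue contrast or anatomical variability beyond jittered primitives;
the corruption model has two energy bins, no scatter, no detector
cross-talk, and a single-material metal model; the acquisition is 2D
fan-beam per slice rather than helical cone-beam; and the MAR baseline is
deliberately classical. Dose calculation is out of scope entirely — the
framework scores geometry (HU fidelity), not dosimetry. Absolute metric
values depend on the corruption operating point; only orderings and
correlations are claims of the synthetic study.
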