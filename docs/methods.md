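# Methods

## Sensor model and the synthetic scene generator

The generator (`hsiprep.phantom`) renders a line-scan acquisition on the
canonical (x, y, band) grid:

    DN(x, y, b) = L(y, b) · ρ(x, y, b) + ξ(y, b) + ε(x, y, b)

* **L(y, b)** — illumination × detector gain, in DN per unit reflectance.
  Default: full scale 1000 DN with a parabolic fall-off of 15% toward the
  ends of the field-of-view line, flat across bands (uneven lamp
  illumination along the line is the dominant real-world gain structure;
  spectral gain shape cancels in every correction considered, so modeling it
  adds nothing to the tests).
* **ξ(y, b)** — structured dark-current noise, *exactly* constant along the
  scan axis by construction (it is stored as a 2D field and broadcast).
  Default amplitude 5% of full scale; shape = sum of four random
  low-frequency cosine waves over the (row, band) plane, shifted to be
  strictly positive — a smooth stand-in for temperature-driven dark-current
  drift across detector rows and spectral channels.
* **ε** — i.i.d. zero-mean Gaussian sensor noise, default σ = 0.5% of full
  scale.

The scene is a bright flat stage (reflectance 0.9), three calibrated plates
(2%, 50%, 98%) occupying scan-axis intervals that span the full
field-of-view line, and 16 elliptical seed blobs of two spectral classes in
the remaining sample region. Blob semi-axes are drawn from 6–10 px with a
hard-core minimum center spacing of 20 px (sequential placement with
retries; 16 blobs is comfortably below the saturation density of the
region, so placement succeeds for any seed). Each blob gets a radial
multiplicative shading gradient (edge factor 0.6) emulating the 3D shape
that makes single-threshold segmentation hard on real seeds.

Class spectra are smooth analytic curves on 400–1000 nm: healthy seeds show
a vegetation-like red edge near 720 nm; infected seeds are brighter in the
visible (bleached/pink tissue) and weaker past the red edge. The default
contrast gives a peak separation of ≈0.12 reflectance. The default grid is
220 × 120 pixels × 60 bands — deliberately smaller than a real acquisition
(hundreds of bands, larger frames) so a full pipeline run takes seconds;
every algorithm is resolution-agnostic.

**What the phantom does not emulate:** mixed pixels at blob edges, pushbroom
geometric distortion, spectrally structured gain, detector nonlinearity, and
spatially correlated sensor noise. Tests passing on the phantom therefore
demonstrate algorithmic correctness under the stated model, not instrument
robustness.

All randomness flows from `SceneSpec.rng_seed` through independent named
streams (noise field, blob placement, sensor noise, dark frame), so renders
are bit-reproducible and references can be re-drawn independently.

## Double-plate correction

`estimate_noise` solves the two-plate system exactly:
ξ = (R₁f₂ − R₂f₁)/(R₁ − R₂). This is an algebraic identity whenever the
plate column means equal their model values — the test suite asserts exact
(< 1e-12) reflectance recovery with ε = 0 for arbitrary ξ and L fields.
Numerical guards: the plate pair must satisfy |R₁ − R₂| ≥ 1e-6; calibration
DN at or below a floor (default 1e-9 of the profile's full scale) raises
instead of producing infinities. Plate reflectance may be a scalar or a
per-band curve (calibrated plates are near-flat spectrally, but the curve
form costs nothing). Plates that span only part of the field-of-view line
are extrapolated to the remaining rows by nearest neighbor, with a warning —
the noise field is needed at every row.

The black-and-white baseline uses a white profile measured in-scene and a
lens-capped dark frame. Its characteristic failure — a dark frame carrying a
*different* dark-current realization than the scene — is reproduced by
`render_references(spec, dark_noise_seed=...)`; a regression test asserts
the double-plate MSE on the 50% plate beats the stale-dark-frame baseline.

Correction quality is scored as the per-band squared error of the corrected
50%-plate mean spectrum against its known constant 0.500 value, averaged
over a 500–900 nm window (the spectral region where both calibration plates
are far from the sensor's low-signal ends).

## Segmentation

Band selection uses the spectral angle of each flattened band image against
a reference direction. The default reference is the all-ones direction,
making the angle a scale-invariant measure of spatial heterogeneity: bands
where targets contrast strongly against the stage score highest. The
literal coordinate-axis reading (`basis_axis`) and a mean-image reference
(`mean_spectrum_direction`) are selectable. The top-k (default 20) band
images are averaged — uncorrelated per-band noise shrinks by averaging while
the common spatial structure is preserved — and thresholded (Otsu by
default, manual override available; default polarity `below`, i.e. dark
targets on a bright stage).

The PCA branch treats pixels as observations and bands as variables,
centers by the mean spectrum, and fixes the arbitrary eigenvector sign so
every score image has non-negative skewness (minority structure on the
positive side — a pure reproducibility convention). Which component shows
the targets with distinct contours is a property of the scene: on the
original use case it was the second component, chosen by visual inspection.
A fixed index is brittle, so the pipeline default is `pc_index="auto"`:
among the leading `n_components` (default 6), pick the component/polarity
whose thresholded mask agrees best (Dice) with the spectral-angle mask.
This operationalizes the by-eye choice while keeping an explicit integer
index and fixed polarity selectable; the diagnostics record which component
and polarity were used.

The final mask is the intersection of the two branches — it can only remove
pixels relative to either branch, which suppresses each branch's isolated
false positives.

## SG and TSG filtering

`sg_projection_matrix` builds B = X(XᵀX)⁻¹Xᵀ with the window offsets scaled
to [−1, 1] and the projector computed via QR (B = QQᵀ): the column space —
and hence B — is unchanged, but the computation stays accurate up to
n = 2m at m = 10, where raw Vandermonde normal equations (and, notably,
`scipy.signal.savgol_coeffs`) lose precision. The kernel (center row) is
symmetrized and renormalized against ~1e-16 floating-point residue so the
declared invariants (symmetry, unit sum) hold exactly.

The TSG kernel places the 1D coefficients by radial distance index
⌊√(i²+j²)⌋ along the four symmetry directions, weight /4 per direction,
center weight b[0]. Distance indices beyond m (outer diagonal corners, e.g.
offset (3,3) → ⌊√18⌋ = 4) get weight 0, keeping support inside the declared
window. The raw grid's DC gain can then fall below 1 (226/231 at m=3, n=4),
which would darken filtered images by ~2%; kernels are therefore
renormalized to unit sum by default, with the unnormalized construction
retained behind a flag and recorded in output metadata.

Boundary handling defaults to mirror padding (no edge darkening); zero
padding is kept for the convolution-identity test, and spectral filtering
additionally offers polynomial-edge fitting. FFT and direct spatial
convolution are both exposed and agree to 1e-8 relative error.

At the default phantom noise level, TSG filtering strictly reduces the
sensor-noise component in every band but *increases* whole-cube RMSE against
the noise-free truth, because blurring the sharp seed/stage edges costs more
than the small noise removal gains; off the edges, RMSE strictly drops. This
mirrors the expected trade-off for an aggressive spatial filter (structural
similarity to the input decreases even as noise metrics improve) and is
asserted as such in the tests.

## Quality metrics

Single-image conventions are stated explicitly because the literature
varies: entropy = Shannon entropy of a 256-bin histogram spanning the
image's own value range (so it measures the spread of the value
distribution, ≤ 8 bits); SNR = 20·log₁₀(mean/std) per band; clarity = mean
central-difference gradient magnitude over interior pixels. PSNR uses the
reference maximum as peak by default (set 1.0 for reflectance cubes); SSIM
is the standard Gaussian-window (11×11, σ=1.5) form with K₁=0.01, K₂=0.03.
These definitions reproduce the expected directional behavior under
filtering (entropy and SNR rise, clarity falls, SSIM below 1) and are not
calibrated to any external absolute scale.

## Classification pipeline

Datasets draw `n_train` + `n_test` pixels per cube per class without
replacement from labeled foreground pixels (defaults 720/80, keeping the
9:1 train:test convention; sized to the worst-case per-class pixel yield of
the default scene). `pca-k` features (default k=6) are fitted on training
samples only. The classifier is an RBF-SVM (C=1, variance-scaled gamma) —
a deliberately standard choice delegated to scikit-learn; the evaluation
statistics (confusion matrix, test accuracy, pooled train+test "total"
accuracy, Cohen's kappa) are computed in-package. "Total" accuracy is
defined as accuracy over the pooled train+test predictions; accuracy over
all labeled pixels is available by relabeling and rebuilding the dataset.

On the default phantom the two seed classes are separable enough that all
three comparative rows (no filter / SG / TSG) typically reach accuracy 1.0;
the comparative machinery is exercised for ordering and determinism, not for
effect-size claims.

## Numerical and degenerate-input choices

* Spectral angle of an all-zero band: π/2 with a warning (a zero vector has
  no direction; π/2 ranks it as uninformative).
* Otsu on a constant image: error advising a manual threshold.
* Top-k band ties: lower band index wins; entropy-band ties likewise.
* Reflectance cubes are never clipped to [0, 1] on I/O or correction;
  slight overshoot is legitimate and clipping is left to callers.
* All half-open index ranges; canonical axis order (x, y, band) everywhere;
  ENVI interleaves are canonicalized on read.

## Known limitations

* The ENVI reader supports uint16/float32/float64, interleaves bsq/bil/bip,
  single-file raw data; no georeferencing, BIP streaming or compression.
* The noise model assumes ξ exactly constant along the scan axis; slow
  within-scan drift is not modeled or corrected.
* `correction` assumes illumination is independent of x over the plate
  footprints (it cancels between plates only then); the phantom obeys this.
* Watershed/region-growing baselines and morphological post-cleaning are
  intentionally absent; the mask intersection is the only false-positive
  control.
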