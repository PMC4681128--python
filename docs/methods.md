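# Methods

This note documents the models, conventions and design decisions behind
`depoloct`, and the validation design used by the test suite. It states no
empirical result that the tests or `scripts/acceptance.py` do not themselves
compute.

## Signal model and reconstruction

A Fourier-domain PS-OCT measurement provides, per lateral position, two real
spectral interferograms `s1(k), s2(k)` — one per orthogonal polarization
channel — sampled on a uniform wavenumber grid. The package assumes the grid
is already linear in k: spectrometer λ→k resampling and dispersion
compensation are acquisition-side steps outside its scope (apply a
user-supplied resampler to `RawSpectra.data` beforehand if needed).

`preprocess_spectra` subtracts the mean spectrum across A-lines per channel
and frame, removing reference-arm DC and fixed-pattern terms while leaving
speckle-varying signal intact.

`reconstruct` applies the unitary (`norm="ortho"`) inverse DFT along k and
keeps the positive-frequency half: `samples // 2` depth pixels with pitch
`π / (k span)` µm, depth index 0 at zero delay. The unitary convention makes
Parseval's identity hold without scale factors (checked on the full
transform, `depth="full"`), which pins down the amplitude convention:
reconstructed intensity equals apodized spectral energy. Complex-conjugate
removal is out of scope; the phantom writes carriers as
`Re{c(k)·exp(−i·2kz)}` so the unconjugated Jones coefficients land in the
retained half. Within the retained half, residual conjugate-lobe leakage is
bounded by the source-spectrum amplitude at the grid edge: with the default
span of 3 source-FWHM it limits single-scatterer state recovery to ~3·10⁻⁴
rad; at 6 FWHM the round trip is exact to <10⁻⁷ rad (the precision tests use
the wider span for this reason).

Sub-band reconstruction multiplies the spectra by a window `G(k_β, Δk)`
before the same transform. Windows are Gaussian (σ = FWHM/(2√(2 ln 2))) or
rectangular (half-open `[k_β − Δk/2, k_β + Δk/2)`; the topmost grid sample is
assigned to the last tile so contiguous tiles partition the grid). Gaussian
windows truncate at the grid edge without reshaping. Per-window unit-L2
energy normalization is on by default so bands with unequal source power
contribute comparably — the band-weighting question is not settled by the
source material, and normalization is the neutral choice; the detected
spectral shaping S̃(k) is *not* divided out before windowing, since with
energy-normalized windows its effect on sDOPU is second order. Band centers
given in wavelength convert exactly via `k = 2π/λ` (and the band FWHM via the
band-edge formula `Δk = 2πΔλ/(λ² − Δλ²/4)`), not the small-bandwidth
linearization; the default bank is 820/840/860 nm with 20 nm FWHM on a
840 nm / 60 nm-FWHM source.

## Polarimetry conventions

Stokes parameters follow `I = A1²+A2²`, `Q = A1²−A2²`, `U = 2A1A2 cos ΔΦ`,
`V = 2A1A2 sin ΔΦ` with the sign convention `ΔΦ = arg(e1·conj(e2))` (channel
1 leading; fixes which circular handedness carries V > 0 — the underlying
measurement only defines ΔΦ up to sign). A pixel derived from one Jones
vector satisfies `I² = Q²+U²+V²`; this and invariance under a global phase
are enforced as property tests.

Low-reflectivity masking: the noise floor is the median intensity of the
deepest 10 % of pixels (assumed signal-free), and a pixel is valid when its
intensity exceeds the floor by `threshold_db` (default 15 dB). Both the floor
estimator and the threshold are config-exposed; the display convention
renders invalid pixels gray.

## The three estimators

All three report the Euclidean norm of an averaged Stokes vector; they
differ in the ensemble and in the normalization convention:

- **spatial** — per-pixel-normalized `(q,u,v)` averaged over a centered
  `kernel_x × kernel_z` window. Windows truncate at borders (no padding, so
  no fabricated states), masked pixels are excluded and the divisor is the
  count of valid contributors; a window with fewer than two valid pixels
  keeps the single-pixel value 1. The window at pixel p spans
  `p − (k−1)//2 … p + k//2` per axis.
- **temporal** — the same normalized average per pixel across frames, after
  aligning each frame (and its mask) to the first by integer shifts; pixels
  valid in fewer than two frames are flagged invalid. Registration is
  integer-pixel on mean-subtracted log-intensity via FFT cross-correlation,
  ties broken toward the smaller displacement magnitude then
  lexicographically. Sub-pixel warping is deliberately avoided: resampling
  would interpolate, i.e. mix, polarization states.
- **spectral (sDOPU)** — follows its definition literally: unweighted means
  of the *unnormalized* band Stokes parameters, `√(⟨Q⟩²+⟨U⟩²+⟨V⟩²)/⟨I⟩`.
  A `normalize_bands` flag switches to normalized-band averaging for
  sensitivity studies. Whether the temporal estimator should normalize per
  frame before averaging is likewise not fixed by the source material; the
  conventional normalized reading is the default and the spectral-style
  unnormalized alternative is what the flagged sDOPU variant explores.

All valid outputs lie in [0, 1] (triangle inequality; for the spectral form,
`|⟨S⟩| ≤ ⟨|S|⟩ ≤ ⟨I⟩`), and every estimator is invariant under one global
unitary Jones rotation applied to all pixels/bands/frames.

### Sub-band ↔ axial-kernel equivalence

With many narrow windows tiling the band, the sub-band average of a Stokes
parameter corresponds to an axial average under g, the depth-domain transform
of the window shape, so sDOPU approximates DOPU with a 1 (x) × g (z) kernel.
`kernel_equivalence_check` builds g by sampling the transform magnitude of
one band window at the depth-pixel spacing, zeroing entries below 1 % of the
peak and normalizing to unit sum (odd length, centered). Because the
correspondence is between unnormalized averages — the convention sDOPU itself
uses — the primary comparison map g-averages raw Stokes parameters and
divides by the g-averaged intensity; the normalized-averaging variant is
reported alongside. The check returns per-pixel absolute-difference
statistics and the Spearman rank correlation over jointly valid pixels.

## The phantom

The simulator realizes the interferometric signal model directly: per
A-line, `s_c(k) = Σ_j a_j √S(k) · Re{e_cj(k) · exp(−i(2k z_j + φ_j))}` over
discrete scatterers with Poisson counts per A-line per layer, uniform depths
within each layer, Rayleigh amplitudes scaled by √reflectivity, uniform
random scattering phases (fully developed speckle), a Gaussian lateral PSF
(default σ = 1.5 A-lines, periodic in x) coupling scatterers into
neighboring A-lines, a Gaussian source spectrum, and additive Gaussian
detection noise.

Depolarization is modelled at the scatterer level — one mechanism family
with three knobs, rather than an explicit Mueller depolarizer — matching the
attribution of tissue scrambling to granule-scale scattering:

- `depol_index` δ ∈ [0,1]: scatterer state = `normalize((1−δ)·s0 + δ·u)`
  with s0 the circular illumination state and u isotropic on the Poincaré
  sphere. δ=0 leaves a layer uniform; δ=1 is exactly isotropic (verified
  against a Monte-Carlo resultant-length null). The perturbation is drawn
  per scatterer, not per layer: within-kernel state diversity is the very
  mechanism that produces depolarization contrast.
- `spectral_decorr` χ ≥ 0: per-scatterer k-linear retardance with slope
  drawn `N(0, χ)` rad per grid span, applied as ±slope/2 channel phases, so
  the state rotates about the Q axis across the spectrum. The per-scatterer
  spread between band states equals slope × (band separation)/(grid span)
  exactly (verified against an analytic single-scatterer oracle). Slopes are
  stored as unit normals scaled by χ so a fixed seed shares its speckle
  realization across χ levels — sweeps are paired comparisons.
- `frame_decorr` τ ∈ [0,1]: fraction of each layer's scatterers redrawn per
  frame; stands in for out-of-plane motion, which is not modelled as a
  correction.

Rigid per-frame (dz, dx) drift emulates bulk motion (the µm-scale in-plane
motion reported for retinal sequences); scatterers drifting beyond the
unambiguous depth are rejected with a diagnostic. All randomness flows from
one `SeedSequence` through named substreams (layer, frame, noise), making
identical spec + seed bit-identical.

χ is a phantom knob, not a calibrated tissue property: no quantitative DOPU
level is claimed to match real melanin optics, and phantom-based thresholds
are self-referential (oracle- and trend-based) by construction.

Noise calibration: `with_snr` synthesizes one noiseless frame, takes the
median reconstructed intensity over truly occupied pixels, and sets the
spectral noise σ so that the per-depth-pixel noise intensity (equal to σ²
under the unitary transform) sits the requested SNR below it. Ground truth
includes per-pixel layer labels, programmed support (splat of scatterer
energy under the axial/lateral PSFs, thresholded 20 dB below peak — the
emulated system's displayable dynamic range), and programmed integer pixel
shifts.

The default `two_layer` phantom (512 k-samples, 96 A-lines, preserving layer
60–160 µm with δ=χ=0, depolarizing layer 220–380 µm with δ=0.8, χ=6, density
15 scatterers per A-line per layer, 30 dB SNR) is the canonical test
substrate; `retina_like` and `iris_like` presets mirror a preserving stack
over a thin strongly scrambling band and a preserving surface over a
scrambling bulk, respectively.

What the phantom does *not* emulate: physically calibrated melanin optics,
Mie phase functions, absorption, y-motion dynamics beyond frame
decorrelation, swept-source acquisition, spectrometer response. Passing
tests therefore demonstrate correctness and trend behavior of the
estimators, not quantitative agreement with any tissue.

## Validation design and problem sizes

- Analytic limits (single pixel, parallel ensembles, single-band and
  collinear-band sDOPU = 1) and the pure-state identity are checked exactly
  (10⁴ random Jones pairs, 10⁻¹² relative).
- Every estimator is compared to an unvectorized double-loop reference on
  seeded 32 × 32 fields at 10⁻¹² absolute agreement, including NaN patterns.
- Isotropic-ensemble spatial DOPU is checked against a 10⁵-replicate
  Monte-Carlo resultant-length null (central 99 % interval).
- The sub-band ↔ axial-kernel check runs on the two-layer phantom with 16
  tiled rectangular windows; kernel-size and decorrelation trends use the
  default phantom at 48–96 A-lines across 10 seeds.
- The spectral-decorrelation sweep uses levels χ ∈ {0, 3, 6, 10, 16}
  rad/span with five independent speckle realizations pooled per seed and
  level (64 A-lines each). The levels sit inside the estimator's response
  region — the intensity-weighted band average saturates near 0.70 for
  χ ≳ 16 under the default geometry — and the pooling keeps each expected
  step a few times larger than the layer median's sampling error, so the
  per-seed monotonicity check is adequately powered rather than a coin flip
  on sampling noise.
- Registration recovery uses programmed integer drifts up to ±15 pixels,
  5 frames × 20 seeds, with 10 % per-frame scatterer redraw.

Problem sizes throughout (256–512 spectral samples, 32–96 A-lines, ≤ 8
frames) are chosen so the full suite runs in minutes on one CPU while
keeping ≥ ~4 × 10³ valid pixels behind every layer-median statistic.

## Known limitations

- Integer-pixel registration only; sub-pixel motion appears as residual
  temporal decorrelation, as it does in practice without state-mixing
  interpolation.
- sDOPU's literal intensity weighting compresses its dynamic range: pixels
  where one band dominates the intensity read high regardless of state
  spread, flooring the depolarizing-layer median near 0.70 under the default
  three-band geometry. This is a property of the estimator definition, not
  of the implementation; the `normalize_bands` flag explores the
  alternative.
- The λ→k-linear grid assumption means real spectrometer data must be
  resampled upstream.
- The binary container stores float32; float64 inputs round-trip lossily
  (documented, exact for float32-representable data).
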