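# Methods

## Optical model

All lengths are nanometres, spatial frequencies nm⁻¹ and angles radians
internally; constructors accept kV, mm (spherical aberration) and mrad
and convert once. The electron wavelength is always recomputed
relativistically from the accelerating voltage, never stored separately.

The aberration phase is truncated at defocus and spherical aberration,

    χ(k) = π λ C₁ k² + (π/2) λ³ C₃ k⁴,

in the Saxton sign convention with overfocus-positive C₁. Higher-order
and off-axial aberrations, astigmatism and coma are out of scope and
rejected at configuration load.

Partial coherence enters through two envelopes:

* temporal — `E_t = exp(−[(πλΔ/2)·k²]²)` with Δ the focal spread. Under
  beam tilt the effective (weak-phase) transfer function replaces `k²`
  by `|q + k_τ|² − |k_τ|²`, which vanishes on the achromatic circle
  `|q + k_τ| = |k_τ|` and produces the characteristic annular transfer at
  large tilt. The loss at the centre of the shifted passband,
  `1 − exp(−[(πλΔ/2)|k_τ|²]²)`, evaluates to ≈ 11% at 10 mrad and ≈ 45%
  at 15 mrad for Δ = 4.3 nm at 300 kV, which is what pins this
  convention for Δ.
* spatial — a Gaussian angular source of RMS semi-angle β gives
  `E_s = exp(−½ (β/λ)² |∇χ|²)`, the first-order expansion of χ over the
  source. At the β = 0.02 mrad used throughout, the RMS-vs-FWHM
  ambiguity is numerically irrelevant.

The closed-form tilt relations — optimal coupling `τ = √(−C₁/C₃)`,
tilt-induced defocus change `ΔC₁ = 2C₃τ²` and tilt-induced image shift
`s = (C₁τ + C₃τ³)·û = ∇χ(k_τ)/2π` — follow from the same χ.

## Synthetic data

The generator emulates the two acquisition designs used in practice:
`TiltProtocol.robust()` (one axial + six tilted images, equally spaced
azimuths) for radiation-tolerant samples and
`TiltProtocol.low_fluence()` (four tilted images, no axial exposure) for
beam-sensitive ones, with the total fluence budget split equally across
images (uniform exposure).

Phantoms are pure-phase (amplitude contrast is available but off by
default, since the biological regime is phase-dominated): a `lattice` of
Gaussian bumps standing in for a crystal, random Gaussian `blobs` for
isolated particles, band-pass-filtered Gaussian noise `ice` for
amorphous background, and their `composite`. They deliberately do not
model atomistic potentials, frozen phonons, inelastic scattering or
dose fractionation; passing tests therefore validate the optics,
statistics and reconstruction machinery, not atomic-scale contrast.

Exit waves use the multislice scheme: tilted plane-wave start,
alternating slice transmission and Fourier-space Fresnel propagation
`exp(−iπλz|k|²)`. Beam tilt is carried by the initial plane wave only
(no tilted propagator), adequate for specimens ≤ 30 nm thick at tilts
≤ 15 mrad. Tilt wavevectors are snapped to the nearest grid frequency
sample — periodic grids only support commensurate plane waves — and the
reconstruction rounds tilts to the same canvas step, so simulator and
solver stay mutually consistent; the snap error is at most half a
frequency step (≈ 0.3 mrad on a 256² grid at 0.013 nm/px, less on
larger fields of view).

The detector is parametric: Poisson counting at
`fluence × pixel_area × normalized intensity` expected counts, followed
by a unit-sum Gaussian MTF kernel (default σ = 0.35 cycles/px) and an
optional gain. It is not a model of any specific camera; a `noiseless`
flag returns the scaled expectation exactly (the infinite-fluence
limit). Every image draws from an RNG stream derived from the detector
seed and the image index, so series are bit-reproducible.

## Preprocessing

Defocus is estimated CTFFIND-style: rotationally averaged amplitude
spectrum (Hann-windowed), smooth background removed by a running median
one-twentieth of Nyquist wide, zero-mean normalized cross-correlation
against `|sin χ(k; C₁)|` templates over a trial-defocus grid (fit band
1/10–9/10 Nyquist by default), argmax with parabolic refinement. With
the default 4×4 patch tiling, estimates beyond 3× the median absolute
deviation are rejected and the survivor mean ± standard error is
reported. The correlation is 1-D (radial) because only C₁ is fitted and
astigmatism is not modelled; when C₃ ≈ 0 the CTF magnitude cannot
distinguish the defocus sign and the result is flagged ambiguous, to be
resolved from prior knowledge (cryo data are underfocused).

Registration is phase correlation (unit-normalized cross-power
spectrum) with DFT-upsampled subpixel refinement, returning
displacements in the `np.roll` sign convention. Registering tilted
against axial images is biased wherever their contrast transfer differs
in sign, so an optional band limit restricts the correlation below the
first CTF zero; with it, measured displacements agree with the
closed-form tilt-shift prediction to < 0.3 px on noiseless 256² series.

Shift compensation separates the two entangled contributions to the
measured displacement: stage drift and the optical shift
`(C₁τ + C₃τ³)/pixel` that the forward model itself produces (the full
aberration phase around each tilted carrier *is* a displacement).
Removing the total measured shift would therefore corrupt the
reconstruction; instead the drift — measured minus predicted, referenced
to the chosen reference image — is removed by Fourier-domain subpixel
translation and the model-consistent optical displacement is left in
place. The report records measured, predicted and applied vectors per
image. Motion within a single exposure (dose-fractionated frames) is
not corrected; images are accepted pre-summed.

## Reconstruction

The object spectrum lives on a canvas `upsample ×` the measurement
shape with identical frequency step (the canvas is the super-resolved
field of view; upsample 2 suffices while |k_τ| stays below the
measurement Nyquist). The starting estimate has unit amplitude and zero
phase everywhere — all spectral energy at DC.

Each visit of tilt *j*: crop the sub-spectrum at the rounded −k_τ offset,
multiply by the axial `w(k)` (envelopes included: a damped model is
compared to damped data; deconvolving instead is configurable but off),
inverse transform, replace the real-space amplitude by the measured
one, transform back, and add

    Ô ← Ô + α · conj(w) / ((1 + ε) max|w|²) · ΔΨ

into the canvas, an ePIE-style weighting with ε = 10⁻³ guarding regions
where the envelopes vanish. The step α starts at 0.1 and halves every
10 iterations; tilts are visited in listed order by default (a
seed-shuffled order is available). The per-iteration normalized
amplitude misfit is recorded as the data error; it is invariant under
the global-phase gauge of the estimate.

**Exposure gauge.** Counts fix only relative intensities, and dividing
each image by its mean discards the absolute scale that the envelope
damping of the unscattered carrier would otherwise carry. The measured
amplitude is therefore rescaled to the current model's RMS amplitude
before replacement. With this gauge the true object is an exact fixed
point of the iteration on noiseless data; without it the iteration
minimizes a biased misfit and stalls.

## Analysis

The redundancy map counts, per object frequency, the illuminations
whose effective transfer magnitude exceeds a threshold (default 0.10,
the conventional 10% information-transfer limit); frequencies with ≥ 2
independent measurements form the usable synthetic aperture, and its
best/worst-direction radii are reported as resolutions. A binary-disc
mode (hard apertures, no envelopes) supports exact geometric checks.

PSNR uses `10·log₁₀(P²/MSE)` with `P` the ground-truth dynamic range
(max − min; a max-only normalization is configurable) after removing the
mean difference — the global-phase gauge of phase retrieval. Identical
fields report a 300 dB cap. Circular averages use annular bins one
frequency step wide and conserve energy exactly; the `intensity^0.2`
display weighting is visualization-only. Reflection I/σ is the
background-subtracted mean intensity of a peak disc divided by the
standard deviation of a surrounding, disjoint background annulus.

## Problem sizes and test conditions

The test and acceptance workloads run on 128²–512² grids: the noiseless
round trip uses the robust protocol on a 256² lattice phantom at
0.013 nm/px (50 iterations, upsample 2), defocus estimation uses a 512²
ice micrograph at 0.26 nm/px, and the fluence sweep uses the
low-fluence protocol on a 256² composite phantom at 0.05 nm/px with
C₁ = −250 nm — the published −2000 nm scaled by the grid-size ratio so
that the CTF stays Nyquist-sampled on the smaller grid (χ′(k)·Δk
preserved). The fluence sweep scores each noisy reconstruction against
the infinite-fluence reconstruction of the same series.

## Known limitations

* Low-frequency phase of smooth, blob-like objects under nearly
  aberration-corrected optics is weakly encoded in image amplitudes
  (sin χ ≈ 0 near DC): the iteration reaches very small data error while
  the lowest frequencies converge slowly. Crystalline/high-frequency
  content, or a moderate defocus, conditions the problem far better.
* The effective-WTF analysis (achromatic annulus, tilt planning) assumes
  the weak-phase object approximation; the reconstruction itself does
  not.
* No probe/aberration refinement inside the loop, no position
  refinement, no 3-D (multi-slice) ptychography, no GPU path.
* The detector stand-in and phantoms are deliberately generic; absolute
  I/σ values from experimental cameras and specimens are out of scope.
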