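# Methods

This note documents the models, conventions, parameters, and numerical
choices behind `coilcomb`, and what the synthetic studies do and do not show
about real acquisitions.

## Signal model and conventions

A spectrum is a sum of complex Lorentzians: resonance `(δ, A, L, φ)`
contributes `A e^{iφ} / (1 + 2i(f − f_δ)/L)` on the discrete frequency grid,
so at zero phase the real part is an absorption line of height `A` (peak
normalization) and FWHM `L` Hz, with the matching dispersion in the
imaginary part. The lineshape is Lorentzian because the time-domain signal
of a freely decaying resonance is a damped complex exponential; no other
relaxation or pulse-sequence physics is modeled.

Spectra are stored frequency-ascending, with the carrier at index `n // 2`;
the chemical-shift axis is stored explicitly (ppm = carrier + f/f₀, f₀ in
MHz), and no left/right display convention is ever assumed. The Fourier pair
is `fid = ifft(ifftshift(spectrum))` and `spectrum = fftshift(fft(fid))`,
exact inverses of each other; the roundtrip is property-tested to 1e-10.

The default ³¹P model has 256 points over a 5 kHz band at 120.6 MHz (7 T),
with PCr (height 1.0, 20 Hz) at the band center and Pi, PME, PDE, γ-/α-/β-ATP
at literature shifts with package-chosen heights (0.25–0.55) and linewidths
(25–40 Hz). These amplitudes are illustrative defaults that produce a
realistic-looking brain spectrum; they are not measured ground truth, and
every operation accepts a user model.

Channel noise is complex Gaussian, independent per channel and per sample,
with *per-component* (real or imaginary) standard deviation σ. The study
noise levels are expressed as `FID_max/σ ∈ {10, 3.33, 2}` where `FID_max` is
the largest noise-free FID magnitude; the per-component-σ reading is the one
consistent with those printed ratios. True sensitivities are unit-magnitude
quadrature phases `b_k = e^{ik·2π/N}`, `k = 1..N` — every channel
contributes equally, which makes the ideal uniform-noise gain exactly √N.

FID indices in user-facing APIs are 1-based inclusive ranges (the field's
"second till the fifth points" convention), converted internally to 0-based
half-open slices; the sensitivity estimate is the plain mean of those
samples per channel.

## Combination operators

Uniform-noise (SNR-optimal): `P = C·bᴴR⁻¹p / √(bᴴR⁻¹b)`. The printed forms
of this expression vary in conjugation conventions; the package fixes the
Hermitian form, which is the unique reading that makes the quadratic form
real and the output noise position-independent. With `R` the complex noise
covariance the combined output has unit complex variance (1/√2 per
component); in the identity-`R` pathway used by the Monte Carlo harness the
output per-component noise equals the single-channel σ. Uniform-sensitivity
divides by `bᴴR⁻¹b` instead, flattening the receive profile (noise-free data
reconstructs exactly); sum-of-squares is the phase-blind √Σ|p_k|².

The noise covariance is the Hermitian sample covariance of a noise-only
scan, `(N−1)⁻¹Σ(n−n̄)(n−n̄)ᴴ`, regularized to positive-definite by a
diagonal jitter of 1e-10 times the largest eigenvalue only when numerically
singular. From simulated fields it is the conductivity-weighted overlap
`R_ik = Σ_voxels σ E_i·E_k* ΔV`; the conjugated product is required for
Hermitian symmetry. Degenerate voxels (sensitivity norm below 1e-6 of the
volume maximum, configurable) yield flagged-missing outputs, never
noise-amplified garbage.

## Phase correction and its identifiability limit

Corrections are `e^{i(φ₀ + φ₁(f − f_ref))}` with `f_ref` the magnitude peak
inside the reference window, chosen to maximize the real reference-peak
height by a coarse grid (72 zero-order steps, 41 first-order steps over
±4π/bandwidth rad/Hz) plus Nelder–Mead refinement.

This objective is *exactly degenerate* in φ₁: whatever the ramp, φ₀ can make
the peak sample fully real, so the maximum height is attained on a ridge.
An unconstrained optimizer wanders along that ridge and arbitrarily rotates
spectral regions far from the reference peak. The package therefore accepts
a nonzero φ₁ only when it improves the reference peak by more than 1%
relative to the best zero-order-only correction — otherwise φ₁ = 0 is kept.
The identifiable content of the correction (φ₀, restored peak height) is
what the tests assert; a single narrow reference window simply cannot
determine a first-order term, and integrated-real objectives were measured
to carry a dispersion-tail bias large enough to corrupt off-center peaks.

## Monte Carlo harness

Each repetition synthesizes `p = b_true·s + noise`, forms a sensitivity
estimate (ideal: clean early-FID average; self: the same average of `p`
itself; other: of an independent equal-variance copy; cross: the clean value
plus independent noise scaled down by `cross_snr_ratio`, default 10, plus an
optional fixed systematic perturbation), combines with `R = I`, and Fourier
transforms. Complex spectra are averaged over repetitions (equivalent to
averaging real parts once the single final phase correction is fixed), and
peak heights are read as maxima of the real part inside ±1 ppm windows.
Three independent, seed-derived RNG streams (data / other-copy / cross)
make regimes *paired*: runs with the same seed share the data-noise stream,
which sharpens regime contrasts at fixed repetition count.

Two bias readouts are reported, because "bias" mixes two effects:

- `rel_bias` — peak height relative to the ideal regime. Any noisy weight
  vector loses SNR (the normalization `‖b̂‖` is inflated by weight noise),
  so even the uncorrelated "other" regime sits several percent below ideal
  at low SNR. This is a loss, not an overestimation.
- `shape_bias` — the residual of each peak after fitting the regime's mean
  spectrum to the ideal regime's by a single scalar. For any sensitivity
  independent of the data noise the expected mean spectrum is an exact
  scalar multiple of the ideal one, so this readout isolates the
  correlated-noise overestimation: it is consistent with zero for the
  "other" regime at every tested noise level, and shows the self-weighted
  distortion concentrated near the band center.

Default repetition counts are study-sized where cheap (hundreds to a few
thousand; the harness is vectorized in blocks of 256 repetitions) and every
run reports per-peak Monte Carlo standard errors computed from accumulated
first and second moments of the phase-corrected real spectrum.

## Phase calibration

Cross-nucleus sensitivity maps carry one spatially constant phase offset per
channel from the differing receive chains. Calibration maximizes the
whole-volume SNR: per voxel, the magnitude peak of the uniform-noise
combined spectrum inside the PCr window divided by a fixed noise level,
summed over voxels (magnitude, because the offsets rotate each voxel's
overall phase and the downstream zero-order correction recovers exactly the
magnitude peak; the reference peak is configurable). The greedy procedure
sweeps channel 2 against channel 1 over a 0.2π grid, accretes the remaining
channels one at a time against the running optimum, then re-sweeps channels
in randomly shuffled order until five consecutive rounds gain less than
1e-6 relative. The recorded objective trace covers the full-array
configuration and accepted improvements only, so it is non-decreasing by
construction.

By default each accepted sweep is sharpened by a quadratic fit through the
best grid point and its neighbors: the pure grid sweep quantizes each
channel to ±0.1π *given the others*, and those quantization errors interact,
measured at up to 0.32 rad per channel and ~1% objective shortfall on a
noiseless phantom — the refined sweep recovers injected offsets to ~0.02 rad
and reaches the known-truth objective. `refine=False` restores the pure grid
sweep.

## CSI phantoms and the 1D point-spread demonstrator

Phantoms assign a spectral model per compartment (the default scene: a thin
high-signal slab, a signal-free gap, a large low-signal interior — the
muscle/CSF/brain configuration), multiply by smooth per-channel sensitivity
maps, and transport the spatial signal through a truncated, optionally
Hamming-weighted k-space; truncation keeps the central `⌈fraction·N⌉`
samples centered on the zero-frequency index (even counts keep the extra
sample on the low-frequency side). Boundaries are circular (DFT), making
leakage deterministic and translation-equivariant. Per-channel global phase
offsets are injectable for calibration testing; the ³¹P/²³Na pair generator
gives the sensitivity-source dataset one tenth the target's noise (the
concentration advantage) and optionally a systematic per-channel
perturbation standing in for the receive-field difference between the two
frequencies.

The 1D demonstrator uses two exponentially decaying coil profiles from
opposite FOV ends and 95% k-space truncation by default. Error maps compare
each reconstruction against the *same method's* clean reconstruction (full
k-space, true sensitivities), isolating truncation and
sensitivity-contamination effects; self-estimated sensitivities (the
received signals themselves) reproduce the bleed-amplification mechanism —
note that with them the uniform-noise combination reduces to sum-of-squares
and the uniform-sensitivity one to a flat image wherever signal leaks.
Scene levels and widths are illustrative defaults.

## EM-field evaluation

`emeval` consumes user-supplied per-channel complex E-fields and receive
(B₁⁻) maps on a voxel grid (documented HDF5 layout; no vendor parsing).
All physical constants in the SNR prefactor `ωMV/√(4kTΔf)` default to 1 —
the module reports relative SNR, and the comparisons of interest are ratio
maps in which the constants cancel. Cross-sensitivity ratios against the
matched filter are bounded by 1 (Cauchy–Schwarz), tested everywhere.

## What the synthetic studies do not show

The generator emulates the statistical structure assumed by the analysis —
ideal Lorentzian lines, white per-channel noise, spatially constant
cross-nucleus phase offsets, perfectly shared grids — and none of the
confounds of real acquisitions: B₀/B₁ inhomogeneity, frequency drift,
lineshape distortion, motion, chemical-shift displacement, relaxation
weighting, or a genuinely frequency-dependent receive-field difference
between nuclei. Passing tests therefore validate the estimators and the
bias mechanisms, not end-to-end in vivo performance. Reproducing measured
field-simulation ratio maps would additionally require the external
anatomical EM dataset those maps were computed on, which is out of scope;
the package verifies the algebraic identities and bounds of that evaluation
instead.

## Problem sizes

The shipped tests and the acceptance script run the Monte Carlo harness at
200–4000 repetitions (standard errors are reported alongside every
contrast), phase calibration on an 8×8×4 grid with 8 channels and 64-point
FIDs, and field evaluations on small random grids against brute-force
oracles. These sizes were chosen so the whole suite documents the same
phenomena the full-size runs show while remaining quick to re-run.
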