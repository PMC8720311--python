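# Methods

## Model

A dipole population at sample position `r` is summarized by three per-pixel
quantities: the polarization-invariant emission `g_dc(r) ≥ 0`, the
polarization-variant amplitude `g_ac(r) ≥ 0`, and the in-plane orientation
`α(r) ∈ [0°, 180°)` measured counterclockwise from the image X-axis
(columns increase along X; rows increase downward, so a screen-up tangent
has α near 90°). Under linear excitation at angle θ the emission is
`g_dc + g_ac·cos²(θ − α)`; the excitation intensity I₀ is absorbed into the
units of `g_dc`/`g_ac`, removing a redundant multiplicative symmetry (the
photon scale lives in the noise model instead).

Angles are degrees at every public interface and radians internally. All
orientations are axial (defined modulo 180°); distances between them use
the axial-circular metric `min(d, 180−d)`, and dispersion uses the circular
statistics of the doubled angle.

When several dipole populations overlap in one pixel, the summed cos²
responses combine as complex phasors `g_ac·e^{2jα}`:

```
Σᵢ g_ac,ᵢ cos²(θ−αᵢ) = (Σ g_ac,ᵢ − B)/2 + B cos²(θ−α̂),  B = |Σ g_ac,ᵢ e^{2jαᵢ}|
```

i.e. cancelled polarized mass re-emerges as unpolarized (DC) emission. The
synthetic-field accumulator implements exactly this identity, so a combined
field renders the same stack as the sum of its parts; it is also why OUF at
mixed pixels is lower than any constituent's anisotropy — a physical
statement, not an artifact to correct.

## Acquisition geometry

Excitation polarization is rotated by a half-wave plate: polarization angle
= 2 × motor angle, so one 360° motor turn sweeps polarization twice around
and the cos² response completes exactly 4 modulation cycles (4 OLID
periods). One OLID period is a π sweep sampled with M uniform steps
Δθ = π/M; m periods give N = m·M frames. The modulation frequency is 1/π
per radian of polarization angle. Defaults: m = 4, M = 30 (6° steps).
M is a free parameter of the instrument; 30 gives comfortable margin over
the Nyquist requirement of >2 samples per cos² period, and every stage
accepts any M ≥ 4.

## Lock-in filtering (OLID)

Per pixel, the N-point DFT with kernel `e^{−j2πkn/N}` concentrates the
ideal signal in bins {0, +m, N−m}; those are kept, all others zeroed, and a
single M-frame period is resynthesized as
`A + (2|G(m)|/N)·cos(2nΔθ + arg G(m))`. The scale is pinned by the
requirement that a noiseless input's first period is reproduced exactly.
Additive white noise keeps 3 of N bins, so its variance is reduced by 3/N
and the SNR gain on the noise floor is `10·log10(N/3)` (≈16 dB at N=120).
Photobleaching is not detrended by default (an optional linear detrend flag
exists); a ~10% total decay over 4 periods biases orientation by well under
one degree.

## Deconvolution

The single-period stack is deconvolved by minimizing
`Σ_θ ‖U ∗ g(·,θ) − I(·,θ)‖²` over the spatial–angular stack `g(R,θ)` —
plain least squares, no sparsity penalty and no Poisson likelihood; the
lock-in step has already done the denoising. Choices that matter:

- **Boundary handling.** Both the simulator and the deconvolver realize
  reflective-boundary convolution as reflect-pad → circular FFT convolution
  → crop. The FISTA unknown lives on the padded grid, so the
  forward/adjoint pair (crop∘conv, corr∘zero-embed) is exactly adjoint.
  Simulator and reconstruction therefore share one operator, and noiseless
  data have an exact zero-objective fixed point.
- **FISTA variant.** Monotone FISTA with adaptive restart: the candidate
  step is kept only if it does not increase the objective, and momentum is
  reset when it would. The step is 1/L with L = σ_max² of the blur operator
  from ≥20 power iterations (delta PSF → L = 1; any unit-sum kernel →
  L ≤ 1). The reported `objective_trace` is non-increasing by construction.
- **Nonnegativity.** On by default (intensities are physical; unconstrained
  least squares rings negative around point sources and corrupts OUF), with
  a flag to disable for a literal unconstrained solve.
- **Angular coupling.** The unknown is the full M-frame angular stack with
  a purely spatial blur per frame; an optional cos²-shaped circular
  smoothing along θ (`angular_coupling`) is provided but off by default —
  the forward model of the acquisition contains no angular blur.
- **Upsampling.** `upsample = s` places the unknown on an s× finer grid
  with the PSF re-discretized at pitch/s and s×s sum-binning in the forward
  model (adjoint = replication). Factor 2 is used for the finest two-point
  studies; default 1.
- **Initialization.** The replicated measurement (`init="data"`, fast
  warm start) or zeros (`init="zero"`, the canonical ‖I‖² initial
  objective used by convergence tests).
- Defaults: 200 iterations, relative objective-change tolerance 1e−6.

The sparse baseline (`sdom_baseline`) adds `λ‖g‖₁` solved by proximal
(soft-threshold) FISTA; λ = 0 reduces exactly to the plain solver. A single
L1 weight is used for this comparison baseline.

## Orientation extraction (FFTPE)

Per pixel, `A = G(0)/N`, `B = 2|G(m)|/N`, `α = −arg G(m)/2 (mod 180°)`
(the modulation bin satisfies `G(m) = (N/2)·B·e^{−j2α}` under the forward
DFT kernel — the sign convention is pinned by a unit test). On uniform
full-period sampling this is identical to the linear least-squares fit on
{1, cos2θ, sin2θ} (the DFT *is* that orthogonal projection); the LS path is
kept for non-uniform frame subsets and as an independent cross-check, and
is the slower of the two. OUF = 2B/(A+B), clipped to [0,1] only against
floating-point excursion.

Pixels with `B/A < 0.02` (or `A ≤ 0`) are masked invalid: below that
modulation depth the phase is noise-dominated. The threshold is a declared
default, adjustable everywhere.

Absolute calibration uses the standard curve of a polarizer parallel to the
X-axis: the spatially averaged reference trace gives the instrument phase
offset θ₀ (added to α) and a modulation depth used as a quality gate
(rejected below 0.2).

## Synthetic data

The generator emulates: the cos² dipole response; spatial blur by a
unit-sum Gaussian PSF (Airy optional), default FWHM 200 nm — the
diffraction limit of conventional wide-field imaging — discretized on a
20 nm simulation grid; Poisson shot noise at a specified photon scale plus
Gaussian read noise (default σ = 2 photons); constant background; and
optional exponential per-frame photobleaching. Sub-pixel emitters are
placed by bilinear mass splatting (total flux exact). Fixtures: two-point
pairs with controlled separation/Δα/OUF, polyline filaments with
tangent-aligned orientation, and seeded random scatters.

What it does **not** emulate: vectorial high-NA PSFs, out-of-plane (3D)
dipole components, camera-specific gain registers, drift, or
sample dynamics. Passing tests therefore demonstrate correctness of the
algorithmic chain under the stated image-formation model, not robustness to
every property of real microscope data.

## Study conditions and problem sizes

The quantitative studies (tests and `scripts/acceptance.py`) use: 20 nm
grid, PSF FWHM 200 nm, m = 4 × M = 30 unless a 1-vs-4-period comparison is
the point; high-SNR conditions are 1000 expected photons at the brightest
blurred pixel (moderate: 200), read σ = 2. Monte-Carlo precision studies
run 200–500 noise realizations of a single emitter on a 32×32 grid with a
40-iteration deconvolution (the orientation phase converges much faster
than the intensity profile); separation sweeps use 48×48 grids, 10 nm
sweep steps, 200 iterations, and 2× upsampling for the intensity-dip
studies. Sweeps exploit monotonicity: separations are scanned from large
to small and stop at the first unresolved value.

## Resolvability criteria

- **Intensity**: the profile along the known inter-emitter axis (bilinear
  interpolation, 5 nm steps) of the modulated-component amplitude map must
  show two local maxima with an interior valley ≤ 0.75 of the lower peak —
  a Rayleigh-like dip rule. Two diffraction-limited Gaussians at 200 nm
  separation give valley/peak ≈ 0.93 and are correctly called unresolved.
  The 0.75 threshold is a declared constant; conclusions are insensitive
  across 0.6–0.9 because the post-deconvolution dip is deep once present.
- **Orientation**: the recovered orientations at the two true emitter
  pixels must each lie within `0.35·Δα + 5°` of their own truth and differ
  from each other by at least Δα/2. The constants are chosen so noiseless
  perfect recovery always resolves and a fully mixed pixel (both positions
  reading the common mean) never does.
- The reported minimum separation is the smallest value above the largest
  unresolved separation, which makes the reading monotone even if an
  isolated small separation passes spuriously.

## Known limitations

- The OUF-error multi-period gain: the measured RMSE ratio between 1-period
  and 4-period estimates of a weak (OUF = 0.1) emitter follows the 1/√N
  law (≈2.0, slightly reduced by the shared Rician bias floor of the
  modulation amplitude) across every noise level we simulate; a ratio as
  low as ~1.6 is not reproduced under this image-formation model.
- Frame rolling assumes the scene is quasi-static within one N-frame
  window; windows advance one OLID period at a time and each carries its
  correct starting excitation phase. Warm-starting deconvolution across
  windows is available but off by default.
- Deconvolution sharpness (hence the same-orientation two-point limit)
  depends on iteration count; the defaults above are the declared
  operating point, not a converged super-resolution limit.
- OUF mixes populations within a pixel: it is a per-pixel uniformity
  measure, not a per-molecule anisotropy estimate.
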